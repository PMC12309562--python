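"""Distance decay, distance normalization and track statistics."""

import numpy as np
import pytest
from scipy import stats

from telsprite.clusters import CHRT, MappedRead, SpriteCluster
from telsprite.contacts import GenomeBinning
from telsprite.intervals import GenomeIntervals
from telsprite.teltrack import (
    decay_curve,
    distance_classes,
    distance_normalize,
    eigencorrelation,
    gene_counts,
    group_compare,
    overlap_flags,
    peak_proximity_profile,
)


class TestDistanceClasses:
    def test_terminal_bins_are_class_one(self, small_binning):
        classes = distance_classes(small_binning)
        # chrA: 10 bins -> classes 1..5..1; chrB: 6 bins -> 1,2,3,3,2,1
        assert classes[:10].tolist() == [1, 2, 3, 4, 5, 5, 4, 3, 2, 1]
        assert classes[10:].tolist() == [1, 2, 3, 3, 2, 1]


class TestDecayCurve:
    def test_constant_track_is_flat(self, small_binning):
        curve = decay_curve(np.full(16, 3.7), small_binning)
        assert np.allclose(curve["ratio"], 1.0)

    def test_class_one_reference(self, small_binning):
        classes = distance_classes(small_binning)
        track = np.where(classes == 1, 10.0, 1.0)
        curve = decay_curve(track, small_binning)
        assert curve.loc[curve.distance_class == 1, "ratio"].iloc[0] == 1.0
        assert np.allclose(curve.loc[curve.distance_class > 1, "ratio"], 0.1)

    def test_zero_bins_excluded(self, small_binning):
        classes = distance_classes(small_binning)
        track = np.where(classes == 1, 2.0, 0.0)
        track[1] = 6.0  # single non-zero class-2 bin
        curve = decay_curve(track, small_binning)
        assert set(curve["distance_class"]) == {1, 2}
        assert curve.loc[curve.distance_class == 2, "n_bins"].iloc[0] == 1

    def test_degenerate_track_raises(self, small_binning):
        with pytest.raises(ValueError, match="degenerate"):
            decay_curve(np.zeros(16), small_binning)

    def test_recovers_planted_exponential_decay(self, small_binning):
        """Log-ratio slope of a planted exponential decay matches -lambda."""
        rng = np.random.default_rng(0)
        classes = distance_classes(small_binning)
        lam = 0.5
        slopes = []
        for _ in range(20):
            track = np.exp(-lam * (classes - 1)) * rng.lognormal(0, 0.05, 16)
            curve = decay_curve(track, small_binning)
            fit = stats.linregress(curve.distance_class - 1, np.log(curve.ratio))
            slopes.append(fit.slope)
        assert np.mean(slopes) == pytest.approx(-lam, abs=0.05)


class TestDistanceNormalize:
    def test_class_means_are_one(self, small_binning, rng):
        track = rng.gamma(2.0, 1.0, 16)
        track[3] = 0.0  # an unmappable bin
        normalized = distance_normalize(track, small_binning)
        classes = distance_classes(small_binning)
        assert np.isnan(normalized[3])
        for d in np.unique(classes):
            vals = normalized[(classes == d) & (track != 0)]
            if len(vals):
                assert vals.mean() == pytest.approx(1.0, abs=1e-12)

    def test_constant_track_normalizes_to_ones(self, small_binning):
        normalized = distance_normalize(np.full(16, 5.0), small_binning)
        assert np.allclose(normalized, 1.0)

    def test_idempotent(self, small_binning, rng):
        track = rng.gamma(2.0, 1.0, 16)
        once = distance_normalize(track, small_binning)
        twice = distance_normalize(np.nan_to_num(once), small_binning)
        assert np.allclose(once, twice, equal_nan=True)

    def test_all_zero_class_stays_flagged(self, small_binning):
        classes = distance_classes(small_binning)
        track = np.where(classes == 3, 0.0, 1.0)
        normalized = distance_normalize(track, small_binning)
        assert np.isnan(normalized[classes == 3]).all()

    def test_planted_hotspot_emerges(self):
        """A 5x hotspot deep in the decay is unremarkable in the raw track
        but becomes the normalized maximum; with k bins in its distance
        class the noiseless normalized value is exactly 5k/(k+4)."""
        binning = GenomeBinning(
            {f"chr{i}": 12_000_000 for i in range(1, 6)}, 1_000_000
        )
        classes = distance_classes(binning)
        track = np.exp(-0.8 * (classes - 1))
        hot = 4  # class 5 bin on chr1
        assert classes[hot] == 5
        track[hot] *= 5.0
        assert track[hot] < track[0]  # raw value below the terminal bins
        normalized = distance_normalize(track, binning)
        k = (classes == 5).sum()
        assert normalized[hot] == pytest.approx(5 * k / (k + 4), abs=1e-12)
        assert np.nanargmax(normalized) == hot


class TestOverlapFlags:
    def test_exact_bin(self, small_binning):
        flags = overlap_flags(
            small_binning, GenomeIntervals.from_tuples([("chrA", 1_000_000, 2_000_000)])
        )
        assert flags[1] and flags.sum() == 1

    def test_boundary_spanning(self, small_binning):
        flags = overlap_flags(
            small_binning, GenomeIntervals.from_tuples([("chrA", 1_999_999, 2_000_001)])
        )
        assert flags[1] and flags[2] and flags.sum() == 2

    def test_disjoint_bins_counted(self, small_binning):
        ivals = GenomeIntervals.from_tuples(
            [("chrA", 100, 200), ("chrA", 3_500_000, 3_600_000), ("chrB", 0, 50)]
        )
        assert overlap_flags(small_binning, ivals).sum() == 3

    def test_unknown_chromosome_warns(self, small_binning):
        with pytest.warns(UserWarning, match="unknown chromosome"):
            flags = overlap_flags(
                small_binning, GenomeIntervals.from_tuples([("chrZ", 0, 100)])
            )
        assert flags.sum() == 0

    def test_gene_counts(self, small_binning):
        genes = GenomeIntervals.from_tuples(
            [
                ("chrA", 100, 200, "g1"),
                ("chrA", 150, 400, "g2"),
                ("chrA", 2_500_000, 2_600_000, "g3"),
            ]
        )
        counts = gene_counts(small_binning, genes)
        assert counts[0] == 2 and counts[2] == 1 and counts.sum() == 3


class TestGroupCompare:
    def test_identical_groups(self):
        values = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        flags = np.array([True] * 4 + [False] * 4)
        res = group_compare(values, flags)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_large_separation(self, rng):
        values = np.concatenate([rng.normal(10, 1, 200), rng.normal(0, 1, 2800)])
        flags = np.arange(3000) < 200
        res = group_compare(values, flags)
        assert res.pvalue < 1e-10 and res.statistic > 0

    def test_nan_excluded_and_small_group_raises(self):
        values = np.array([np.nan, np.nan, np.nan, 1.0, 2.0, 3.0])
        flags = np.array([True, True, True, False, False, False])
        with pytest.raises(ValueError, match="flagged group"):
            group_compare(values, flags)

    def test_scale_invariance(self, rng):
        values = rng.gamma(2, 1, 500)
        flags = rng.random(500) < 0.1
        a = group_compare(values, flags)
        b = group_compare(values * 37.5, flags)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_empirical_power_matches_welch_oracle(self):
        """Empirical rejection rate at d=1, n=200/2800 matches the
        noncentral-t closed form within 5 points."""
        n1, n2, d, alpha = 40, 560, 0.5, 0.01  # scaled so power is not ~1
        nc = d / np.sqrt(1 / n1 + 1 / n2)
        # Welch-Satterthwaite df at equal unit variances
        df = (1 / n1 + 1 / n2) ** 2 / (
            (1 / n1) ** 2 / (n1 - 1) + (1 / n2) ** 2 / (n2 - 1)
        )
        crit = stats.t.ppf(1 - alpha / 2, df)
        power = 1 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)
        rng = np.random.default_rng(11)
        hits = 0
        reps = 400
        for _ in range(reps):
            values = np.concatenate([rng.normal(d, 1, n1), rng.normal(0, 1, n2)])
            flags = np.arange(n1 + n2) < n1
            hits += group_compare(values, flags).pvalue < alpha
        assert hits / reps == pytest.approx(power, abs=0.05)


def profile_clusters():
    peaks_at = [1_000_000, 3_000_000]
    tel, nontel = [], []
    for k, center in enumerate(peaks_at):
        for off in (-20_000, 0, 20_000):
            tel.append(
                SpriteCluster(
                    f"t{k}{off}",
                    (
                        MappedRead(f"t{k}{off}", CHRT, 0, 1),
                        MappedRead(f"t{k}{off}", "chrA", center + off - 45, center + off + 45),
                    ),
                )
            )
            nontel.append(
                SpriteCluster(
                    f"n{k}{off}",
                    (
                        MappedRead(f"n{k}{off}", "chrA", center + off - 45, center + off + 45),
                        MappedRead(f"n{k}{off}", "chrA", center - off - 45, center - off + 45),
                    ),
                )
            )
    return tel, nontel


class TestPeakProximity:
    peaks = GenomeIntervals.from_tuples(
        [("chrA", 900_000, 1_100_000), ("chrA", 2_900_000, 3_100_000)]
    )

    def test_identical_placement_gives_flat_curve(self):
        tel, _ = profile_clusters()
        nontel = [
            SpriteCluster(c.barcode + "x", tuple(m for m in c.members if not m.is_chrT))
            for c in tel
        ]
        # give the non-telomere clusters a second member so they are clusters
        nontel = [
            SpriteCluster(c.barcode, c.members + (MappedRead(c.barcode, "chrA", 10_000_000, 10_000_090),))
            for c in nontel
        ]
        curve = peak_proximity_profile(tel + nontel, self.peaks, window=30_000, step=10_000)
        observed = curve.dropna(subset=["ratio"])
        assert np.allclose(observed["ratio_min1"], 1.0)

    def test_concentration_at_peak_center(self):
        # telomere reads sit exactly at peak centers; non-telomere coverage
        # is spread uniformly across the window
        tel = [
            SpriteCluster(
                f"t{k}",
                (
                    MappedRead(f"t{k}", CHRT, 0, 1),
                    MappedRead(f"t{k}", "chrA", center - 45, center + 45),
                ),
            )
            for k, center in enumerate([1_000_000, 3_000_000] * 3)
        ]
        spread = [
            SpriteCluster(
                f"s{i}",
                (
                    MappedRead(f"s{i}", "chrA", 1_000_000 + i * 7_000 - 45, 1_000_000 + i * 7_000 + 45),
                    MappedRead(f"s{i}", "chrA", 3_000_000 - i * 7_000 - 45, 3_000_000 - i * 7_000 + 45),
                ),
            )
            for i in range(-6, 7)
        ]
        curve = peak_proximity_profile(tel + spread, self.peaks, window=49_000, step=7_000)
        peak_bin = curve.loc[curve["ratio_min1"].idxmax(), "distance"]
        assert abs(peak_bin) < 7_000

    def test_no_telomere_clusters_raises(self):
        _, nontel = profile_clusters()
        with pytest.raises(ValueError, match="telomere"):
            peak_proximity_profile(nontel, self.peaks)

    def test_empty_peaks_raises(self):
        tel, _ = profile_clusters()
        with pytest.raises(ValueError, match="empty"):
            peak_proximity_profile(tel, GenomeIntervals())

    def test_cluster_duplication_invariance(self):
        tel, nontel = profile_clusters()
        a = peak_proximity_profile(tel + nontel, self.peaks, window=30_000, step=10_000)
        b = peak_proximity_profile(
            tel + tel + nontel + nontel, self.peaks, window=30_000, step=10_000
        )
        assert np.allclose(a["ratio"], b["ratio"], equal_nan=True)


class TestEigencorrelation:
    def test_perfect_correlation(self, rng):
        v = rng.normal(size=100)
        r, p = eigencorrelation(v, v)
        assert r == pytest.approx(1.0)
        r, _ = eigencorrelation(v, -v)
        assert r == pytest.approx(-1.0)

    def test_nan_dropped_pairwise(self, rng):
        v = rng.normal(size=50)
        w = v.copy()
        v[0] = np.nan
        w[1] = np.nan
        r, _ = eigencorrelation(v, w)
        assert r == pytest.approx(1.0)

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError, match="<3"):
            eigencorrelation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_planted_negative_dependence_recovered(self):
        """Planted r0=-0.4 at n=2500 estimated within +-0.05 across seeds."""
        r0 = -0.4
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=2500)
            y = r0 * x + np.sqrt(1 - r0**2) * rng.normal(size=2500)
            r, p = eigencorrelation(y, x)
            assert r == pytest.approx(r0, abs=0.05)
            assert p < 1e-10
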