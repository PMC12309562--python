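"""Analysis of the genome-wide telomere contact track.

Telomere contact frequency is dominated by linear distance from the nearest
chromosome end: spatial contacts are most likely between linearly proximal
loci, so the terminal bins of every arm carry by far the highest telomere
signal. The analyses here quantify that decay, remove it by distance
normalization (divide each bin by the mean over all bins equidistant from
their nearest chromosome end), and then ask what else structures the track:
overlap with centromeres or ectopic-repeat loci (Welch t-test on normalized
values), proximity of telomere-cluster reads to H3K9me3 peaks, and
correlation with A/B compartment eigenvectors.

Bins whose raw contact frequency is exactly zero are assumed to lack
mappable DNA and are excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import SpriteCluster
from .contacts import GenomeBinning
from .intervals import GenomeIntervals

__all__ = [
    "distance_classes",
    "decay_curve",
    "distance_normalize",
    "overlap_flags",
    "gene_counts",
    "group_compare",
    "GroupCompareResult",
    "peak_proximity_profile",
    "eigencorrelation",
]


def distance_classes(binning: GenomeBinning) -> np.ndarray:
    """Distance of each genomic bin from the nearest chromosome end, in bin
    units, with the terminal bin of every arm assigned class 1."""
    classes = np.empty(binning.n_genomic_bins, dtype=np.int64)
    for chrom in binning.chrom_sizes:
        lo, hi = binning.chrom_bin_range(chrom)
        m = hi - lo
        within = np.arange(m)
        classes[lo:hi] = np.minimum(within, m - 1 - within) + 1
    return classes


def decay_curve(track: np.ndarray, binning: GenomeBinning) -> pd.DataFrame:
    """Mean telomere contact per distance class, as a ratio to class 1.

    Zero bins are excluded. Returns a DataFrame with columns distance_class,
    n_bins, mean, sem, ratio, ratio_sem where ratio = class mean divided by
    the class-1 mean.
    """
    track = np.asarray(track, dtype=float)
    classes = distance_classes(binning)
    nonzero = track != 0
    rows = []
    for d in np.unique(classes):
        vals = track[(classes == d) & nonzero]
        if len(vals) == 0:
            continue
        sem = float(stats.sem(vals)) if len(vals) > 1 else np.nan
        rows.append((int(d), len(vals), float(vals.mean()), sem))
    df = pd.DataFrame(rows, columns=["distance_class", "n_bins", "mean", "sem"])
    if df.empty or df.loc[df["distance_class"] == 1, "mean"].empty:
        raise ValueError("degenerate track: no non-zero class-1 bins")
    ref = float(df.loc[df["distance_class"] == 1, "mean"].iloc[0])
    if ref == 0:
        raise ValueError("degenerate track: class-1 mean is zero")
    df["ratio"] = df["mean"] / ref
    df["ratio_sem"] = df["sem"] / ref
    return df


def distance_normalize(track: np.ndarray, binning: GenomeBinning) -> np.ndarray:
    """Divide each bin by the mean over non-zero bins of its distance class.

    Zero bins (assumed unmappable) are flagged NaN and excluded from the
    class means; a class whose bins are all zero stays entirely NaN.
    """
    track = np.asarray(track, dtype=float)
    if len(track) != binning.n_genomic_bins:
        raise ValueError("track length does not match the genomic bin count")
    classes = distance_classes(binning)
    normalized = np.full_like(track, np.nan, dtype=float)
    nonzero = track != 0
    for d in np.unique(classes):
        sel = (classes == d) & nonzero
        if not sel.any():
            continue
        normalized[sel] = track[sel] / track[sel].mean()
    return normalized


def overlap_flags(binning: GenomeBinning, intervals: GenomeIntervals) -> np.ndarray:
    """Per-genomic-bin flag: True iff the bin overlaps any interval >=1 bp."""
    intervals = intervals.restrict_to(binning.chrom_sizes)
    flags = np.zeros(binning.n_genomic_bins, dtype=bool)
    for chrom, start, end, idx in binning.bins.itertuples(index=False):
        if idx >= binning.chrT_index:
            continue
        flags[idx] = intervals.overlaps(chrom, start, end)
    return flags


def gene_counts(binning: GenomeBinning, genes: GenomeIntervals) -> np.ndarray:
    """Number of gene intervals overlapping each genomic bin."""
    genes = genes.restrict_to(binning.chrom_sizes)
    counts = np.zeros(binning.n_genomic_bins, dtype=np.int64)
    for chrom, start, end, idx in binning.bins.itertuples(index=False):
        if idx >= binning.chrT_index:
            continue
        counts[idx] = genes.count_overlapping(chrom, start, end)
    return counts


@dataclass(frozen=True)
class GroupCompareResult:
    statistic: float
    pvalue: float
    mean_in: float
    mean_out: float
    n_in: int
    n_out: int


def group_compare(values: np.ndarray, flags: np.ndarray) -> GroupCompareResult:
    """Welch two-sample t-test of flagged vs unflagged bins.

    NaN values (zero/unmappable bins) are excluded. Welch's unequal-variance
    form is used because the two groups (e.g. centromeric vs all other bins)
    differ drastically in size and variance.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    ok = ~np.isnan(values)
    a = values[flags & ok]
    b = values[~flags & ok]
    if len(a) < 2:
        raise ValueError(f"flagged group has {len(a)} usable bins (<2)")
    if len(b) < 2:
        raise ValueError(f"unflagged group has {len(b)} usable bins (<2)")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupCompareResult(
        float(t), float(p), float(a.mean()), float(b.mean()), len(a), len(b)
    )


def _nearest_center_distance(
    midpoints: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Signed distance (midpoint - center) to the nearest peak center."""
    idx = np.searchsorted(centers, midpoints)
    idx_lo = np.clip(idx - 1, 0, len(centers) - 1)
    idx_hi = np.clip(idx, 0, len(centers) - 1)
    d_lo = midpoints - centers[idx_lo]
    d_hi = midpoints - centers[idx_hi]
    return np.where(np.abs(d_lo) <= np.abs(d_hi), d_lo, d_hi)


def peak_proximity_profile(
    clusters: Iterable[SpriteCluster],
    peaks: GenomeIntervals,
    window: int = 50_000,
    step: int = 1_000,
) -> pd.DataFrame:
    """Ratio of telomere-cluster to non-telomere-cluster read density as a
    function of signed distance to the nearest peak center.

    For every genomic read, the distance from its midpoint to the nearest
    peak center is binned on [-window, +window] at ``step``. The profile is
    the per-bin count ratio (clusters containing chrT) / (clusters without
    chrT), rescaled so its minimum is one. Distance bins with zero
    non-telomere counts are reported as NaN (missing).
    """
    centers = {
        chrom: np.sort((arr[:, 0] + arr[:, 1]) // 2)
        for chrom, arr in peaks.intervals.items()
        if arr.size
    }
    if not centers:
        raise ValueError("peak set is empty")
    n_bins = (2 * window) // step
    edges = -window + np.arange(n_bins + 1) * step
    tel_counts = np.zeros(n_bins, dtype=np.int64)
    nontel_counts = np.zeros(n_bins, dtype=np.int64)
    for c in clusters:
        target = tel_counts if c.has_chrT else nontel_counts
        by_chrom: dict[str, list[int]] = {}
        for m in c.members:
            if not m.is_chrT and m.chrom in centers:
                by_chrom.setdefault(m.chrom, []).append((m.start + m.end) // 2)
        for chrom, mids in by_chrom.items():
            d = _nearest_center_distance(np.asarray(mids), centers[chrom])
            d = d[(d >= -window) & (d < window)]
            if d.size:
                np.add.at(target, (d + window) // step, 1)
    if tel_counts.sum() == 0:
        raise ValueError("no reads from telomere-containing clusters near peaks")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(nontel_counts > 0, tel_counts / nontel_counts, np.nan)
    if np.all(np.isnan(ratio)):
        raise ValueError("all distance bins missing (no non-telomere coverage)")
    ratio_min = np.nanmin(ratio[ratio > 0]) if np.any(ratio > 0) else np.nan
    if not np.isfinite(ratio_min) or ratio_min == 0:
        normalized = ratio
    else:
        normalized = ratio / ratio_min
    return pd.DataFrame(
        {
            "distance": edges[:-1] + step // 2,
            "n_telomere": tel_counts,
            "n_nontelomere": nontel_counts,
            "ratio": ratio,
            "ratio_min1": normalized,
        }
    )


def eigencorrelation(
    values: np.ndarray, eigenvector: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between a track and a compartment eigenvector.

    NaN entries in either vector are dropped pairwise; fewer than 3 retained
    bins is an error.
    """
    values = np.asarray(values, dtype=float)
    eigenvector = np.asarray(eigenvector, dtype=float)
    if values.shape != eigenvector.shape:
        raise ValueError("vectors must cover the same bins")
    ok = ~(np.isnan(values) | np.isnan(eigenvector))
    if ok.sum() < 3:
        raise ValueError(f"only {int(ok.sum())} retained bins (<3)")
    r, p = stats.pearsonr(values[ok], eigenvector[ok])
    return float(r), float(p)
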