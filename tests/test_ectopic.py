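"""Soft-clip telomere window scan and the ectopic-locus filter chain."""

import numpy as np
import pytest

from conftest import random_dna
from oracles import oracle_best_window
from telsprite.ectopic import (
    ClipTelomereEvidence,
    ListMappability,
    LongReadAlignment,
    call_ectopic_loci,
    classify_clip,
    locus_mappability_filter,
    annotate_loci_genes,
    scan_telomere_window,
)
from telsprite.intervals import GenomeIntervals
from telsprite.repeatfilter import CANONICAL_C, CANONICAL_G
from telsprite.simdata import SimGenome, simulate_long_reads

SIZES = {"chrA": 10_000_000, "chrB": 8_000_000}


def coverage(chrom, pos, mapqs):
    return [
        LongReadAlignment(f"cov{i}", chrom, pos - 3000, pos + 3000, q, 0, 0, None)
        for i, q in enumerate(mapqs)
    ]


class TestScanWindow:
    def test_tandem_canonical_passes(self, motifs):
        hit = scan_telomere_window(CANONICAL_G * 66, motifs)  # 396 bp
        assert hit is not None
        assert hit.count == 50  # 300 / 6
        assert hit.strand == "G" and hit.offset == 0

    def test_44_repeats_in_300bp_fails(self, motifs, rng):
        seq = CANONICAL_G * 44 + random_dna(rng, 300 - 44 * 6)
        assert scan_telomere_window(seq, motifs) is None

    def test_short_sequence_ineligible(self, motifs):
        assert scan_telomere_window(CANONICAL_G * 49, motifs) is None  # 294 bp

    def test_window_must_anchor_at_canonical(self, motifs):
        # variant-only sequence: 50 repeats but no canonical anchor
        assert scan_telomere_window("TCAGGG" * 66, motifs) is None

    def test_c_strand_window(self, motifs):
        hit = scan_telomere_window(CANONICAL_C * 66, motifs)
        assert hit is not None and hit.strand == "C"

    def test_mosaics_match_bruteforce_window_oracle(self, motifs, rng):
        for _ in range(40):
            parts = []
            for _ in range(12):
                roll = rng.random()
                if roll < 0.4:
                    parts.append(CANONICAL_G * int(rng.integers(1, 12)))
                elif roll < 0.6:
                    parts.append("TCAGGG" * int(rng.integers(1, 8)))
                else:
                    parts.append(random_dna(rng, int(rng.integers(5, 60))))
            seq = "".join(parts)[:600]
            hit = scan_telomere_window(seq, motifs)
            best = oracle_best_window(seq, motifs)
            if best >= 45:
                assert hit is not None and hit.count == best
            else:
                assert hit is None


class TestClassifyClip:
    def make(self, left=0, right=0, left_seq="", right_seq="", mapq=60):
        aligned = "A" * 2000
        seq = left_seq + aligned + right_seq
        return LongReadAlignment(
            "r1", "chrA", 1_000_000 - 0, 1_000_000 + 2000, mapq,
            left, right, seq,
        )

    def test_right_clip_standard(self, motifs):
        aln = self.make(right=402, right_seq=CANONICAL_G * 67)
        (ev,) = classify_clip(aln, motifs)
        assert ev.side == "right" and ev.orientation == "standard"
        assert ev.position == aln.end
        assert ev.window_count >= 45

    def test_right_clip_inverted(self, motifs):
        aln = self.make(right=402, right_seq=CANONICAL_C * 67)
        (ev,) = classify_clip(aln, motifs)
        assert ev.orientation == "inverted"

    def test_left_clip_standard_is_c_strand(self, motifs):
        aln = self.make(left=402, left_seq=CANONICAL_C * 67)
        (ev,) = classify_clip(aln, motifs)
        assert ev.side == "left" and ev.orientation == "standard"
        assert ev.position == aln.start

    def test_telomere_in_aligned_portion_ignored(self, motifs):
        seq = "A" * 500 + CANONICAL_G * 67 + "A" * 500
        aln = LongReadAlignment("r1", "chrA", 0, len(seq), 60, 0, 0, seq)
        assert classify_clip(aln, motifs) == []

    def test_clip_too_short_for_window(self, motifs):
        aln = self.make(right=200, right_seq=(CANONICAL_G * 34)[:200])
        assert classify_clip(aln, motifs) == []

    def test_missing_sequence_warns(self, motifs):
        aln = LongReadAlignment("r1", "chrA", 0, 2000, 60, 400, 0, None)
        with pytest.warns(UserWarning, match="no stored sequence"):
            assert classify_clip(aln, motifs) == []


class TestMappabilityFilter:
    def test_boundary_inclusive_at_40_percent(self):
        m = ListMappability(coverage("chrA", 500_000, [5] * 4 + [60] * 6))
        assert not locus_mappability_filter("chrA", 500_000, m)

    def test_just_below_threshold_passes(self):
        m = ListMappability(coverage("chrA", 500_000, [5] * 3 + [60] * 7))
        assert locus_mappability_filter("chrA", 500_000, m)

    def test_no_overlapping_reads_fails(self):
        m = ListMappability([])
        assert not locus_mappability_filter("chrA", 500_000, m)


def evidence(read_id, chrom, pos, mapq=60):
    return ClipTelomereEvidence(read_id, chrom, pos, "right", "standard", 50, mapq)


class TestCallLoci:
    def good_mappability(self):
        reads = []
        for pos in (500_000, 500_040, 500_080, 2_000_000, 99_000, 9_950_000):
            reads.extend(coverage("chrA", pos, [60] * 10))
        return ListMappability(reads)

    def test_nearby_evidence_merges(self):
        ev = [evidence("r1", "chrA", 500_000), evidence("r2", "chrA", 500_080)]
        loci = call_ectopic_loci(ev, SIZES, self.good_mappability())
        assert len(loci) == 1
        assert loci[0].position == 500_040  # median
        assert loci[0].support == 2

    def test_gap_above_100bp_splits(self):
        ev = [
            evidence("r1", "chrA", 500_000),
            evidence("r2", "chrA", 500_000),
            evidence("r3", "chrA", 500_101),
            evidence("r4", "chrA", 500_101),
        ]
        loci = call_ectopic_loci(ev, SIZES, self.good_mappability())
        assert len(loci) == 2

    def test_single_read_not_called(self):
        loci = call_ectopic_loci(
            [evidence("r1", "chrA", 500_000)], SIZES, self.good_mappability()
        )
        assert loci == []

    def test_duplicate_read_id_counts_once(self):
        ev = [evidence("r1", "chrA", 500_000), evidence("r1", "chrA", 500_050)]
        assert call_ectopic_loci(ev, SIZES, self.good_mappability()) == []

    def test_low_mapq_dropped(self):
        ev = [evidence("r1", "chrA", 500_000, mapq=29), evidence("r2", "chrA", 500_000, mapq=29)]
        assert call_ectopic_loci(ev, SIZES, self.good_mappability()) == []
        ev30 = [evidence("r1", "chrA", 500_000, mapq=30), evidence("r2", "chrA", 500_000)]
        assert len(call_ectopic_loci(ev30, SIZES, self.good_mappability())) == 1

    def test_near_end_dropped(self):
        for pos in (99_000, 9_950_000):  # within 100 kb of either end
            ev = [evidence("r1", "chrA", pos), evidence("r2", "chrA", pos)]
            assert call_ectopic_loci(ev, SIZES, self.good_mappability()) == []

    def test_poorly_mapped_locus_discounted(self):
        ev = [evidence("r1", "chrA", 500_000), evidence("r2", "chrA", 500_000)]
        bad = ListMappability(coverage("chrA", 500_000, [5] * 4 + [60] * 6))
        assert call_ectopic_loci(ev, SIZES, bad) == []

    def test_order_invariance(self, rng):
        ev = [
            evidence(f"r{i}", "chrA", 500_000 + int(rng.integers(0, 90)))
            for i in range(6)
        ] + [evidence(f"q{i}", "chrB", 3_000_000 + i * 30) for i in range(3)]
        m = ListMappability(
            coverage("chrA", 500_040, [60] * 10) + coverage("chrB", 3_000_030, [60] * 10)
        )
        a = call_ectopic_loci(list(ev), SIZES, m)
        shuffled = list(ev)
        rng.shuffle(shuffled)
        b = call_ectopic_loci(shuffled, SIZES, m)
        assert [(l.chrom, l.position, l.support) for l in a] == [
            (l.chrom, l.position, l.support) for l in b
        ]

    def test_gene_annotation(self):
        ev = [evidence("r1", "chrA", 500_000), evidence("r2", "chrA", 500_000)]
        loci = call_ectopic_loci(ev, SIZES, self.good_mappability())
        genes = GenomeIntervals.from_tuples(
            [
                ("chrA", 400_000, 600_000, "GENE1"),
                ("chrA", 499_000, 501_000, "GENE2"),
                ("chrA", 700_000, 800_000, "GENE3"),
            ]
        )
        annotated = annotate_loci_genes(loci, genes)
        assert annotated[0].genes == ("GENE1", "GENE2")


class TestPlantedTruth:
    def run_caller(self, alignments, genome):
        evidence_list = []
        for aln in alignments:
            evidence_list.extend(classify_clip(aln))
        return call_ectopic_loci(
            evidence_list, genome.chrom_sizes, ListMappability(alignments)
        )

    def test_planted_loci_recovered_exactly(self):
        genome = SimGenome.default()
        alignments, truth = simulate_long_reads(genome, n_loci=20, seed=5)
        loci = self.run_caller(alignments, genome)
        called = {(l.chrom, l.position) for l in loci}
        planted = set()
        for r in truth["planted"].itertuples():
            # supporting reads jitter by <=40 bp around the planted position
            match = [c for c in called if c[0] == r.chrom and abs(c[1] - r.position) <= 50]
            assert len(match) == 1, f"planted locus {r} not recovered uniquely"
            planted.add(match[0])
        assert called == planted  # precision: nothing beyond the planted loci
        decoys = {(r.chrom, r.position) for r in truth["decoys"].itertuples()}
        assert all(
            min((abs(c[1] - p[1]) for p in decoys if p[0] == c[0]), default=10**9) > 200
            for c in called
        )

    def test_each_decoy_rejected_for_its_reason(self, motifs):
        genome = SimGenome.default()
        alignments, truth = simulate_long_reads(genome, n_loci=2, seed=6)
        decoys = truth["decoys"].set_index("kind")
        by_locus = {}
        for aln in alignments:
            for ev in classify_clip(aln, motifs):
                by_locus.setdefault((ev.chrom, ev.position // 1000), []).append(ev)

        def evidence_near(kind):
            chrom, pos = decoys.loc[kind, "chrom"], decoys.loc[kind, "position"]
            return [
                ev
                for evs in by_locus.values()
                for ev in evs
                if ev.chrom == chrom and abs(ev.position - pos) <= 100
            ]

        # aligned-tract and short-clip decoys never yield clip evidence
        assert evidence_near("aligned_tract") == []
        assert evidence_near("short_clip") == []
        # low-mapq decoy yields evidence, all below the MAPQ 30 gate
        assert all(ev.mapq == 29 for ev in evidence_near("low_mapq"))
        assert len(evidence_near("low_mapq")) == 3
        # near-end decoy yields valid evidence that only the end rule removes
        near_end = evidence_near("near_end")
        assert len(near_end) == 3 and all(ev.mapq >= 30 for ev in near_end)
        # single-support decoy yields exactly one read
        assert len({ev.read_id for ev in evidence_near("single_support")}) == 1
        # poorly-mapped decoy fails the locus mappability filter
        chrom, pos = decoys.loc["poorly_mapped", "chrom"], decoys.loc["poorly_mapped", "position"]
        assert not locus_mappability_filter(chrom, pos, ListMappability(alignments))

    def test_threshold_sharpness(self):
        """Lowering one planted read's window count, MAPQ, or distance to
        the chromosome end removes exactly the expected call."""
        m = ListMappability(coverage("chrA", 500_000, [60] * 10))
        base = [evidence("r1", "chrA", 500_000), evidence("r2", "chrA", 500_000)]
        assert len(call_ectopic_loci(base, SIZES, m)) == 1
        # mapq 29 on one read -> support drops below 2
        weakened = [base[0], base[1]._replace(mapq=29)]
        assert call_ectopic_loci(weakened, SIZES, m) == []
        # position 99,999 bp from the end -> both reads excluded
        near = [e._replace(position=99_999) for e in base]
        m2 = ListMappability(coverage("chrA", 99_999, [60] * 10))
        assert call_ectopic_loci(near, SIZES, m2) == []
        # window count below 45 would never become evidence at all
        assert scan_telomere_window(CANONICAL_G * 44 + "A" * 36) is None
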