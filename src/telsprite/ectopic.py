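"""Calling ectopic telomere repeats from long-read alignments.

ALT-positive genomes carry structural variants in which tracts of telomere
repeats sit at interstitial chromosomal positions (neotelomeres or more
complex rearrangements). In a long-read alignment such a tract appears as
soft-clipped sequence: the aligner anchors the unique flank and clips the
repeat tract. The caller scans each soft-clipped segment for a 300-bp window
that starts at a canonical repeat and holds at least 45 total repeats,
anchors the insertion at the alignment start (left clip) or end (right
clip), and then applies a filter chain: read MAPQ >= 30, insertion more than
100 kb from either chromosome end, locus not in a poorly-mapped region (at
least 40% of overlapping reads in the unfiltered alignment set with
MAPQ < 10 discounts the locus), single-linkage merging of insertions within
100 bp, and at least two distinct supporting reads per locus.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Protocol

import numpy as np
import pysam

from .intervals import GenomeIntervals
from .repeatfilter import RepeatMotifSet, count_repeats

__all__ = [
    "LongReadAlignment",
    "WindowHit",
    "ClipTelomereEvidence",
    "EctopicLocus",
    "scan_telomere_window",
    "classify_clip",
    "locus_mappability_filter",
    "call_ectopic_loci",
    "annotate_loci_genes",
    "find_ectopic_loci",
    "write_loci_bed",
    "ListMappability",
    "BamMappability",
]

WINDOW_SIZE = 300
MIN_WINDOW_REPEATS = 45


@dataclass(frozen=True)
class LongReadAlignment:
    """A long-read alignment with its clip geometry and stored sequence.

    ``sequence`` is the full read in reference orientation (as stored in the
    alignment record); ``start``/``end`` are the 0-based half-open reference
    span of the aligned segment.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    mapq: int
    left_clip: int
    right_clip: int
    sequence: Optional[str]
    is_supplementary: bool = False

    @classmethod
    def from_pysam(cls, aln: "pysam.AlignedSegment") -> "LongReadAlignment":
        cig = aln.cigartuples or []
        left = cig[0][1] if cig and cig[0][0] == pysam.CSOFT_CLIP else 0
        right = cig[-1][1] if cig and cig[-1][0] == pysam.CSOFT_CLIP else 0
        return cls(
            read_id=aln.query_name,
            chrom=aln.reference_name,
            start=aln.reference_start,
            end=aln.reference_end,
            mapq=aln.mapping_quality,
            left_clip=left,
            right_clip=right,
            sequence=aln.query_sequence,
            is_supplementary=aln.is_supplementary,
        )


class WindowHit(NamedTuple):
    offset: int  # window start within the scanned sequence
    count: int  # total repeats (canonical + variant) in the window
    strand: str  # strand of the richer tiling within the window


class ClipTelomereEvidence(NamedTuple):
    read_id: str
    chrom: str
    position: int  # insertion position on the reference
    side: str  # "left" or "right"
    orientation: str  # "standard" or "inverted"
    window_count: int
    mapq: int


@dataclass(frozen=True)
class EctopicLocus:
    chrom: str
    position: int  # representative (median member) position
    members: tuple[ClipTelomereEvidence, ...]
    genes: tuple[str, ...] = ()

    @property
    def support(self) -> int:
        return len({m.read_id for m in self.members})

    @property
    def side_tally(self) -> Counter:
        return Counter(m.side for m in self.members)

    @property
    def orientation_tally(self) -> Counter:
        return Counter(m.orientation for m in self.members)


def scan_telomere_window(
    seq: str,
    motifs: Optional[RepeatMotifSet] = None,
    window: int = WINDOW_SIZE,
    min_repeats: int = MIN_WINDOW_REPEATS,
) -> Optional[WindowHit]:
    """Best telomere-repeat window in ``seq``, or None.

    Windows of ``window`` bp are anchored at every canonical-repeat match
    (either strand) that leaves a full window inside the sequence; repeats in
    a window are counted with the strand-unmixed greedy tiling. The window
    with the maximal total count is returned if that count reaches
    ``min_repeats``. Sequences shorter than ``window`` are ineligible.
    """
    if motifs is None:
        motifs = RepeatMotifSet.default()
    seq = seq.upper()
    if len(seq) < window:
        return None
    best: Optional[WindowHit] = None
    canonicals = (motifs.canonical_g, motifs.canonical_c)
    for i in range(len(seq) - window + 1):
        if seq[i : i + 6] not in canonicals:
            continue
        count = count_repeats(seq[i : i + window], motifs)
        if best is None or count.total > best.count:
            best = WindowHit(i, count.total, count.strand)
    if best is not None and best.count >= min_repeats:
        return best
    return None


def classify_clip(
    aln: LongReadAlignment, motifs: Optional[RepeatMotifSet] = None
) -> list[ClipTelomereEvidence]:
    """Telomere evidence from the soft-clipped segments of one alignment.

    Each clip is scanned independently; evidence is emitted only when a
    passing window lies entirely within the clipped segment — telomere
    sequence inside the aligned portion is present in the reference and is
    ignored. Orientation is "standard" when the G-strand motif runs away
    from the aligned segment (TTAGGG tiling on a right clip, CCCTAA on a
    left clip) and "inverted" otherwise. The insertion position is the
    alignment start for a left clip and the alignment end for a right clip.
    """
    if aln.left_clip < WINDOW_SIZE and aln.right_clip < WINDOW_SIZE:
        return []
    if aln.sequence is None:
        warnings.warn(
            f"alignment {aln.read_id} has no stored sequence (hard-clipped?); skipped"
        )
        return []
    evidence = []
    if aln.left_clip >= WINDOW_SIZE:
        hit = scan_telomere_window(aln.sequence[: aln.left_clip], motifs)
        if hit is not None:
            orientation = "standard" if hit.strand == "C" else "inverted"
            evidence.append(
                ClipTelomereEvidence(
                    aln.read_id, aln.chrom, aln.start, "left", orientation,
                    hit.count, aln.mapq,
                )
            )
    if aln.right_clip >= WINDOW_SIZE:
        hit = scan_telomere_window(aln.sequence[len(aln.sequence) - aln.right_clip :], motifs)
        if hit is not None:
            orientation = "standard" if hit.strand == "G" else "inverted"
            evidence.append(
                ClipTelomereEvidence(
                    aln.read_id, aln.chrom, aln.end, "right", orientation,
                    hit.count, aln.mapq,
                )
            )
    return evidence


class Mappability(Protocol):
    def overlapping_mapqs(self, chrom: str, position: int) -> list[int]: ...


@dataclass
class ListMappability:
    """Mappability lookup over an in-memory unfiltered alignment list."""

    alignments: list[LongReadAlignment]

    def overlapping_mapqs(self, chrom: str, position: int) -> list[int]:
        return [
            a.mapq
            for a in self.alignments
            if a.chrom == chrom and a.start <= position < a.end
        ]


class BamMappability:
    """Mappability lookup backed by a coordinate-sorted indexed BAM."""

    def __init__(self, path):
        self._bam = pysam.AlignmentFile(str(path))

    def overlapping_mapqs(self, chrom: str, position: int) -> list[int]:
        return [
            a.mapping_quality
            for a in self._bam.fetch(chrom, position, position + 1)
            if not a.is_secondary
        ]

    def close(self):
        self._bam.close()


def locus_mappability_filter(
    chrom: str,
    position: int,
    mappability: Mappability,
    max_low_mapq_fraction: float = 0.40,
    low_mapq: int = 10,
) -> bool:
    """True iff the locus passes: fewer than 40% of the reads overlapping it
    in the unfiltered alignment set have MAPQ < 10. The 40% boundary is
    inclusive (exactly 40% fails); a locus with no overlapping reads is
    undeterminable and fails."""
    mapqs = mappability.overlapping_mapqs(chrom, position)
    if not mapqs:
        return False
    frac = sum(1 for q in mapqs if q < low_mapq) / len(mapqs)
    return frac < max_low_mapq_fraction


def call_ectopic_loci(
    evidence: Iterable[ClipTelomereEvidence],
    chrom_sizes: dict[str, int],
    mappability: Mappability,
    min_mapq: int = 30,
    end_exclusion: int = 100_000,
    merge_gap: int = 100,
    min_support: int = 2,
) -> list[EctopicLocus]:
    """Merge clip evidence into supported ectopic-repeat loci.

    Evidence with MAPQ < ``min_mapq`` or with an insertion position within
    ``end_exclusion`` bp of either chromosome end is dropped. Remaining
    evidence is chained by single linkage (adjacent positions <=
    ``merge_gap`` apart merge); each chain's representative position is the
    median member position; chains failing the mappability filter at the
    representative position or supported by fewer than ``min_support``
    distinct reads are discarded. Output is sorted and order-independent of
    the input.
    """
    kept = []
    for ev in evidence:
        if ev.mapq < min_mapq:
            continue
        size = chrom_sizes.get(ev.chrom)
        if size is None:
            warnings.warn(f"evidence on unknown chromosome {ev.chrom!r} ignored")
            continue
        if ev.position < end_exclusion or ev.position > size - end_exclusion:
            continue
        kept.append(ev)
    kept.sort(key=lambda e: (e.chrom, e.position, e.read_id, e.side))

    loci = []
    group: list[ClipTelomereEvidence] = []
    for ev in kept:
        if group and (ev.chrom != group[-1].chrom or ev.position - group[-1].position > merge_gap):
            loci.extend(_finalize_group(group, mappability, min_support))
            group = []
        group.append(ev)
    loci.extend(_finalize_group(group, mappability, min_support))
    loci.sort(key=lambda l: (l.chrom, l.position))
    return loci


def _finalize_group(
    group: list[ClipTelomereEvidence], mappability: Mappability, min_support: int
) -> list[EctopicLocus]:
    if not group:
        return []
    position = int(np.median([e.position for e in group]))
    locus = EctopicLocus(group[0].chrom, position, tuple(group))
    if locus.support < min_support:
        return []
    if not locus_mappability_filter(locus.chrom, position, mappability):
        return []
    return [locus]


def annotate_loci_genes(
    loci: Iterable[EctopicLocus], genes: GenomeIntervals
) -> list[EctopicLocus]:
    """Label each locus with every gene whose transcriptional window contains
    the representative position."""
    return [
        replace(l, genes=tuple(genes.names_containing(l.chrom, l.position)))
        for l in loci
    ]


def find_ectopic_loci(
    bam_path,
    chrom_sizes: dict[str, int],
    motifs: Optional[RepeatMotifSet] = None,
    genes: Optional[GenomeIntervals] = None,
    min_mapq: int = 30,
    end_exclusion: int = 100_000,
    merge_gap: int = 100,
    min_support: int = 2,
) -> list[EctopicLocus]:
    """Full caller over a coordinate-sorted indexed BAM."""
    evidence = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary:
                continue
            aln = LongReadAlignment.from_pysam(rec)
            evidence.extend(classify_clip(aln, motifs))
    mappability = BamMappability(bam_path)
    try:
        loci = call_ectopic_loci(
            evidence, chrom_sizes, mappability, min_mapq, end_exclusion,
            merge_gap, min_support,
        )
    finally:
        mappability.close()
    if genes is not None:
        loci = annotate_loci_genes(loci, genes)
    return loci


def write_loci_bed(path, loci: Iterable[EctopicLocus]) -> None:
    """BED6+ output: name=locus id, score=distinct-read support, extra
    columns tally clip sides, repeat orientations and gene labels."""
    with open(path, "w") as fh:
        for k, l in enumerate(loci, 1):
            sides = ",".join(f"{s}:{n}" for s, n in sorted(l.side_tally.items()))
            orients = ",".join(
                f"{o}:{n}" for o, n in sorted(l.orientation_tally.items())
            )
            genes = ",".join(l.genes) if l.genes else "."
            fh.write(
                f"{l.chrom}\t{l.position}\t{l.position + 1}\tectopic_{k}\t"
                f"{l.support}\t.\t{sides}\t{orients}\t{genes}\n"
            )
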