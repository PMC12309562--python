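"""SPRITE cluster construction and the cluster-file dialect.

A SPRITE cluster is the set of sequenced fragments sharing one split-pool
barcode; fragments in a cluster were spatially proximal in the nucleus.
Telomeric reads (which cannot be aligned uniquely) are assigned to the
artificial single-base locus ``chrT`` so that all telomere fragments fall in
one bin of the contact matrix at any resolution. Repeat masking and PCR
deduplication deliberately exempt chrT members: every chrT read has the same
coordinate by construction, so coordinate-identity rules would collapse them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import pysam

from .intervals import GenomeIntervals
from .repeatfilter import (
    DEFAULT_BARCODE_DELIMITER,
    FastqRecord,
    barcode_of,
)

__all__ = [
    "CHRT",
    "MappedRead",
    "SpriteCluster",
    "assign_chrT",
    "apply_mask",
    "build_clusters",
    "read_cluster_file",
    "write_cluster_file",
    "read_mapped_bam",
]

CHRT = "chrT"


class MappedRead(NamedTuple):
    barcode: str
    chrom: str
    start: int
    end: int
    mapq: int = 60
    strand: str = "."

    @property
    def is_chrT(self) -> bool:
        return self.chrom == CHRT


def chrT_read(barcode: str, mapq: int = 60) -> MappedRead:
    return MappedRead(barcode, CHRT, 0, 1, mapq, ".")


@dataclass(frozen=True)
class SpriteCluster:
    """Barcode-grouped set of mapped reads, member order canonicalized."""

    barcode: str
    members: tuple[MappedRead, ...]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def has_chrT(self) -> bool:
        return any(m.is_chrT for m in self.members)

    @property
    def n_chrT(self) -> int:
        return sum(1 for m in self.members if m.is_chrT)


def assign_chrT(
    records: Iterable[FastqRecord],
    barcode_delimiter: str = DEFAULT_BARCODE_DELIMITER,
    mapq: int = 60,
) -> list[MappedRead]:
    """Turn telomeric FASTQ records into chrT reads at the fixed [0, 1) locus."""
    out = []
    for rec in records:
        bc = barcode_of(rec.name, barcode_delimiter)
        if bc is None:
            raise ValueError(f"telomeric read {rec.name!r} lacks a barcode token")
        out.append(chrT_read(bc, mapq))
    return out


def apply_mask(reads: Iterable[MappedRead], mask: GenomeIntervals) -> list[MappedRead]:
    """Remove genomic reads overlapping the repeat mask by >=1 bp.

    chrT reads are always retained: masking of repetitive elements must not
    touch the artificial telomere locus.
    """
    return [
        r
        for r in reads
        if r.is_chrT or not mask.overlaps(r.chrom, r.start, r.end)
    ]


def build_clusters(
    reads: Iterable[MappedRead],
    min_size: int = 1,
    deduplicate: bool = True,
) -> tuple[list[SpriteCluster], dict]:
    """Group reads by barcode into canonically sorted clusters.

    Within a barcode, genomic reads with identical (chrom, start) are treated
    as PCR duplicates and collapsed to one member; chrT members are exempt
    (they all share the same coordinate by construction). Clusters below
    ``min_size`` are retained but flagged in the stats. Returns
    (clusters, stats) where stats counts duplicates removed and small
    clusters.
    """
    by_barcode: dict[str, list[MappedRead]] = {}
    for r in reads:
        by_barcode.setdefault(r.barcode, []).append(r)

    clusters = []
    n_dups = 0
    n_small = 0
    for barcode in sorted(by_barcode):
        members = by_barcode[barcode]
        if deduplicate:
            seen: set[tuple[str, int]] = set()
            kept = []
            for m in members:
                if m.is_chrT:
                    kept.append(m)
                    continue
                key = (m.chrom, m.start)
                if key in seen:
                    n_dups += 1
                else:
                    seen.add(key)
                    kept.append(m)
            members = kept
        members = sorted(members, key=lambda m: (m.chrom, m.start))
        if len(members) < min_size:
            n_small += 1
        clusters.append(SpriteCluster(barcode, tuple(members)))
    return clusters, {"duplicates_removed": n_dups, "below_min_size": n_small}


_MEMBER_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def write_cluster_file(path, clusters: Iterable[SpriteCluster]) -> None:
    """Write the tab-delimited cluster dialect.

    Line format: ``barcode<TAB>chrom:start-end<TAB>...`` with members sorted
    by (chrom, start); chrT members serialize as ``chrT:0-1``. Round trips
    are byte-exact.
    """
    with open(path, "w") as fh:
        for c in clusters:
            fields = [c.barcode] + [f"{m.chrom}:{m.start}-{m.end}" for m in c.members]
            fh.write("\t".join(fields) + "\n")


def read_cluster_file(path) -> list[SpriteCluster]:
    clusters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: cluster line has no members")
            barcode = fields[0]
            members = []
            for tok in fields[1:]:
                m = _MEMBER_RE.match(tok)
                if m is None:
                    raise ValueError(f"{path}:{lineno}: malformed member {tok!r}")
                members.append(
                    MappedRead(
                        barcode, m["chrom"], int(m["start"]), int(m["end"])
                    )
                )
            clusters.append(SpriteCluster(barcode, tuple(members)))
    return clusters


def read_mapped_bam(
    path,
    barcode_delimiter: str = DEFAULT_BARCODE_DELIMITER,
    min_mapq: int = 0,
) -> list[MappedRead]:
    """Read mapped genomic reads from SAM/BAM, parsing the barcode from the
    read name suffix. Unmapped/secondary/supplementary records are skipped."""
    reads = []
    n_no_barcode = 0
    with pysam.AlignmentFile(str(path), require_index=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            bc = barcode_of(aln.query_name, barcode_delimiter)
            if bc is None:
                n_no_barcode += 1
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append(
                MappedRead(
                    bc,
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    aln.mapping_quality,
                    strand,
                )
            )
    if n_no_barcode:
        warnings.warn(f"skipped {n_no_barcode} mapped reads without a barcode token")
    return reads
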