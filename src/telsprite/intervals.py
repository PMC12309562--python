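"""Genomic interval utilities shared across the pipeline.

All coordinates are 0-based half-open, BED-native. 1-based formats must be
converted at the boundary before reaching these helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeIntervals",
    "read_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a UCSC two-column chrom.sizes file into an ordered mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with columns chrom, start, end[, name]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


@dataclass
class GenomeIntervals:
    """Per-chromosome sorted, merged half-open intervals.

    Used for repeat masks, centromere annotations, gene windows and any other
    BED-style interval set. ``names`` retains the original (unmerged) records
    for operations that need per-interval identity (gene annotation).
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    # original records: chrom -> list of (start, end, name)
    records: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenomeIntervals":
        obj = cls()
        for chrom, grp in df.groupby("chrom", sort=True):
            ivals = sorted(zip(grp["start"], grp["end"]))
            merged: list[list[int]] = []
            for s, e in ivals:
                if e <= s:
                    raise ValueError(f"empty/negative interval {chrom}:{s}-{e}")
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            obj.intervals[str(chrom)] = np.asarray(merged, dtype=np.int64)
            names = grp["name"] if "name" in grp else [""] * len(grp)
            obj.records[str(chrom)] = [
                (int(s), int(e), str(n))
                for s, e, n in zip(grp["start"], grp["end"], names)
            ]
        return obj

    @classmethod
    def from_bed(cls, path) -> "GenomeIntervals":
        return cls.from_dataframe(read_bed(path))

    @classmethod
    def from_tuples(cls, tuples) -> "GenomeIntervals":
        """Build from an iterable of (chrom, start, end[, name])."""
        rows = [(t[0], t[1], t[2], t[3] if len(t) > 3 else "") for t in tuples]
        return cls.from_dataframe(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        )

    def chroms(self):
        return list(self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval on ``chrom`` by >=1 bp."""
        arr = self.intervals.get(chrom)
        if arr is None or arr.size == 0:
            return False
        # first interval whose end is > start
        idx = np.searchsorted(arr[:, 1], start, side="right")
        return idx < len(arr) and arr[idx, 0] < end

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        """Number of original records overlapping [start, end)."""
        recs = self.records.get(chrom)
        if not recs:
            return 0
        return sum(1 for s, e, _ in recs if s < end and e > start)

    def names_containing(self, chrom: str, pos: int) -> list[str]:
        """Names of original records whose interval contains ``pos``."""
        recs = self.records.get(chrom)
        if not recs:
            return []
        return [n for s, e, n in recs if s <= pos < e]

    def restrict_to(self, chroms) -> "GenomeIntervals":
        """Drop intervals on chromosomes not in ``chroms`` (with a warning)."""
        known = set(chroms)
        unknown = [c for c in self.intervals if c not in known]
        if unknown:
            warnings.warn(
                f"ignoring intervals on unknown chromosome(s): {', '.join(sorted(unknown))}"
            )
        out = GenomeIntervals()
        out.intervals = {c: v for c, v in self.intervals.items() if c in known}
        out.records = {c: v for c, v in self.records.items() if c in known}
        return out
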