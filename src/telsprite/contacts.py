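"""2/N-downweighted SPRITE contact matrices and the telomere contact track.

Each cluster of size N contributes weight 2/N to every unordered pair of its
members' bins, so one cluster adds total mass C(N,2) * 2/N = N - 1 to the
matrix regardless of its size; large clusters are not allowed to dominate.
The artificial chrT bin is appended after all genomic bins, and the chrT row
of the matrix is the genome-wide telomere contact track.

Same-bin (diagonal) pairs are recorded so that mass is conserved exactly and
so that chrT-chrT telomere-clustering mass is not lost; the telomere track
excludes the chrT-chrT entry and reports it separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .clusters import CHRT, SpriteCluster
from .intervals import read_chrom_sizes

__all__ = [
    "GenomeBinning",
    "ContactMatrix",
    "cluster_weight",
    "build_matrix",
    "telomere_track",
    "aggregate_matrix",
    "cluster_profile",
    "write_matrix",
    "read_matrix",
    "write_bedgraph",
    "read_bedgraph",
]


class GenomeBinning:
    """Fixed-resolution tiling of a genome plus one appended chrT bin.

    Bins are half-open and tile each chromosome in order; the last bin of a
    chromosome is truncated to the chromosome length. Global bin indices are
    contiguous with chrT always the final index.
    """

    def __init__(self, chrom_sizes: dict[str, int], resolution: int = 1_000_000):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.chrom_sizes = dict(chrom_sizes)
        self.resolution = int(resolution)
        self._offsets: dict[str, int] = {}
        rows = []
        index = 0
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive size")
            self._offsets[chrom] = index
            n = -(-size // resolution)  # ceil
            for b in range(n):
                start = b * resolution
                rows.append((chrom, start, min(start + resolution, size), index))
                index += 1
        self.chrT_index = index
        rows.append((CHRT, 0, 1, index))
        self.bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "index"])
        self.n_bins = index + 1

    @property
    def n_genomic_bins(self) -> int:
        return self.n_bins - 1

    @classmethod
    def from_file(cls, path, resolution: int = 1_000_000) -> "GenomeBinning":
        return cls(read_chrom_sizes(path), resolution)

    def n_chrom_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        """Global [start, stop) index range of a chromosome's bins."""
        off = self._offsets[chrom]
        return off, off + self.n_chrom_bins(chrom)

    def bin_index(self, chrom: str, pos: int) -> int:
        if chrom == CHRT:
            return self.chrT_index
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < size:
            raise ValueError(f"position {chrom}:{pos} beyond chromosome end ({size})")
        return self._offsets[chrom] + pos // self.resolution

    def __eq__(self, other):
        return (
            isinstance(other, GenomeBinning)
            and self.chrom_sizes == other.chrom_sizes
            and self.resolution == other.resolution
        )


def cluster_weight(n: int) -> float:
    """2/N pair weight; clusters of size < 2 have no pairs and contribute 0."""
    return 2.0 / n if n >= 2 else 0.0


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact matrix over global bin indices.

    ``upper`` stores each unordered bin pair once (i <= j); the symmetric
    view is materialized on demand so that W == W.T holds exactly.
    """

    binning: GenomeBinning
    upper: sp.csr_matrix
    metadata: dict = field(default_factory=dict)

    @property
    def weights(self) -> sp.csr_matrix:
        diag = sp.diags(self.upper.diagonal())
        return (self.upper + self.upper.T - diag).tocsr()

    def dense(self) -> np.ndarray:
        return self.weights.toarray()

    @property
    def total_mass(self) -> float:
        """Total matrix mass with each unordered pair counted once."""
        return float(self.upper.sum())


def _member_bins(cluster: SpriteCluster, binning: GenomeBinning) -> np.ndarray:
    return np.fromiter(
        (binning.bin_index(m.chrom, m.start) for m in cluster.members),
        dtype=np.int64,
        count=cluster.size,
    )


def build_matrix(
    clusters: Iterable[SpriteCluster],
    binning: GenomeBinning,
    min_size: int = 2,
    max_size: Optional[int] = None,
) -> ContactMatrix:
    """Accumulate 2/N-weighted pair counts over all clusters within the size
    bounds. Members sharing a bin contribute to the diagonal."""
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    n_used = 0
    for cluster in clusters:
        n = cluster.size
        if n < max(min_size, 2) or (max_size is not None and n > max_size):
            continue
        n_used += 1
        w = cluster_weight(n)
        bins, counts = np.unique(_member_bins(cluster, binning), return_counts=True)
        k = len(bins)
        iu, ju = np.triu_indices(k)
        pair_counts = counts[iu].astype(np.float64) * counts[ju]
        # same-bin pairs: C(c, 2) unordered pairs, not c^2
        same = iu == ju
        pair_counts[same] = counts[iu[same]] * (counts[iu[same]] - 1) / 2.0
        keep = pair_counts > 0
        rows.append(bins[iu[keep]])
        cols.append(bins[ju[keep]])
        vals.append(pair_counts[keep] * w)
    if rows:
        i = np.concatenate(rows)
        j = np.concatenate(cols)
        v = np.concatenate(vals)
    else:
        i = j = np.empty(0, dtype=np.int64)
        v = np.empty(0, dtype=np.float64)
    upper = sp.coo_matrix((v, (i, j)), shape=(binning.n_bins, binning.n_bins)).tocsr()
    upper.sum_duplicates()
    return ContactMatrix(
        binning,
        upper,
        {"min_size": min_size, "max_size": max_size, "n_clusters": n_used},
    )


def telomere_track(matrix: ContactMatrix) -> tuple[np.ndarray, float]:
    """Extract the chrT row as a per-genomic-bin contact frequency vector.

    Returns (track, chrT_self) where the chrT-chrT diagonal mass is reported
    separately rather than as part of the genome-facing track.
    """
    t = matrix.binning.chrT_index
    row = matrix.weights[t].toarray().ravel()
    return row[:t].copy(), float(row[t])


def aggregate_matrix(matrix: ContactMatrix, coarse: GenomeBinning) -> ContactMatrix:
    """Re-bin a fine-resolution matrix onto a coarser binning of the same
    genome. The coarse resolution must be a multiple of the fine one."""
    fine = matrix.binning
    if fine.chrom_sizes != coarse.chrom_sizes:
        raise ValueError("binnings cover different genomes")
    if coarse.resolution % fine.resolution:
        raise ValueError("coarse resolution must be a multiple of the fine resolution")
    mapping = np.empty(fine.n_bins, dtype=np.int64)
    for chrom, start, _end, idx in fine.bins.itertuples(index=False):
        mapping[idx] = (
            coarse.chrT_index if chrom == CHRT else coarse.bin_index(chrom, start)
        )
    proj = sp.coo_matrix(
        (np.ones(fine.n_bins), (np.arange(fine.n_bins), mapping)),
        shape=(fine.n_bins, coarse.n_bins),
    ).tocsr()
    # the mapping is order-preserving, so rebinned upper stays upper and
    # each unordered pair remains counted exactly once
    upper = (proj.T @ matrix.upper @ proj).tocsr()
    return ContactMatrix(coarse, upper, dict(matrix.metadata))


def cluster_profile(
    clusters: Iterable[SpriteCluster],
    region: tuple[str, int, int],
    fine_resolution: int,
    max_cluster_size: Optional[int] = None,
    require_chrT: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Per-cluster binary occupancy rows over fine bins of a region.

    This is the data behind cluster plots: each retained cluster becomes one
    row; a cell is True iff the cluster has a member starting in that fine
    bin. Returns (occupancy, barcodes); an empty selection yields a (0, nbin)
    array, not an error.
    """
    chrom, start, end = region
    if end <= start or fine_resolution <= 0:
        raise ValueError("invalid region or resolution")
    n_cols = -(-(end - start) // fine_resolution)
    rows = []
    barcodes = []
    for c in clusters:
        if max_cluster_size is not None and c.size > max_cluster_size:
            continue
        if require_chrT and not c.has_chrT:
            continue
        hits = [
            (m.start - start) // fine_resolution
            for m in c.members
            if m.chrom == chrom and start <= m.start < end
        ]
        if not hits:
            continue
        row = np.zeros(n_cols, dtype=bool)
        row[hits] = True
        rows.append(row)
        barcodes.append(c.barcode)
    occupancy = np.array(rows, dtype=bool) if rows else np.zeros((0, n_cols), dtype=bool)
    return occupancy, barcodes


def write_matrix(matrix: ContactMatrix, prefix) -> tuple[str, str]:
    """Write triplet text (``bin_i<TAB>bin_j<TAB>weight``, upper triangle) and
    the bin table. Returns the two paths written."""
    prefix = str(prefix)
    triplets = prefix + ".triplets.tsv"
    bins = prefix + ".bins.tsv"
    coo = sp.triu(matrix.upper).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(triplets, "w") as fh:
        fh.write(f"# resolution={matrix.binning.resolution}\n")
        for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
    matrix.binning.bins.to_csv(bins, sep="\t", index=False)
    return triplets, bins


def read_matrix(prefix) -> ContactMatrix:
    prefix = str(prefix)
    bins = pd.read_csv(prefix + ".bins.tsv", sep="\t")
    resolution = None
    i, j, v = [], [], []
    with open(prefix + ".triplets.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                if "resolution=" in line:
                    resolution = int(line.split("resolution=")[1])
                continue
            a, b, w = line.split("\t")
            i.append(int(a))
            j.append(int(b))
            v.append(float(w))
    if resolution is None:
        raise ValueError("triplet file lacks a resolution header")
    sizes = {
        str(chrom): int(grp["end"].max())
        for chrom, grp in bins[bins["chrom"] != CHRT].groupby("chrom", sort=False)
    }
    binning = GenomeBinning(sizes, resolution)
    upper = sp.coo_matrix(
        (v, (i, j)), shape=(binning.n_bins, binning.n_bins)
    ).tocsr()
    return ContactMatrix(binning, upper)


def write_bedgraph(path, binning: GenomeBinning, values: np.ndarray) -> None:
    """Write per-genomic-bin values as BEDGRAPH; NaN bins are skipped and the
    chrT bin is never emitted."""
    values = np.asarray(values, dtype=float)
    if len(values) != binning.n_genomic_bins:
        raise ValueError("value vector does not match the genomic bin count")
    with open(path, "w") as fh:
        for chrom, start, end, idx in binning.bins.itertuples(index=False):
            if chrom == CHRT:
                continue
            v = values[idx]
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.10g}\n")


def read_bedgraph(path, binning: GenomeBinning) -> np.ndarray:
    """Read a per-bin BEDGRAPH back onto a binning; absent bins stay 0."""
    values = np.zeros(binning.n_genomic_bins, dtype=float)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, _end, v = line.split("\t")
            values[binning.bin_index(chrom, int(start))] = float(v)
    return values
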