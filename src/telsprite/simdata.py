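"""Seeded synthetic fixtures with known ground truth for every pipeline stage.

The generators emulate the statistical structure the pipeline is built to
detect, at desk scale:

* ``simulate_fastq`` — barcode-annotated reads with a planted telomeric
  fraction (tandem canonical/variant hexamer reads vs random sequence).
* ``simulate_sprite`` — SPRITE clusters whose members scatter around a
  genomic anchor with a heavy-tailed (Lomax) displacement, reproducing the
  precipitous distance decay of contact frequency; members falling in
  planted telomeric tracts (natural chromosome ends plus interstitial,
  ALT-like tracts) become chrT reads, and centromere-anchored clusters
  carry an elevated telomere co-occurrence rate.
* ``simulate_long_reads`` — long-read alignments with soft-clipped tandem
  telomere tracts planted at known loci, plus decoy classes that each
  violate exactly one caller filter.
* ``simulate_fish_image`` — nucleus fields with Gaussian telomere/centromere
  foci at a controlled adjacency fraction.

Every generator is bit-reproducible from its seed and returns a
machine-readable truth table; tests consume the truth tables, never
generator internals. The toy genome (three chromosomes, 100 Mb total) keeps
full-pipeline runs at desk scale; telomeric tract lengths are scaled up
relative to a real genome so that telomere-read fractions stay realistic on
the small genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .clusters import CHRT, MappedRead, SpriteCluster
from .ectopic import LongReadAlignment
from .repeatfilter import (
    CANONICAL_C,
    CANONICAL_G,
    DEFAULT_VARIANT_G,
    FastqRecord,
    reverse_complement,
)

__all__ = [
    "TelomericTract",
    "SimGenome",
    "SimSpriteParams",
    "simulate_fastq",
    "simulate_sprite",
    "simulate_long_reads",
    "write_long_reads_sam",
    "simulate_fish_image",
]

READ_LENGTH = 90  # genomic-DNA bases sequenced per SPRITE read


@dataclass(frozen=True)
class TelomericTract:
    chrom: str
    start: int
    end: int
    kind: str  # "natural" (chromosome end) or "interstitial"


@dataclass
class SimGenome:
    """Toy genome with planted telomeric tracts and centromeres."""

    chrom_sizes: dict[str, int]
    tracts: list[TelomericTract]
    centromeres: dict[str, tuple[int, int]]

    def __post_init__(self):
        for t in self.tracts:
            size = self.chrom_sizes[t.chrom]
            if not (0 <= t.start < t.end <= size):
                raise ValueError(f"tract {t} out of bounds for {t.chrom} ({size})")

    @classmethod
    def default(cls) -> "SimGenome":
        """Three chromosomes (60/50/40 Mb), 150 kb natural telomere tracts at
        every end, six 50 kb interstitial (ALT-like) tracts, 2-3 Mb
        centromeres near each chromosome middle.

        Interstitial tracts are planted more than 10 Mb from every
        chromosome end, so the near-end portion of the distance-decay curve
        reflects natural telomeres only (on a full-size genome the many arms
        per distance class dilute interstitial spikes; on a three-chromosome
        toy genome they would dominate a class).
        """
        sizes = {"chr1": 60_000_000, "chr2": 50_000_000, "chr3": 40_000_000}
        end_len = 150_000
        tracts = []
        for chrom, size in sizes.items():
            tracts.append(TelomericTract(chrom, 0, end_len, "natural"))
            tracts.append(TelomericTract(chrom, size - end_len, size, "natural"))
        interstitial = [
            ("chr1", 14_600_000),
            ("chr1", 35_250_000),
            ("chr2", 13_400_000),
            ("chr2", 33_100_000),
            ("chr3", 12_700_000),
            ("chr3", 24_300_000),
        ]
        for chrom, pos in interstitial:
            tracts.append(TelomericTract(chrom, pos, pos + 50_000, "interstitial"))
        # submetacentric: centromeres off-center so that the distance
        # classes of centromeric bins also contain non-centromeric peer bins
        centromeres = {
            "chr1": (19_000_000, 22_000_000),
            "chr2": (20_000_000, 22_000_000),
            "chr3": (18_000_000, 19_500_000),
        }
        return cls(sizes, tracts, centromeres)

    def tract_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.chrom, t.start, t.end, t.kind) for t in self.tracts],
            columns=["chrom", "start", "end", "kind"],
        )

    def centromere_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, s, e) for c, (s, e) in self.centromeres.items()],
            columns=["chrom", "start", "end"],
        )


@dataclass
class SimSpriteParams:
    """Study conditions for the SPRITE cluster generator.

    Member displacement from the cluster anchor is a two-scale Lomax
    mixture, P(|D| > d) = (1 + d/scale)^(-alpha) at each scale: most members
    scatter within a local crosslinking neighborhood (``decay_scale``) and a
    ``long_fraction`` of members range over compartment-scale distances
    (``long_scale``), which together reproduce a contact decay that is both
    sharply peaked at zero and still falling steadily at 10 Mb.
    ``telomere_emission`` is the probability that a member landing inside a
    planted telomeric tract is sequenced as a chrT read.
    ``background_telomere_rate`` is the per-cluster probability of carrying
    one additional chrT member regardless of position (extrachromosomal /
    unanchored telomere fragments); clusters anchored inside a centromere
    multiply that rate by ``centromere_affinity``, emulating the spatial
    clustering of telomeric and centromeric heterochromatin.
    """

    n_clusters: int = 50_000
    size_min: int = 2
    size_max: int = 300
    decay_scale: float = 75_000.0
    decay_alpha: float = 1.5
    long_fraction: float = 0.35
    long_scale: float = 2_500_000.0
    telomere_emission: float = 0.9
    background_telomere_rate: float = 0.02
    centromere_affinity: float = 6.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.size_min < 1 or self.size_max < self.size_min:
            raise ValueError("invalid cluster size bounds")
        if min(self.decay_scale, self.telomere_emission, self.centromere_affinity) < 0:
            raise ValueError("rates must be nonnegative")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# FASTQ reads with a planted telomeric fraction


def simulate_fastq(
    n_reads: int,
    telomeric_fraction: float,
    seed=None,
    read_length: int = READ_LENGTH,
    n_barcodes: int = 500,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Barcode-annotated reads, a Bernoulli(telomeric_fraction) of which are
    tandem telomere-repeat reads (canonical fraction ~0.8, floor of four
    canonicals so all planted reads pass the medium filter); the rest are
    uniform random sequence. Returns (records, truth)."""
    rng = _rng(seed)
    n_hex = read_length // 6
    bases = np.array(list("ACGT"))
    variants = list(DEFAULT_VARIANT_G)
    records = []
    truth = []
    is_tel = rng.random(n_reads) < telomeric_fraction
    for i in range(n_reads):
        barcode = f"BC{rng.integers(0, n_barcodes):05d}"
        name = f"read{i}::{barcode}"
        if is_tel[i]:
            k_can = max(4, int(rng.binomial(n_hex, 0.8)))
            motifs = [CANONICAL_G] * k_can + [
                variants[j] for j in rng.integers(0, len(variants), n_hex - k_can)
            ]
            rng.shuffle(motifs)
            seq = "".join(motifs)[:read_length]
            if rng.random() < 0.5:  # either strand is sequenced
                seq = reverse_complement(seq)
            seq = seq + "".join(rng.choice(bases, read_length - len(seq)))
        else:
            seq = "".join(rng.choice(bases, read_length))
        records.append(FastqRecord(name, seq, "I" * read_length))
        truth.append((name, bool(is_tel[i])))
    return records, pd.DataFrame(truth, columns=["name", "is_telomeric"])


# ---------------------------------------------------------------------------
# SPRITE clusters


def _reflect(pos: np.ndarray, length: int) -> np.ndarray:
    """Fold positions into [0, length) by reflection at the boundaries."""
    period = 2 * length
    pos = np.mod(pos, period)
    return np.where(pos < length, pos, period - 1 - pos).astype(np.int64)


def simulate_sprite(
    genome: Optional[SimGenome] = None,
    params: Optional[SimSpriteParams] = None,
    seed=None,
) -> tuple[list[SpriteCluster], dict]:
    """Generate SPRITE clusters with distance-decaying co-occurrence and
    telomere-derived members.

    Returns (clusters, truth) where truth holds DataFrames: ``tracts``,
    ``centromeres`` and a per-cluster table ``clusters`` (barcode, anchor
    chromosome/position, size, n_telomeric, anchor_in_centromere).
    """
    genome = genome or SimGenome.default()
    params = params or SimSpriteParams()
    rng = _rng(seed if seed is not None else params.seed)

    chroms = list(genome.chrom_sizes)
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)
    probs = lengths / lengths.sum()
    n = params.n_clusters

    sizes = np.rint(
        np.exp(rng.uniform(np.log(params.size_min), np.log(params.size_max), n))
    ).astype(np.int64)
    sizes = np.clip(sizes, params.size_min, params.size_max)
    chrom_idx = rng.choice(len(chroms), size=n, p=probs)
    anchors = (rng.random(n) * lengths[chrom_idx]).astype(np.int64)

    # per-chromosome tract lookup (sorted starts/ends) for vectorized hit tests
    tract_arrays: dict[str, np.ndarray] = {}
    for chrom in chroms:
        rows = [(t.start, t.end) for t in genome.tracts if t.chrom == chrom]
        tract_arrays[chrom] = np.array(sorted(rows), dtype=np.int64).reshape(-1, 2)

    def in_tract(chrom: str, pos: np.ndarray) -> np.ndarray:
        arr = tract_arrays[chrom]
        if arr.size == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
        idx_ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[idx_ok] = pos[idx_ok] < arr[idx[idx_ok], 1]
        return hit

    def in_centromere(chrom: str, pos: int) -> bool:
        s, e = genome.centromeres.get(chrom, (0, 0))
        return s <= pos < e

    clusters = []
    truth_rows = []
    for ci in range(n):
        chrom = chroms[chrom_idx[ci]]
        length = int(lengths[chrom_idx[ci]])
        anchor = int(anchors[ci])
        size = int(sizes[ci])
        signs = rng.choice([-1, 1], size=size)
        scales = np.where(
            rng.random(size) < params.long_fraction,
            params.long_scale,
            params.decay_scale,
        )
        magnitudes = scales * rng.pareto(params.decay_alpha, size)
        pos = _reflect(anchor + (signs * magnitudes).astype(np.int64), length)

        barcode = f"SIM{ci:06d}"
        tel_hit = in_tract(chrom, pos) & (rng.random(size) < params.telomere_emission)
        cen_anchor = in_centromere(chrom, anchor)
        rate = params.background_telomere_rate * (
            params.centromere_affinity if cen_anchor else 1.0
        )
        extra_tel = rng.random() < rate

        members = []
        for p, tel in zip(pos, tel_hit):
            if tel:
                members.append(MappedRead(barcode, CHRT, 0, 1, 60, "."))
            else:
                start = int(min(p, length - READ_LENGTH))
                members.append(
                    MappedRead(barcode, chrom, start, start + READ_LENGTH, 60, ".")
                )
        if extra_tel:
            members.append(MappedRead(barcode, CHRT, 0, 1, 60, "."))
        members.sort(key=lambda m: (m.chrom, m.start))
        clusters.append(SpriteCluster(barcode, tuple(members)))
        truth_rows.append(
            (
                barcode,
                chrom,
                anchor,
                len(members),
                int(tel_hit.sum()) + int(extra_tel),
                cen_anchor,
            )
        )

    truth = {
        "tracts": genome.tract_table(),
        "centromeres": genome.centromere_table(),
        "clusters": pd.DataFrame(
            truth_rows,
            columns=[
                "barcode",
                "anchor_chrom",
                "anchor_pos",
                "size",
                "n_telomeric",
                "anchor_in_centromere",
            ],
        ),
    }
    return clusters, truth


# ---------------------------------------------------------------------------
# Long reads with soft-clipped telomere tracts


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _tandem(motif: str, length: int) -> str:
    reps = -(-length // 6)
    return (motif * reps)[:length]


def simulate_long_reads(
    genome: Optional[SimGenome] = None,
    n_loci: int = 20,
    reads_per_locus: int = 3,
    clip_length: int = 402,
    aligned_length: int = 2_000,
    mapq: int = 60,
    coverage_per_locus: int = 10,
    seed=None,
) -> tuple[list[LongReadAlignment], dict]:
    """Plant ``n_loci`` ectopic-telomere insertion loci plus decoy classes.

    Each planted locus gets ``reads_per_locus`` supporting reads (tandem
    telomere soft clips of ``clip_length`` bp, MAPQ ``mapq``, >1 Mb from
    chromosome ends) alternating clip side and repeat orientation. Decoy
    classes each violate exactly one caller rule: single supporting read,
    MAPQ 29, insertion 99 kb from the chromosome end, telomere tract inside
    the aligned portion, clip too short for the scan window, and a locus
    whose surrounding coverage is 50% MAPQ-5 reads (poorly mapped). Every
    locus also receives ``coverage_per_locus`` plain spanning reads so the
    mappability filter is determinable.

    Returns (alignments, truth) with truth["planted"] the expected calls and
    truth["decoys"] the decoy table.
    """
    genome = genome or SimGenome.default()
    rng = _rng(seed)
    chroms = list(genome.chrom_sizes)

    def draw_positions(count: int, margin: int = 1_500_000) -> list[tuple[str, int]]:
        out = []
        taken: dict[str, list[int]] = {c: [] for c in chroms}
        while len(out) < count:
            chrom = chroms[rng.integers(0, len(chroms))]
            size = genome.chrom_sizes[chrom]
            pos = int(rng.integers(margin, size - margin))
            if all(abs(pos - p) > 50_000 for p in taken[chrom]):
                taken[chrom].append(pos)
                out.append((chrom, pos))
        return out

    alignments: list[LongReadAlignment] = []
    read_counter = 0

    def emit_read(chrom, pos, side, orientation, this_mapq, this_clip):
        nonlocal read_counter
        read_counter += 1
        rid = f"LR{read_counter:05d}"
        motif = {
            ("right", "standard"): CANONICAL_G,
            ("right", "inverted"): CANONICAL_C,
            ("left", "standard"): CANONICAL_C,
            ("left", "inverted"): CANONICAL_G,
        }[(side, orientation)]
        clip_seq = _tandem(motif, this_clip)
        aligned = _random_seq(rng, aligned_length)
        if side == "right":
            start, end = pos - aligned_length, pos
            seq = aligned + clip_seq
            left, right = 0, this_clip
        else:
            start, end = pos, pos + aligned_length
            seq = clip_seq + aligned
            left, right = this_clip, 0
        alignments.append(
            LongReadAlignment(rid, chrom, start, end, this_mapq, left, right, seq)
        )
        return rid

    def emit_coverage(chrom, pos, n_reads, low_frac=0.0):
        nonlocal read_counter
        n_low = int(round(n_reads * low_frac))
        for k in range(n_reads):
            read_counter += 1
            q = 5 if k < n_low else 60
            start = pos - 3_000 + int(rng.integers(0, 1_000))
            alignments.append(
                LongReadAlignment(
                    f"COV{read_counter:05d}", chrom, start, start + 6_000, q,
                    0, 0, None,
                )
            )

    sides = ["right", "left"]
    orientations = ["standard", "standard", "inverted"]
    planted = draw_positions(n_loci)
    for li, (chrom, pos) in enumerate(planted):
        for r in range(reads_per_locus):
            jitter = int(rng.integers(-40, 41))
            emit_read(
                chrom, pos + jitter, sides[(li + r) % 2],
                orientations[r % len(orientations)], mapq, clip_length,
            )
        emit_coverage(chrom, pos, coverage_per_locus)

    decoy_rows = []
    extra = draw_positions(4)

    chrom, pos = extra[0]  # single supporting read
    emit_read(chrom, pos, "right", "standard", mapq, clip_length)
    emit_coverage(chrom, pos, coverage_per_locus)
    decoy_rows.append(("single_support", chrom, pos))

    chrom, pos = extra[1]  # low-MAPQ supporting reads
    for r in range(reads_per_locus):
        emit_read(chrom, pos, "right", "standard", 29, clip_length)
    emit_coverage(chrom, pos, coverage_per_locus)
    decoy_rows.append(("low_mapq", chrom, pos))

    chrom = chroms[0]  # insertion within 100 kb of the chromosome end
    pos = 99_000
    for r in range(reads_per_locus):
        emit_read(chrom, pos, "left", "standard", mapq, clip_length)
    emit_coverage(chrom, pos, coverage_per_locus)
    decoy_rows.append(("near_end", chrom, pos))

    chrom, pos = extra[2]  # telomere tract inside the aligned portion
    for r in range(reads_per_locus):
        read_counter += 1
        seq = (
            _random_seq(rng, 800)
            + _tandem(CANONICAL_G, clip_length)
            + _random_seq(rng, 800)
        )
        alignments.append(
            LongReadAlignment(
                f"LR{read_counter:05d}", chrom, pos - len(seq), pos, mapq, 0, 0, seq
            )
        )
    emit_coverage(chrom, pos, coverage_per_locus)
    decoy_rows.append(("aligned_tract", chrom, pos))

    chrom, pos = extra[3]  # clip too short to hold a scan window
    for r in range(reads_per_locus):
        emit_read(chrom, pos, "right", "standard", mapq, 200)
    emit_coverage(chrom, pos, coverage_per_locus)
    decoy_rows.append(("short_clip", chrom, pos))

    chrom, pos = draw_positions(1)[0]  # poorly mapped surroundings
    for r in range(reads_per_locus):
        emit_read(chrom, pos, "right", "standard", mapq, clip_length)
    emit_coverage(chrom, pos, coverage_per_locus, low_frac=0.5)
    decoy_rows.append(("poorly_mapped", chrom, pos))

    truth = {
        "planted": pd.DataFrame(planted, columns=["chrom", "position"]).sort_values(
            ["chrom", "position"], ignore_index=True
        ),
        "decoys": pd.DataFrame(decoy_rows, columns=["kind", "chrom", "position"]),
    }
    return alignments, truth


def write_long_reads_sam(
    alignments: list[LongReadAlignment], path, chrom_sizes: dict[str, int]
) -> None:
    """Write simulated alignments as SAM/BAM (format chosen by extension)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(s)} for c, s in chrom_sizes.items()],
    }
    path = str(path)
    mode = "wb" if path.endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        tid = {c: i for i, c in enumerate(chrom_sizes)}
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.reference_id = tid[a.chrom]
            seg.reference_start = a.start
            seg.mapping_quality = a.mapq
            aligned_len = a.end - a.start
            cigar = []
            if a.left_clip:
                cigar.append((pysam.CSOFT_CLIP, a.left_clip))
            cigar.append((pysam.CMATCH, aligned_len))
            if a.right_clip:
                cigar.append((pysam.CSOFT_CLIP, a.right_clip))
            seg.cigartuples = cigar
            if a.sequence is not None:
                seg.query_sequence = a.sequence
            else:
                seg.query_sequence = "A" * (a.left_clip + aligned_len + a.right_clip)
            seg.flag = 2048 if a.is_supplementary else 0
            out.write(seg)


# ---------------------------------------------------------------------------
# FISH nucleus images


def _add_spot(img: np.ndarray, row: float, col: float, amp: float, sigma: float):
    r0, c0 = int(round(row)), int(round(col))
    rad = int(3 * sigma) + 1
    rr = np.arange(max(0, r0 - rad), min(img.shape[0], r0 + rad + 1))
    cc = np.arange(max(0, c0 - rad), min(img.shape[1], c0 + rad + 1))
    if rr.size == 0 or cc.size == 0:
        return
    d2 = (rr[:, None] - row) ** 2 + (cc[None, :] - col) ** 2
    img[np.ix_(rr, cc)] += amp * np.exp(-d2 / (2 * sigma**2))


def simulate_fish_image(
    shape: tuple[int, int] = (600, 600),
    n_nuclei: int = 4,
    tel_per_nucleus: int = 20,
    cen_per_nucleus: int = 20,
    adjacency_fraction: float = 0.0,
    seed=None,
    nucleus_radius: int = 62,
    spot_sigma: float = 1.8,
    spot_amplitude: float = 250.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """One field of disk nuclei with planted telomere/centromere foci.

    ``adjacency_fraction`` of the telomere foci are placed within 3 px of a
    randomly chosen centromere focus (guaranteeing centroid adjacency under
    the 5 px rule); the rest are uniform in the nucleus. Returns
    (dna, telomere, centromere, truth) with truth rows (nucleus_id, channel,
    row, col).
    """
    rng = _rng(seed)
    h, w = shape
    dna = np.full(shape, 10.0)
    tel = np.full(shape, 5.0)
    cen = np.full(shape, 5.0)

    # jittered grid placement keeps nuclei disjoint
    n_cols = int(np.ceil(np.sqrt(n_nuclei)))
    n_rows = int(np.ceil(n_nuclei / n_cols))
    cell_h, cell_w = h // n_rows, w // n_cols
    if min(cell_h, cell_w) < 2 * nucleus_radius + 10:
        raise ValueError("field too small for the requested nuclei")

    yy, xx = np.mgrid[0:h, 0:w]
    truth_rows = []
    # telomeres are placed (and later randomized) uniformly over the nuclear
    # area — zero margin, matching the randomization's uniform-over-mask law
    # exactly; centromeres are fixed anyway and kept off the nuclear rim so
    # their foci segment cleanly
    tel_margin, cen_margin = 0, 8
    for k in range(n_nuclei):
        gr, gc = divmod(k, n_cols)
        cy = gr * cell_h + cell_h // 2 + int(rng.integers(-5, 6))
        cx = gc * cell_w + cell_w // 2 + int(rng.integers(-5, 6))
        dna[(yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius**2] += 110.0

        def uniform_point(margin):
            r = (nucleus_radius - margin) * np.sqrt(rng.random())
            theta = rng.random() * 2 * np.pi
            return cy + r * np.sin(theta), cx + r * np.cos(theta)

        cen_points = []
        while len(cen_points) < cen_per_nucleus:
            p = uniform_point(cen_margin)
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > 12**2 for q in cen_points):
                cen_points.append(p)
        for p in cen_points:
            _add_spot(cen, p[0], p[1], spot_amplitude, spot_sigma)
            truth_rows.append((k + 1, "centromere", p[0], p[1]))

        n_adjacent = int(round(adjacency_fraction * tel_per_nucleus))
        tel_points = []
        for j in range(tel_per_nucleus):
            if j < n_adjacent:
                base = cen_points[int(rng.integers(0, len(cen_points)))]
                r = 3.0 * np.sqrt(rng.random())
                theta = rng.random() * 2 * np.pi
                p = (base[0] + r * np.sin(theta), base[1] + r * np.cos(theta))
            else:
                p = uniform_point(tel_margin)
            tel_points.append(p)
        for p in tel_points:
            _add_spot(tel, p[0], p[1], spot_amplitude, spot_sigma)
            truth_rows.append((k + 1, "telomere", p[0], p[1]))

    for img in (dna, tel, cen):
        img += rng.normal(0, 2.0, shape)
        np.clip(img, 0, None, out=img)

    truth = pd.DataFrame(truth_rows, columns=["nucleus_id", "channel", "row", "col"])
    return dna, tel, cen, truth
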