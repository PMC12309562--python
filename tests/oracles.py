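"""Independent brute-force oracles used by the test suite.

These implementations deliberately share no code with the package: repeat
counts come from a dynamic program over *all* non-overlapping tilings, and
window scans enumerate every candidate window.
"""

from __future__ import annotations


def best_tiling(seq: str, canonical: str, variants: frozenset[str]) -> tuple[int, int]:
    """(max total, max canonical among max-total) over all non-overlapping
    tilings of 6-mers from one strand's motif set."""
    n = len(seq)
    best = [(0, 0)] * (n + 1)
    for i in range(n - 1, -1, -1):
        b = best[i + 1]
        hexamer = seq[i : i + 6]
        if len(hexamer) == 6:
            if hexamer == canonical:
                cand = (best[i + 6][0] + 1, best[i + 6][1] + 1)
                b = max(b, cand)
            elif hexamer in variants:
                cand = (best[i + 6][0] + 1, best[i + 6][1])
                b = max(b, cand)
        best[i] = b
    return best[0]


def oracle_count(seq: str, motifs) -> tuple[int, int, str]:
    """(total, canonical, strand) by exhaustive tiling, strand-unmixed,
    larger total wins, tie broken toward the G strand."""
    seq = seq.upper()
    g = best_tiling(seq, motifs.canonical_g, motifs.variant_g)
    c = best_tiling(seq, motifs.canonical_c, motifs.variant_c)
    if g[0] >= c[0]:
        return g[0], g[1], "G"
    return c[0], c[1], "C"


def oracle_classify(seq: str, thresholds, motifs) -> bool:
    total, canonical, _ = oracle_count(seq, motifs)
    return (
        total >= thresholds.min_total_repeats
        and canonical >= thresholds.min_canonical_repeats
    )


def oracle_best_window(seq: str, motifs, window: int = 300) -> int:
    """Maximal repeat count over every window anchored at a canonical match,
    counting by exhaustive tiling (0 when no anchored window fits)."""
    seq = seq.upper()
    best = 0
    canonicals = (motifs.canonical_g, motifs.canonical_c)
    for i in range(max(0, len(seq) - window + 1)):
        if seq[i : i + 6] in canonicals:
            total, _can, _strand = oracle_count(seq[i : i + window], motifs)
            best = max(best, total)
    return best
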