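import numpy as np
import pytest

from telsprite.contacts import GenomeBinning
from telsprite.repeatfilter import RepeatMotifSet, StringencyThresholds


@pytest.fixture(scope="session")
def motifs():
    return RepeatMotifSet.default()


@pytest.fixture(scope="session")
def medium():
    return StringencyThresholds.preset("medium")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_binning():
    # two chromosomes, 10 Mb and 5.5 Mb (last bin truncated), 1 Mb bins
    return GenomeBinning({"chrA": 10_000_000, "chrB": 5_500_000}, 1_000_000)


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def mosaic_sequence(rng, motifs, n_motifs, spacer_max=12):
    """Telomere-motif mosaic with random spacers: motifs never overlap, so
    greedy and exhaustive tilings agree by construction on the planted part."""
    variant_pool = sorted(motifs.variant_g)
    parts = []
    for _ in range(n_motifs):
        if rng.random() < 0.6:
            parts.append(motifs.canonical_g)
        else:
            parts.append(variant_pool[rng.integers(0, len(variant_pool))])
        if spacer_max and rng.random() < 0.3:
            parts.append(random_dna(rng, int(rng.integers(1, spacer_max))))
    return "".join(parts)
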