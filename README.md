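# telsprite

Telomere contact mapping from SPRITE split-pool barcoding data, with
companion tools for calling ectopic telomere-repeat structural variants from
long reads and for scoring telomere–centromere adjacency in FISH images.

## The problem

Genome-wide 3D contact assays (Hi-C, SPRITE) discard reads that align to
repetitive sequence, so almost nothing is known about how telomeres are
arranged relative to the rest of the genome — a question of particular
interest in ALT-positive cancer cells (Alternative Lengthening of
Telomeres), whose rearranged genomes carry telomere repeats at ectopic,
interstitial sites. `telsprite` solves this one-dimensionally: instead of
mapping telomeric reads, it *recognizes* them by their repeat content and
pools them into a single artificial locus, so that telomere-versus-genome
contact frequency becomes one row of an ordinary contact matrix.

## The method

1. **Repeat filtering.** A read is telomeric when a greedy, strand-unmixed,
   non-overlapping tiling of canonical (TTAGGG / CCCTAA) and variant
   hexamers reaches preset thresholds — medium stringency requires total
   repeats ≥ 7 and canonical repeats ≥ 4 (low: 4/2, high: 14/7).
2. **chrT assignment.** Telomeric reads keep their split-pool barcode and
   are assigned to a 1-bp artificial locus `chrT`; everything else is
   aligned normally. Barcode groups form SPRITE clusters; repeat masking
   and PCR deduplication never touch chrT members.
3. **2/N contact matrix.** Each cluster of size N adds weight 2/N to every
   unordered pair of its members' bins (1 Mb default, chrT appended as the
   last bin), so a cluster contributes total mass C(N,2)·2/N = N−1. The
   chrT row is the genome-wide telomere contact track.
4. **Track analytics.** Contact frequency decays steeply with distance from
   the nearest chromosome end; the decay curve averages bins at equal
   end-distance, and *distance normalization* divides each bin by its
   distance-class mean. On the normalized track the package tests
   annotation contrasts (centromeres, ectopic loci) with Welch's t-test,
   profiles read density around H3K9me3 peaks in telomere vs non-telomere
   clusters, and correlates the track with A/B compartment eigenvectors
   (O/E Pearson matrices, PC chosen by a 1.5× gene-density rule, A side
   positive).
5. **Ectopic-repeat caller.** In long-read alignments an interstitial
   telomere tract appears as soft-clipped sequence. The caller scans each
   clip for a 300-bp window starting at a canonical repeat with ≥ 45 total
   repeats, anchors the insertion at the alignment start/end, and filters:
   MAPQ ≥ 30, > 100 kb from chromosome ends, locus mappability (< 40% of
   overlapping unfiltered reads with MAPQ < 10), 100-bp single-linkage
   merging, ≥ 2 distinct supporting reads.
6. **FISH proximity.** Nuclei (Multi-Otsu on the DNA stain) and ≥ 9-px foci
   are segmented; the score is the mean number of telomere foci within 5 px
   of a centromere focus; its percentile against 1000 uniform
   randomizations of the telomere positions within the nuclear mask is the
   reported statistic.

A seeded synthetic-data module (`telsprite.simdata`) generates clusters,
long reads and nucleus images with planted ground truth for every stage.

## Worked example

```bash
python examples/03_distance_decay_and_centromeres.py
```

simulates 50,000 SPRITE clusters on a three-chromosome toy genome with
telomeric tracts at every chromosome end, six interstitial ALT-like tracts
and a telomere–centromere affinity, then prints:

```
contact ratio vs distance from nearest chromosome end (class 1 = 1 Mb):
 distance_class    ratio  ratio_sem
              1 1.000000   0.045071
              2 0.344666   0.013353
              3 0.204679   0.007942
              ...
             10 0.049563   0.006423

centromere bins: mean normalized contact 1.25 (n=7) vs other bins 0.99 (n=143)
Welch t = 4.34, two-sided p = 3.86e-05
```

The ratio column is the decay curve: telomere contact at 10 Mb from a
chromosome end is ~5% of the terminal-bin value and falls monotonically.
After distance normalization the centromeric bins retain a 1.25× excess of
telomere contact (p < 1e-4) — the planted heterochromatin association,
which the raw track hides under the distance effect. The other examples
(`examples/01…06`) walk through read filtering, matrix conservation,
compartment selection, the ectopic caller (8/8 planted loci recovered, all
six decoy classes rejected) and the FISH randomization test.

Each stage is also a subcommand of the `telsprite` CLI (`filter`,
`clusters`, `matrix`, `teltrack`, `analyze`, `compartments`, `ectopic`,
`fish`, `simulate`); rerunning any command with the same seed and inputs
reproduces its outputs byte for byte.

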