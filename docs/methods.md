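# Methods

This note records the models, defaults and numerical choices behind
`telsprite`, and what the synthetic-data tests do and do not establish.

## Repeat counting and read classification

Telomeric reads are recognized, not aligned. A read's sequence is tiled
greedily left-to-right with non-overlapping hexamers: at each position the
canonical motif (TTAGGG on the G strand, CCCTAA on the C strand) is
preferred, then any variant motif; a match advances 6 bases, a miss 1. The
two strands are tiled independently and never mixed — a genuine telomere
fragment derives from one strand — and the strand with the larger total is
reported (ties go to G). `N` matches nothing; case is ignored; characters
outside A/C/G/T/N are input errors.

Because all motifs have length 6, the greedy scan always attains the
maximum possible number of non-overlapping matches (earliest-end-first is
optimal for equal-length intervals); the test suite verifies this against
an exhaustive dynamic-programming tiling on random and constructed
sequences. One caveat is deliberate and documented rather than "fixed":
the split between canonical and variant counts can depend on scan
direction in rare overlapping junctions (e.g. `CCCTACCCTAA`, where a
variant starting 5 bp before a canonical shadows it). Totals are always
direction-invariant; the greedy result is the defined behavior.

Stringency presets (total/canonical): low 4/2, medium 7/4, high 14/7.
About 85–90 bp of genomic sequence per read bounds the total near 14, so
high stringency demands an essentially pure repeat read. The shipped
variant list (TCAGGG, TGAGGG, TTGGGG, TTCGGG, TTTGGG, TAAGGG, GTAGGG,
CTAGGG, plus reverse complements) is the set of commonly reported human
variant telomere hexamers and is an explicit stand-in: any analysis can be
re-run with a user-supplied one-motif-per-line file.

## Clusters, chrT and the contact matrix

All telomeric reads are assigned to a single artificial 1-bp locus `chrT`,
which occupies one bin at any resolution. Within a barcode, genomic reads
with identical (chromosome, start) are collapsed as PCR duplicates; chrT
members are exempt from both masking and deduplication — every chrT read
shares the coordinate (0, 1) by construction, so a coordinate-identity
rule would collapse all telomere reads in a cluster to one. Masking uses
any-overlap, half-open (BED) interval arithmetic; masking runs before
deduplication. Coordinates are 0-based half-open throughout.

The contact matrix uses 2/N downweighting: a cluster of size N (the
post-mask, post-dedup member count) adds 2/N to every unordered pair of
member bins, including same-bin pairs on the diagonal, so each cluster
contributes total mass N−1 and mass conservation is exact in exact
arithmetic. In float64 the conservation identity is verified to a relative
error of 1e−9 (summation-order rounding only; measured error is ~1e−16).
The matrix is stored as an upper triangle and mirrored on output, making
symmetry exact by construction. The telomere track is the chrT row minus
its diagonal entry, which is reported separately as telomere–telomere
(clustering) mass. Default cluster-size bounds are [2, ∞); size caps such
as ≤100 or ≤1000 are display-time choices for cluster plots, not defaults.

## Track analytics

*Distance class* of a bin is its index from the nearest chromosome end,
terminal bin = class 1 (at 1 Mb resolution this equals the Mb distance).
The decay curve is the per-class mean over bins with non-zero contact,
expressed as a ratio to the class-1 mean, with the standard error of the
per-bin values. Bins with exactly zero contact are treated as unmappable
and excluded everywhere. *Distance normalization* divides each non-zero
bin by its class mean; by construction the normalized class means equal 1,
and the operation is idempotent. Annotation contrasts use Welch's
unequal-variance t-test on the normalized track, because group sizes and
variances (e.g. 7 centromeric vs 143 other bins) differ drastically.

The H3K9me3 proximity profile counts genomic reads by signed distance from
read midpoint to the nearest peak center, separately for clusters with and
without a chrT member, takes the per-distance-bin ratio and rescales so
the minimum is 1. Defaults: ±50 kb window, 1 kb step, all configurable;
bins with zero non-telomere coverage are reported missing. Eigenvector
correlation uses the distance-normalized track by default (a flag exposes
the raw track) with pairwise exclusion of missing bins.

## A/B compartments

Intrachromosomal contacts are divided by the genome-wide mean contact at
the same bin separation (expected pooled across chromosomes, zeros
included), rows of the per-chromosome O/E matrix are Pearson-correlated
(bins with more than 50% zero-or-missing entries are excluded — the 0.5
fraction is a documented knob — and remaining missing entries are excluded
pairwise), and the correlation matrix is decomposed by PCA
(column-mean-centered, SVD, deterministic up to sign). For each of the
first five components the bins are split by score sign (zeros grouped with
the positive side); gene density of a side is the mean count of gene
intervals overlapping each bin, a definition whose ratio is
resolution-invariant. The first component with density ratio ≥ 1.5 is
selected, otherwise the component with the largest ratio (ties to the
lowest index), and the sign is set so the denser (A) side is positive —
which also removes the PCA sign ambiguity.

## Ectopic telomere-repeat caller

Soft-clipped segments of ≥ 300 bp are scanned with windows anchored at
every canonical-repeat match; repeats inside a window are counted with the
same strand-unmixed greedy tiling as the read filter, and the best window
must hold ≥ 45 repeats. Evidence takes the insertion position from the
alignment start (left clip) or end (right clip); orientation is "standard"
when the G-strand motif runs away from the aligned segment (TTAGGG on a
right clip, CCCTAA on a left clip) and is reported, never filtered on.
Filters, applied in order: evidence MAPQ ≥ 30; insertion > 100 kb from
either chromosome end; single-linkage chaining of insertions ≤ 100 bp
apart (the simplest closure of the pairwise rule); representative position
= median member position (robust, deterministic); locus mappability — a
locus fails when ≥ 40% (inclusive) of reads overlapping the representative
position in the unfiltered alignment set have MAPQ < 10, and a locus with
no overlapping coverage fails as undeterminable; finally ≥ 2 *distinct*
supporting read ids (supplementary alignments contribute evidence only
through their own clips; duplicate ids count once). Output is sorted and
invariant to input read order.

## FISH proximity

Nuclei are segmented from the DNA channel with a 3-class Multi-Otsu
threshold; because the lowest threshold can fall inside a broad background
mode, the implementation takes the first threshold whose foreground covers
less than half the field. Components ≥ 500 px become nuclei. Foci are
segmented per channel within each nucleus with 3-class Multi-Otsu,
top-class foreground, area ≥ 9 px, centroid = mean pixel coordinate; a
robust contrast guard (threshold must exceed the masked median by 6 scaled
MADs) prevents pure noise from being split into foci on channels with no
real signal. The adjacency score is the mean number of telomere foci whose
centroid lies within 5 px (inclusive, centroid-to-centroid — the
self-consistent metric when randomization relocates point positions; an
edge-distance flag exists) of each centromere focus centroid. The
randomization test relocates every telomere centroid to an independent
uniform draw over nuclear-mask pixels, 1000 times, centromeres fixed, and
reports the mid-rank percentile (ties counted half), which is unbiased
under the discreteness of the score. Nuclei with no centromere foci are
skipped with a warning.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions for all end-to-end tests.

*Genome.* Three chromosomes (60/50/40 Mb). Natural telomeric tracts of
150 kb at every end and six interstitial 50 kb tracts; tract lengths are
scaled up relative to real telomeres so that the telomeric read fraction
(~1% of members, ~3% of reads in the FASTQ generator) stays in the
ALT-realistic range on a 30×-smaller-than-human genome. Interstitial
tracts sit > 10 Mb from every end: with only six bins per distance class a
near-end interstitial spike would dominate a class that the ~46 arms of a
real genome would dilute. Centromeres (2–3 Mb) are placed off-center, as
in submetacentric chromosomes; exactly mid-chromosome centromeres would
form their own distance class and distance normalization would divide
their enrichment by itself.

*Clusters.* 50,000 clusters, sizes log-uniform on [2, 300]. Members
scatter from a uniformly drawn anchor by a symmetric two-scale Lomax
displacement, P(|D| > d) = (1 + d/s)^(−1.5) with s = 75 kb for 65% of
members (local crosslinking neighborhood) and s = 2.5 Mb for 35%
(compartment-scale contacts), reflected at chromosome boundaries. A single
scale cannot reproduce both a sharply peaked local contact spike and a
decay still falling steadily at 10 Mb at these counts; the mixture does.
Members landing in a tract are sequenced as chrT reads with probability
0.9; every cluster additionally carries one chrT member with probability
0.02 (unanchored/extrachromosomal telomere fragments), multiplied by 6 for
clusters anchored inside a centromere — the mechanism that plants the
telomere–centromere association.

*Long reads.* Planted loci get three supporting reads each (2 kb aligned,
402 bp tandem-telomere soft clip, MAPQ 60, alternating sides and
orientations, ±40 bp jitter) plus ten spanning coverage reads so the
mappability filter is determinable. Six decoy classes each violate exactly
one filter: single support, MAPQ 29, 99 kb from a chromosome end, telomere
tract inside the aligned portion, 200 bp clip, and 50% MAPQ-5 coverage.

*FISH.* Disk nuclei (radius 62 px) on a jittered grid; 20 telomere and 20
centromere Gaussian foci (σ = 1.8 px, amplitude 250 over background 5,
noise σ = 2) per nucleus. Telomeres are placed uniformly over the full
nuclear disk — exactly the randomization's null law, which is what makes
the percentile calibration testable; centromeres keep an 8 px rim margin
and 12 px mutual separation so they segment cleanly. A stated fraction of
telomeres is instead planted within 3 px of a random centromere. The
20/20 focus counts keep the adjacency score's support rich enough that the
mid-rank percentile is approximately continuous; with few foci the score
is so discrete that a Kolmogorov–Smirnov uniformity check fails for
distributional rather than calibration reasons.

*Limitations.* The generator does not model sequencing error, barcode
collisions, mappability structure, chromatin compartments (compartment
recovery is tested on constructed correlation matrices instead), chained
or complex rearrangements, z-stacks or chromatic shift. Passing tests
demonstrate that each algorithm recovers what was planted under its own
model assumptions — they do not validate the biological models against
real data, which the pipeline consumes in standard formats (FASTQ,
SAM/BAM, BED, chrom.sizes, TIFF).

## Problem sizes and numerics

End-to-end checks run 50,000 clusters (~3M members), matrix conservation
on 10,000, the filter oracle on 10,000 sequences, the caller on 20 planted
loci, and FISH calibration on 200 null plus 100 enforced nuclei at 1000
randomizations — the scale at which every planted signal is comfortably
detectable while the whole suite runs in well under a test session.
Fixed seeds make every stochastic check deterministic. Mass-conservation
and aggregation identities are asserted at 1e−9 relative tolerance
(float64 summation order); the distance-normalization identity at 1e−9
absolute; eigenvector checks at 1e−8 after sign normalization.
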