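# Methods

`darkbin` re-implements, as one tested pipeline, the bespoke
computational procedures used in strain-level shotgun-metagenomic studies
of skin: conservative contig taxonomy, GC–coverage binning of the
taxonomically dark residual, fragment-ANI novelty detection, core-genome
concatenated phylogeny, metagenomic MLST and a paired-site
diversity/differential-abundance protocol. This note records the models,
their assumptions, the defaults that matter, and the choices made where
the design was genuinely open.

## Conservative contig taxonomy

For each assembled contig, alignment hits against the single best-matching
reference genome are summarised into two numbers: the **breadth of
coverage** (|union of query intervals| / contig length) and a
length-weighted mean **identity** over hits (overlap counted once per
hit; the aggregation is order-independent). The best reference is the
genome maximising Σ(identity × aligned length), ties resolved to the
lexicographically smaller id. A contig receives the species label of its
best reference only when *both* breadth and identity are strictly above
0.90; boundary equality is unassigned. The strictness is deliberate —
the rule is designed to minimise false species assignments, at the cost
of recall near the boundary. Labelled contigs longer than 1000 nt are
grouped into per-species bins; everything else (unassigned or short) is
the residual set passed to dark-matter binning. Species names come from a
user-supplied genome→species table; no attempt is made to detect
mislabelled reference genomes.

## Dark-matter binning and curation

Residual contigs are clustered by K-means on (GC fraction, log10
coverage), each standardised to zero mean and unit variance. Coverage is
logged because depth noise is multiplicative. K is selected in 2..k_max
(default 8) by mean silhouette, with two guards:

* a **floor of 0.45**: if no K reaches it, the residual stays in one
  bin. A homogeneous standardised 2-D point cloud yields silhouette
  ≈ 0.35 under any K-means split, so a meaningful floor must sit above
  that; 0.45 separates that regime from genuinely clustered data (planted
  clusters in our fixtures score > 0.7).
* a **parsimony tie-break**: the smallest K within 0.05 of the best
  silhouette wins. When one feature is uninformative, standardisation
  stretches its noise and the silhouette curve becomes nearly flat while
  slightly favouring over-splits; the tie-break keeps two elongated true
  clusters as two bins.

Curation then accepts a bin only if (i) every member's GC lies within 5%
*relative* deviation of the bin's GC median, (ii) every member's coverage
lies within 25% relative deviation of the coverage median, (iii) the
bin's centroid is separated from the nearest other centroid by more than
2 within-bin RMS radii in the standardised feature space, and (iv) the
bin is large enough to support downstream analysis (≥ 5 contigs and
≥ 50 kb). Rejected bins carry machine-readable reasons. The relative
(rather than absolute-percentage-point) reading of the GC tolerance is a
configuration choice (`gc_tol`); note it makes the criterion tighter at
low GC, where the binomial GC noise of short contigs can approach the
tolerance — curation is intended for bins of long contigs.

## Fragment ANI and the novelty call

Average nucleotide identity between a bin (or genome) and a reference is
computed fragment-wise: the query is cut into consecutive 1000 nt
windows (trailing stubs under 500 nt dropped), each window is aligned to
the reference, and windows whose best hit reaches ≥ 70% identity over
≥ 70% of the window are retained. ANI is the mean of retained fragment
identities × 100, reported with the sample standard deviation (ddof = 1)
over fragments. A bin is assigned to the species of its best reference
(highest ANI) only when ANI is strictly above 97.5%; otherwise it is
novel; if no fragment is retained against any reference the bin has no
signal. On substitution-only data the calibration is tight:
ANI ≈ 100(1−p) within ~0.2 points for planted divergence p ≤ 0.10
(the residual bias is upward, from mismatch-free trimming of segment
ends).

## Core-genome concatenated phylogeny

A reference gene catalogue is searched against every genome and curated
bin. A hit is a plausible ortholog when strictly longer than 500 bp and
strictly above 70% identity; multi-copy hits resolve to the best score.
Genes present in strictly more than 95% of the genomes form the core.
Per-gene blocks are extracted co-linearly with the full gene along the
hit diagonal (exact for substitution-only data; genomes missing a
near-core gene contribute an all-gap block) and concatenated in stable
gene order. Columns with gap fraction above 0.2 are trimmed — a fixed,
reproducible single-parameter stand-in for adaptive gappy-column
removal. Trees are built by neighbor joining on p- or Jukes–Cantor
distances with pairwise deletion of gap sites; JC is undefined at
mismatch fraction ≥ 0.75 and the offending pair is named in the error.
Negative NJ branch lengths are clamped to zero. NJ replaces
maximum-likelihood inference deliberately: the claims exercised here are
topological placements, which NJ recovers exactly (Robinson–Foulds 0 in
the planted-tree tests) whenever branch substitution rates are ≥ 0.02
and the core is ≥ 20 kb.

## Metagenomic MLST

Reads are anchored to scheme loci by exact 21-mers against the catalogued
alleles (k-mers shared between loci are discarded as ambiguous); since
allelic variation is substitution-only, alleles of a locus are co-linear
and the anchor fixes the read's offset in locus coordinates. Per-position
base counts form a pileup; the template is the catalogued allele with
minimum Hamming distance to the preliminary majority sequence (ties to
the lowest allele id). The consensus takes the majority base where depth
≥ 2 (ties → template base), the observed base at depth 1, and the
template base at depth 0. Consensus alleles are matched to the catalogue
by exact equality; a full profile of known alleles is looked up in the ST
table (an unknown combination is reported as a novel type), any new
allele makes the type novel, and a locus without reads makes it
incomplete. Two samples carry the identical strain iff at most one locus
differs and no differing locus differs by more than one SNP — for an
8-locus scheme this is exactly "more than six of eight identical", and
the at-most-one-differing-locus form generalises the rule to schemes of
any size (e.g. 7-locus schemes).

## Diversity and the paired-site protocol

Samples are rarefied to a common depth (default 50 000 reads) by
multivariate hypergeometric subsampling — exact, seeded, summing to the
depth; samples below the depth are excluded by an explicit error, never
silently truncated. Richness is the number of taxa with positive count;
evenness is the Gini–Simpson index 1 − Σp². Beta diversity is
Bray–Curtis 1 − Σ min(pᵢ, qᵢ) on relative abundances; all unordered
sample pairs are split into same-patient (intra-subject) and
different-patient (inter-subject) distributions. The accompanying
rank-sum comparison is descriptive only, and says so in its output:
pairwise distances share samples and are not independent.

Differential abundance uses the paired design: each eligible patient
contributes one diseased and one unaffected sample of the same site
class (contralateral sides); both are rarefied to the pair's minimum
depth (seeded) before converting to relative abundances; each taxon is
tested by the Wilcoxon signed-rank test across pairs (exact null for
n ≤ 25 without ties, else normal approximation with continuity
correction; zero differences dropped; ties mid-ranked), and p-values are
corrected across the taxa tested — Benjamini–Hochberg by default,
Bonferroni/Holm configurable. Patients flagged for antibiotic use are
excluded before pairing. Fewer than 6 pairs sets a small-n flag; a
single pair returns p = 1. Welch's unequal-variance t-test (two-sided,
Welch–Satterthwaite degrees of freedom) is provided for group
comparisons of diversity indices.

## What the synthetic cohort emulates — and what it does not

All generators are pure functions of their seed and emit machine-readable
truth beside their outputs.

* **Genomes** evolve by i.i.d. substitutions along a user-specified
  genealogy; the truth table gives expected pairwise divergence by path
  addition. No indels, no rearrangements, no horizontal transfer — this
  keeps identity/ANI oracles exact and per-gene alignments ungapped, at
  the price of not exercising gap handling.
* **Contigs** are non-overlapping substrings covering the genome
  completely, with log-normal depth noise (positive and right-skewed like
  real contig depths). There is no assembly error, chimerism or repeat
  collapse.
* **Cohorts** draw multinomial read counts at fixed depth from a
  genus-level skin-like base profile combined with (a) a per-patient
  log-normal offset (s.d. `subject_sd`, default 1.0) shared by all of a
  patient's samples — one parameter that reproduces the
  intra < inter subject beta-diversity structure; (b) an independent
  per-sample log-normal dispersion (`sample_sd`, default 0.35) emulating
  ecological noise between contralateral sites; and (c) a planted
  multiplier (default 2×) on one taxon (*Staphylococcus* by default) at
  diseased sites. The per-sample dispersion is essential: counts are
  compositional, so the planted increase deflates every other taxon by a
  common factor, and with only multinomial noise that deterministic
  spillover would make all null taxa "significant". `sample_sd` was
  calibrated so the protocol meets its intended operating
  characteristics (power ≥ 0.80 for the planted genus at 2× with 20
  patients; any-taxon false-positive rate well under 10% with no
  effect). The base profile keeps the effect taxon minor (5%) so
  spillover stays below the noise floor. Real skin profiles have heavier
  tails, zero inflation and taxon correlations that this model does not
  attempt; passing tests demonstrate correctness of the *procedures*
  under the stated model, not field performance on real metagenomes.
* **MLST reads** are substrings of each allele embedded in random
  flanking sequence (one read length per side), with i.i.d. substitution
  errors. The flanks matter: without genomic context, locus ends receive
  ~0–1× depth and single erroneous reads leak into the consensus through
  the depth-1 rule; with them, coverage is uniform as for real
  housekeeping loci.

## Numerical and tie-breaking choices

* Native aligner: exact k-mer seeds (default k = 15; k = 11 for ortholog
  search, where targets are more divergent) define candidate diagonals;
  on each diagonal the maximal-scoring ungapped segment (match +1,
  mismatch −2, first-occurrence argmax) is the hit. Segment boundaries
  always fall on matches, which is the source of the small upward ANI
  bias noted above. Default thresholds (identity 0.70, length 100) sit
  below every downstream rule so the aligner never pre-empts one.
* All thresholds written as strict inequalities in their rules are
  implemented strictly (90/90, 97.5 ANI, 500 bp, 70%, 95% prevalence).
* Coordinates are 0-based half-open in memory; the tabular hit format is
  1-based inclusive on disk, with minus-strand rows normalised to
  ascending intervals and a strand flag. Ungapped rows round-trip
  identity exactly via their mismatch counts.
* Every stochastic step takes an explicit seed; the pipeline derives
  per-stage seeds from the config seed by fixed small offsets, and its
  JSON report is byte-identical across reruns (sorted keys, no
  timestamps).

## Problem sizes used in tests

The suite runs on desk-scale instances chosen to make each statistical
check sharp: 50–100 kb genomes for assignment and ANI (100 fragments per
ANI estimate), 60 contigs of 10 kb for binning recovery, 6–8 taxon trees
on ~24 kb cores, 8-locus × 450 bp MLST schemes at 20×, and 100 simulated
20-patient cohorts at 20 000 reads/sample for the operating
characteristics of the paired test.

## Known limitations

* Ungapped alignment only in the native aligner; gapped external hits
  are consumed through the tabular reader but never produced.
* The curation tolerances are scale-sensitive (relative deviations), and
  GC consistency approaches the tolerance for short, low-GC contigs.
* The intra/inter beta-diversity comparison has no calibrated test — by
  design, only a flagged descriptive statistic.
* MLST consensus models the dominant strain only; within-sample strain
  mixtures are out of scope.
* NJ gives no support values; it is a placement tool here, not a
  substitute for model-based phylogenetics.
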