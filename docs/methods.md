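# Methods

This document describes the statistical models, algorithmic conventions and
numerical choices behind `diagmsat`.

## 1. Repeat scanning (`diagmsat.scan`)

A microsatellite locus is a run of at least `min_repeats` (default 4)
consecutive, identical copies of a primitive 3- or 4-base motif
("primitive" meaning not itself a repetition of a shorter unit, so `ACAC`
is excluded as a 4-mer because it is a dinucleotide repeat).

**Tract anchoring.** A perfectly periodic stretch of DNA can be described
by any rotation of its motif starting at any offset. To report one locus
per physical repeat, the scanner anchors each locus at the start of its
*maximal periodic tract*: position `i` starts a locus for period `k` only
when the periodicity does not extend to `i-1` (condition
`seq[i-1] != seq[i+k-1]`). The reported span covers the full tandem copies
from that anchor; a trailing partial copy is not included in the span.

One consequence of this convention is that scanning a sequence and its
reverse complement yields the same multiset of (canonical motif, repeat
count) loci, but the reported coordinates can differ by up to
`motif_length - 1` bases when a tract carries a partial trailing copy: the
anchor then sits at opposite ends of the tract on the two strands. The
strand-symmetry test asserts equality of counts and motifs and agreement of
coordinates up to this offset.

**Canonical motifs.** Motifs are named by the lexicographically smallest
string among all rotations of the motif and of its reverse complement, so
one label covers a repeat regardless of reading frame and strand (e.g.
`TAA`, `ATA`, `AAT`, `TTA`, `TAT`, `ATT` are all `AAT`).

**Flanks.** Each locus records the adjacent `flank_length` (default 20)
bases on both sides. A flank that would run past the contig end or contains
an ambiguous base (`N`) is stored as `None`; such loci are kept in scan
output but cannot be matched across genomes.

**N50 filtering.** `compute_n50` returns the length `L` such that contigs
of length ≥ `L` cover at least half the assembly. `contigs_above_n50`
keeps contigs strictly longer than the N50, the "larger than N50"
pre-filter used when scanning an assembly for marker candidates.

## 2. Cross-genome matching (`diagmsat.compare`)

A source locus is located in the target assembly by exact occurrence of its
two flanks, searched on both strands (for the reverse strand, the matcher
searches for the reverse complements of the flanks in the appropriate
order). Outcomes:

* `matched` — each flank occurs exactly once across the whole target
  (both strands counted), on the same contig and strand, in the correct
  order, within a span cap; the target repeat count is the longest tandem
  run of any rotation of the source motif in the inter-flank sequence.
* `ambiguous` — some flank occurs more than once across the target; the
  locus cannot be anchored uniquely.
* `flank_missing` — a flank does not occur (or the source locus has no
  usable flanks).
* `span_too_long` — both flanks anchor uniquely but the inter-flank span
  exceeds `max_span` (default `min(2000, len(f5)+len(f3)+50*len(motif))`),
  which guards against spurious distant co-occurrence.
* `motif_absent` — flanks anchor but no copy of the motif lies between
  them.

`diff = |n_source - n_target|` is symmetric under swapping the roles of the
two genomes at loci matched in both directions.

**Diagnostic filter.** `FilterBand(min_shared_repeats, diff_min, diff_max)`
keeps matched loci with `min(n_A, n_B) >= min_shared_repeats` and
`diff_min <= diff <= diff_max`. The default band (4, 3, 10) selects loci
with enough repeats in both species to be genotypable and a repeat-count
difference large enough to suggest diagnostic divergence but small enough
to remain a credible ortholog; the narrower band (4, 4, 10) is nested
inside it by construction.

## 3. Marker statistics (`diagmsat.popgen`)

Genotypes are diploid; alleles are positive integer codes and 0 marks a
missing call. All per-locus statistics use complete-case exclusion.

* **Allele frequencies**: counts over `2 × n_genotyped`.
* **Heterozygosities**: `Ho` is the heterozygote fraction; `He = 1 - Σ p²`
  (no small-sample correction).
* **Shared/private alleles**: set intersection/difference of the two
  samples' allele sets; the count-based shared proportion is
  `|A∩B| / |A∪B|`. A frequency-weighted companion,
  `shared_allele_frequency_mass`, averages across the two samples the total
  frequency carried by shared alleles; this is the quantity used in the
  panel reconstruction (section 6).
* **F_ST**: the 1984 Weir–Cockerham θ from variance components `a` (among
  populations), `b` (among individuals within populations) and `c` (within
  individuals), summed over alleles; the multilocus estimate is
  `Σa / Σ(a+b+c)` over loci (ratio of sums, not mean of ratios). Negative
  estimates are retained; loci monomorphic across both samples are `NaN`.
* **Exact HWE test**: the conditional probability of a genotype array given
  its allele counts is `P = n! 2^h Π c_i! / ((2n)! Π n_ij!)` with `h` the
  heterozygote count. The p-value sums `P` over all arrays no more probable
  than the observed one (tie tolerance 1e-9 in log space; log factorials
  via `gammaln`). Arrays are enumerated recursively; if the enumeration
  exceeds a work cap, `auto` mode falls back to Monte-Carlo shuffling of
  gene copies with the add-one estimator `(hits+1)/(reps+1)`. A monomorphic
  locus returns p = 1.
* **Bonferroni**: `alpha / n_tests`.

## 4. Hybrid-class simulation (`diagmsat.simulate`)

Six genotypic classes are simulated from two parental allele-frequency
pools: `pure_A`, `pure_B`, `F1`, `F2`, `BC_A`, `BC_B`. Loci are
independent; for F2 and backcrosses the F1 gamete is drawn marginally per
gene copy (from pool A with probability 1/2), which is equivalent per locus
to instantiating explicit F1 parents, and per-locus marginals are all the
classifier uses. The diagnostic-limit expectations follow directly: F1
individuals are heterozygous A/B at every fully diagnostic locus, F2 loci
are (A,A)/(A,B)/(B,B) with probability 1/4 : 1/2 : 1/4, and a backcross
never carries the opposite-species homozygote.

## 5. Classification (`diagmsat.classify`)

Each class is characterized by its expected fractions of loci with
(A,A), (A,B), (B,B) gene-copy ancestry:

| class  | (A,A) | (A,B) | (B,B) |
|--------|-------|-------|-------|
| pure_A | 1     | 0     | 0     |
| pure_B | 0     | 0     | 1     |
| F1     | 0     | 1     | 0     |
| F2     | 1/4   | 1/2   | 1/4   |
| BC_A   | 1/2   | 1/2   | 0     |
| BC_B   | 0     | 1/2   | 1/2   |

The per-locus likelihood of a genotype under a class mixes Hardy–Weinberg
genotype probabilities within each ancestry category.

**Plug-in estimator** (`classify_plugin`): treats the parental frequencies
as known; the posterior is prior × product of per-locus likelihoods,
computed in log space. Individuals with zero likelihood under every class
(e.g. carrying an allele absent from both pools) receive a uniform
posterior and are flagged.

**Gibbs sampler** (`classify_mcmc`): samples the full hierarchical model —
class indicators `z`, mixing proportions `π` (Dirichlet(1) prior),
per-locus per-copy ancestry categories, and both pools' allele frequencies
`θ` (symmetric Dirichlet priors over the alleles observed in the data).
Designated reference individuals have `z` fixed to their known class but
their gene copies still inform `θ`. Posteriors are indicator averages over
post-burn-in sweeps. The sweep is fully vectorized over individuals and
loci; class indicators are drawn by Gumbel-max on the log-posterior.

The two estimators answer slightly different questions: the plug-in
conditions on known frequencies and a fixed uniform class prior, while the
sampler learns `π` from the non-reference individuals and integrates over
frequency uncertainty. With abundant reference data and a single free
individual the symmetric Dirichlet prior on `π` integrates out to a uniform
class prior and the two posteriors agree closely (this is the sampler's
consistency test); with many free individuals the learned `π` makes the
posteriors genuinely different, which is intended behavior, not error.

**Power assessment** (`power_assessment`): simulates `n_per_class`
individuals per class plus `n_ref_per_pool` known pure references per
species, classifies, and tabulates per-class argmax accuracy and mean
posteriors by true class. Reported accuracies are Monte-Carlo estimates;
at `n_per_class = 100` one binomial standard error is 3–5 percentage
points depending on the accuracy, and the simulation, reference draw and
chain seeds add further run-to-run variance.

## 6. Synthetic truth-table generators (`diagmsat.synth`)

**Genome pairs.** `make_genome_pair` plants orthologous repeat cassettes
(unique 20-bp flanks around `motif × n` tracts) into backgrounds free of
3/4-mer runs of ≥ 4 copies. Flank boundaries are constrained
(`f5[-1] != motif[-1]`, `f3[0] != motif[0]`) so flanks cannot extend the
tract. Options plant substitutions in the B-side 5' flank (expected status
`flank_missing`) or a duplicate cassette (`ambiguous`). The generator
validates the whole construct by re-scanning and re-counting flank
occurrences, retrying with fresh randomness on collision, so the returned
truth table is exact by construction.

**Divergence datasets.** `make_genotype_dataset` draws Hardy–Weinberg
samples from two pools whose allele sets share a controllable proportion of
alleles, spanning fixed differences (`shared_proportion=0`) to identical
pools (`freq_mode="identical"`), the two F_ST limiting cases.

**Panel reconstruction.** `sparrow_panel` returns a deterministic synthetic
stand-in for the allele frequencies of a published 12-locus diagnostic
panel for the Saltmarsh/Nelson's sparrow pair. The published per-allele
frequency appendix is not redistributed here; instead, per-locus summary
constraints (total and private allele counts, both species'
most-common-allele frequencies in both species, and the frequency-weighted
shared-allele proportion) are used to allocate frequencies: the pinned
most-common-allele frequencies are set exactly, remaining shared mass is
split across synthetic shared alleles, remaining mass across synthetic
private alleles, and rounding residue is absorbed into an unconstrained
allele so the pinned values stay exact. The reconstruction reproduces the
panel's summary statistics and its sampled multilocus F_ST falls in the
published range, but individual allele identities and the fine shape of
each frequency distribution are synthetic. Quantities that depend only on
the constrained summaries are faithful; quantities sensitive to the
unconstrained fine structure (e.g. exact per-class assignment accuracies)
should be expected to deviate by a few percentage points.

## 7. Numerical and protocol choices

* Chain length: classification experiments in the tests and the acceptance
  script run 20,000 sweeps after 20,000 burn-in (a tenfold reduction of the
  published 200k/200k protocol) to fit a desk-scale compute budget; the
  vectorized sampler's posterior averages are stable well before this
  length on the panel sizes used here.
* All randomness flows through `numpy.random.default_rng` seeds; every
  generator and test is deterministic under a fixed seed.
* GenePop parsing is hand-rolled (the format is simple and no maintained
  parser ships with the installed stack); both 2- and 3-digit dialects are
  read, files are written in the 3-digit dialect, and a half-missing call
  is treated as fully missing.
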