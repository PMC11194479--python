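# Methods

## Scope

`aimpanel` evaluates candidate ancestry-informative SNP markers by
exhaustive combination search around a DAPC classifier, and characterizes
diagnostic power against population differentiation with a Balding–Nichols
simulator and a Weir–Cockerham F<sub>ST</sub> estimator. It assumes marker
pre-selection (e.g. from a RAD-seq discovery panel) has already happened;
it ranks and prunes a candidate set, it does not discover markers.

## Genotype representation

Genotypes are diploid integer allele codes with a reserved missing code
(default −9, the STRUCTURE convention). Codes are opaque labels — no
reference/alternate or strand semantics — because the classifier consumes
only per-allele copy counts. Loci observed with more than two alleles are
legal (one count column per observed allele). Both common STRUCTURE
dialects are read and written: two consecutive rows per individual, or one
row with paired columns; reading auto-detects the dialect (paired
consecutive ids ⇒ two-row) and an optional locus-name header, and extra
metadata columns can be skipped. Writing then reading is the identity on
the container, a property the test suite checks on random sets.

## The DAPC classifier

1. **Expansion.** Genotypes become an individuals × (locus, allele) count
   matrix; a missing call masks all of its locus's columns.
2. **Imputation.** Masked entries are replaced by training-column means
   (the field-standard mean imputation); test matrices are always imputed
   with the *training* means so no test information leaks into the fit.
3. **Centring/scaling.** Columns are centred; unit-variance scaling is off
   by default because allele counts share a scale (flag-controlled).
4. **PCA.** Principal axes come from the SVD of the centred matrix; the
   default retention min(⌊n/3⌋, columns, n−1) is the usual guard against
   discriminant overfitting and is capped at the numerical rank. An
   explicit count can be supplied. Single-column panels are legal — the
   PCA degenerates to at most one axis.
5. **Discriminant axes.** The generalized eigenproblem B v = λ W v on the
   between/within scatter of the PC scores, at most g − 1 axes. W carries
   a 1e−8 relative ridge so tiny panels with collinear counts stay
   well-posed.
6. **Posteriors.** Squared Mahalanobis distances to group centroids in
   discriminant space under the pooled within-group covariance
   (ridge-regularized if singular), turned into posteriors with equal
   group priors. Equal priors are deliberate: training-set population
   sizes are incidental to a diagnostic assay. Ties in the argmax break by
   group-label sort order, deterministically.

With full PC retention this is exactly a linear discriminant analysis with
equal priors on the raw count matrix; the tests verify assignment- and
posterior-level agreement with an independent brute-force discriminant
oracle (and the construction matches scikit-learn's LDA on the same
fixtures).

## Cross-validation

The scoring procedure is repeated stratified Monte-Carlo holdout: in each
replicate every population is independently split into floor(0.75·n)
training individuals (clamped to [2, n−1]) and the remaining test
individuals; populations with fewer than 3 members are rejected. A test
individual is correct when its argmax population equals its true origin
**and** the winning posterior reaches the threshold; thresholding the true
population's posterior instead is available (`threshold_on="true_pop"`).
Individuals passing the argmax check but failing the threshold count as
failures. A replicate whose fit is degenerate (e.g. the combination is
monomorphic in the training sample) scores all test individuals incorrect
and records a warning rather than raising, so exhaustive sweeps never
abort on uninformative combinations.

**Seeding contract.** The seed of replicate r for combination c is the
first 32 bits of SHA-256(base_seed | sorted(c) | r). Every replicate is an
independent work unit, so per-combination results are bit-identical across
repeated runs, execution orders, and worker counts; parallelism (joblib)
affects wall-clock only.

**A known statistical subtlety.** On a single *fixed* finite sample with
no true signal, holdout rates sit slightly below 0.5 for two equal
populations (≈0.44 at 20+20 individuals) because the training and test
frequency deviations are anti-correlated when partitioning the same
individuals. The 0.5 null expectation holds over fresh datasets, which is
how the null-behaviour tests are constructed. Real panels with real signal
are unaffected in practice, but rates on very small samples are mildly
pessimistic.

## Panel exploration

All C(n, k) combinations for each size k in the requested range are
enumerated lexicographically and scored; the per-size summary is the
unweighted mean (and SD) of its combinations' mean rates. Per-marker
tables come in two deliberate flavours, because "a marker's rate" is
ambiguous: *singleton* (the marker evaluated alone) and *marginal* (mean
over every evaluated combination containing it). Sweeps above a
combination cap (default 100 000) are refused unless explicitly confirmed;
the CLI prints the full run plan first. Two panel groups are compared by a
two-sample t-test on combination-level mean rates — Welch's form by
default, since the combination-rate lists rarely share a variance, with
the classical equal-variance form behind a flag; two zero-variance groups
short-circuit to (t, p) = (0, 1) if equal, (±∞, 0) if not.

## Simulation and F<sub>ST</sub> estimation

The generator draws, per locus, an ancestral frequency p ~ U(low, high)
(default (0.1, 0.9), avoiding near-fixed loci that make weakly
differentiated datasets uninformative), then per subpopulation a frequency
from Beta(p(1−F)/F, (1−p)(1−F)/F) — mean p, variance F·p(1−p) — and
genotypes as two independent allele copies (Hardy–Weinberg within
subpopulations, no linkage, mutation, migration or selection). F = 0 is
handled exactly (all subpopulations share p). Defaults are the simulation
study's conditions: 2 subpopulations × 1000 diploids, 15 loci.

The estimator is the Weir & Cockerham (1984) variance-component θ̂:
per-locus, per-allele components a, b, c from sample sizes, allele
frequencies and observed heterozygote proportions, with per-locus sample
sizes so missing data is handled naturally, and multiallelic loci summed
over alleles. Multilocus values are the **ratio of sums**, never a mean of
per-locus ratios; negative per-locus estimates are reported as computed
(truncation would bias recovery). Monomorphic loci get a NaN per-locus
value and contribute zero components.

With only two subpopulations, each locus's among-population variance has a
single degree of freedom, so single-dataset estimates scatter widely (SD
≈ 0.05 near F = 0.2 at the study dimensions) even though the mean over 20
replicate datasets recovers the target within ±0.02 (±0.01 near F = 0.01)
— the tests and the acceptance script check exactly this.

## What the simulator does and does not emulate

It produces idealized unlinked biallelic loci, equal subpopulation sizes,
no missing data, no genotyping error and no hierarchical structure.
Passing recovery and monotonicity tests therefore demonstrates correctness
of the generator/estimator/classifier loop, not performance on real
panels, where missingness, linkage among candidate SNPs and unequal,
possibly admixed samples can make empirical F<sub>ST</sub> a weaker
predictor of diagnostic power.

## Problem sizes and numerical choices

The test suite runs the full study dimensions where cheap (20 × 2000 × 15
datasets per divergence level; 100-replicate full-panel cross-validations)
and scales the exhaustive-sweep bookkeeping check (4943 combinations) to a
small 16-individual fixture with one replicate per combination, since that
check concerns counting and aggregation, not statistical power.
Tolerances: posterior rows sum to 1 within 1e−9; oracle equivalence within
1e−6 on posteriors; component-level estimator agreement within 1e−12.

## Open design choices resolved here

- The original description of the validation scheme mixes "leave-one-out"
  wording with a 75/25 split; the implemented and documented procedure is
  the operationally complete one, repeated stratified Monte-Carlo holdout.
- PC retention and column scaling are explicit, documented defaults
  (⌊n/3⌋ rule; centring only) rather than inferred behaviour, both
  user-overridable.
- The threshold applies to the winning posterior by default; the
  alternative reading is a config switch rather than a silent choice.
- "20 simulated populations" per divergence level is read as 20 replicate
  datasets per level, exposed as a parameter.
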