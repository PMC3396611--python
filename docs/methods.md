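# Methods

`prognoseq` implements a genome-wide RNA-seq biomarker screen for
time-to-event outcomes, in the form used for archival (FFPE) breast-cancer
cohorts: raw transcript counts are normalized, every feature is tested for
association with recurrence by univariate Cox regression with robust
variance, discoveries are controlled by Storey's FDR with effect-size
(TDRDA) lower bounds and regression-to-the-mean correction, putative
intergenic transcripts are discovered from pooled read coverage, and
identified features are organized into co-expression networks. A
synthetic-cohort generator reproduces the statistical structure of the
emulated 136-patient cohort so that every stage is testable without
patient data.

## Normalization

Raw counts are log2-transformed with the convention log2(0) := 0. This
collides with log2(1) = 0; the collision is part of the procedure being
implemented and is deliberately not patched with pseudocounts. Features
whose count never reaches 5 in any sample are excluded first.

Third-quartile normalization shifts each sample by (cohort mean Q3 −
sample Q3), where Q3 is the 75th percentile of the log2 counts of a
*reference* feature class: RefSeq transcripts for RefSeq and intergenic
matrices, intronic transcripts for intronic matrices. Quartiles use linear
interpolation between order statistics (the "type 7" convention,
`numpy.percentile`'s default); the choice is configurable
(`quartile_method`). Zeros are included in the quartile. Q3 is computed
after the max-count filter by default. After normalization every sample's
reference Q3 equals the cohort mean exactly; normalizing twice changes
nothing. Note that adding a constant c to one sample's log2 values moves
*every* sample's normalized output by c/n through the cohort mean — the
transform is equivariant, not invariant, to per-sample location shifts.

The relative log expression (RLE) diagnostic — each value minus its
sample's median across features — is reported per sample (median, IQR);
medians hugging zero indicate effective normalization.

## Survival screen

Each feature's normalized expression is standardized (mean 0, SD 1, n−1
denominator; constant features are excluded with a reason) and fit as the
single covariate of a Cox proportional-hazards model, so exp(beta) is the
standardized hazard ratio (SHR): the proportional change in hazard per 1-SD
increase in expression. The partial likelihood uses the Efron tie
approximation by default (Breslow switchable); Newton iteration runs from
beta = 0 with step halving to relative tolerance 1e-9, at most 100
iterations. The solver is vectorized across features — all features share
one risk-set ordering, so the 20k-feature screen and the replicated
simulation suites run in seconds.

Variance uses the Lin–Wei robust sandwich, I⁻¹(Σᵢ Wᵢ²)I⁻¹ with Wᵢ the
per-subject score residuals, guarding against non-proportional hazards and
nonlinearity. Score residuals use Breslow-style martingale increments,
exact for untied (continuous) survival times; with ties the SE differs
from the fully Efron-adjusted value by a percent-scale amount.

**Wald reference.** The two-sided Wald p uses a Student-t reference with
df = (number of events − 1) rather than a normal. The sandwich variance is
informed by only as many independent contributions as there are events;
with 26 events a normal reference is measurably anti-conservative exactly
in the far tail a genome-wide screen reads (≈3.5× at p = 1e-4 on null
cohorts), which destroys FDR control on null data. With the t reference,
null calibration is ≈1.0 in the bulk and conservative in the far tail, and
the mean empirical FDR at q < 0.10 over 100 pure-null cohorts is ≈0.05.
A normal reference remains available (`wald_reference="normal"`).

**FDR.** Storey q-values with tuning parameter λ = 0.5: π0 = #{p > λ} /
((1−λ)m) clipped to (0, 1], q(i) = min over j ≥ i of π0·m·p(j)/j.

**TDRDA sets.** For each lower bound B on a grid (default 1.00–2.00 in
steps of 0.05, covering the range of reported bounds), a shifted Wald test
of H0: |beta| ≤ log B is run in each direction; the two-direction p is
min(1, 2·SF((|beta| − log B)/se)) with the same t reference. Per-bound
Storey q-values (π0 estimated per bound) define the B-set at FDR 10%; each
feature reports its maximum qualifying B. At B = 1 the procedure reduces
exactly to the two-sided screen, and membership is monotone in B.

**Regression-to-the-mean correction.** Screen "winners" are selected
partly for lucky noise, so their estimates overstate the true SHR. The
correction is empirical-Bayes normal–normal shrinkage: τ² = max(0,
Var(beta) − mean(se²)), beta_rtm = mean(beta) + (beta −
mean(beta))·τ²/(τ² + se²). With negligible SEs nothing moves; with τ² = 0
everything collapses to the mean. The MSE-improvement property (shrunken
beats raw against the simulation truth table) is verified in the test
suite; the structure is the canonical normal–normal correction, chosen
because only the correction's purpose, not its formulas, is fixed by the
procedure being implemented.

## Intergenic transcript discovery

Pooled uniquely-mapped reads from all patients ("filtered to a depth of 1
read" is read as: every position covered by ≥1 read participates; the
alternative reading — dropping singleton islands — is available via a
flag) are clustered into read islands: maximal runs of strictly
overlapping reads under half-open coordinates. Abutting reads (one
starting exactly where another ends) do *not* join, so islands are the
connected components of the read-overlap graph, which the tests verify
against a brute-force O(n²) oracle.

Nearby islands are merged into regions of interest (ROIs) at a merge
distance selected from a candidate list by maximizing overlap of the
merged regions with annotated gene bodies. The default objective is the
base-level Jaccard index between the union of merged regions and the union
of [txStart, txEnd) gene spans. A per-region Bernoulli score (fraction of
regions ≥50% inside gene bodies, evaluated as a one-sided log-likelihood
ratio against the genome-wide gene-body fraction) is selectable, but it is
not the default because any per-region success score degrades as intra-gene
fragments merge (fewer, not proportionally more successful, regions) and
can therefore prefer no merging at all; the base-level Jaccard is monotone
in exactly the overlap being maximized. Candidate scanning uses tolerance
semantics (gap ≤ d); ties break to the smallest candidate.

ROIs are then filtered by three inclusive criteria: cohort-average read
count ≥ 5, length ≥ 100 bp, and read depth (average count / length) ≥
0.075. Survivors with zero base overlap with any annotated transcript span
(either strand; introns count as genic) are classified intergenic, and
per-patient read counts over these ROIs feed the normalization and screen
as an intergenic-class count matrix (normalized against the RefSeq
reference). Finally, significant ROIs are condensed by merging neighbors
separated by < 1000 bp (strict, as printed); the merge report contrasts
median pairwise Pearson R within merged groups against unmerged ROIs,
the co-expression evidence that merged neighbors are fragments of one
transcript.

## Co-expression networks and ER calls

The network over a feature set (typically the FDR-identified features)
connects pairs with Pearson R > 0.6 on normalized values — strictly
greater, positive correlations only (an |R| mode and inclusive ≥ are
flags); degree-0 nodes are dropped. Components and degrees come from
undirected traversal.

ER status is called from normalized ESR1 expression: positive iff ESR1 ≥
cutoff. Because "set by visual inspection" is not reproducible, the
default cutoff is the midpoint between the two component means of a
two-component Gaussian mixture with fully deterministic initialization
(equal weights, means at the 25th/75th percentiles, shared variance);
explicit cutoffs override. A fit whose components separate by less than
one pooled SD raises instead of guessing. PGR is used the same way for a
consistency flag (PGR+/ER− or PGR−/ER+ calls are rare in breast tumors and
are reported as discordant).

## Concordance

Lin's concordance correlation coefficient, ρc = 2·cov(x,y)/(var(x) +
var(y) + (mean x − mean y)²) with n-denominator moments (Lin's original
definition), measures agreement with the identity line; it never exceeds
|Pearson r|. Hazard-ratio scatters are compared on the log2 scale. RT-PCR
crossing thresholds are converted to expression as (cohort median C_T −
C_T), so higher = more expressed. Prognostic-agreement tables classify
features as prognostic at p < 0.05 (configurable) on each platform and
test the 2×2 association with Fisher's exact test, optionally stratified
by median-count abundance bin since cross-platform agreement falls off
with decreasing abundance; a zero off-diagonal reports the odds ratio as
unbounded rather than a number.

## Synthetic cohorts

The generator emulates the 136-patient cohort the pipeline was built for:

* **Abundance.** Each feature receives a target median count drawn
  log-uniformly within one of the four bins <10, 10–99, 100–999, ≥1000,
  with bin proportions defaulting to the real cohort's split
  (5817/6245/7657/743 of 20,462). Draws stay 5% (log-scale) inside bin
  edges so realized medians bin crisply.
* **Counts.** A latent Gaussian log-expression layer (SD 0.8 on the
  natural-log scale, ≈1.15 on log2 — typical tumor-cohort biological
  spread) carries the correlation structure: listed blocks share a common
  factor at correlation `block_rho`. Blocks are planted on features with
  target median ≥ 50 so count noise cannot swamp the planted correlation.
  Counts are negative-binomial around median × library factor ×
  exp(latent), with technical dispersion α = 0.05 (Var = μ + αμ²; the
  biological variation lives in the latent layer) and per-sample
  library-size factors log-normal at CV 0.3.
* **Survival.** Exponential times with log hazard equal to a linear
  combination of standardized latent expression — the simplest model
  satisfying proportional hazards, so Cox recovery is well defined.
  Prognostic features are assigned block-first (whole co-expression blocks
  before isolated singletons), mirroring cohorts where prognosis arrives
  as correlated programs; structural effects are N(0, log_hazard_sd²)
  with log_hazard_sd = 0.5 and are rescaled so the prognostic-index SD
  does not exceed `prognostic_index_sd` = 1.0 (per-SD hazard ratios of
  published breast-cancer signatures are ≈2–3; without the cap, hundreds
  of independent effects would make every marginal association
  undetectable). The truth table records each feature's exact marginal
  per-SD log hazard, Cov(z_f, η) — the quantity the univariate screen
  estimates. Censoring is administrative at a cutoff solved numerically so
  the expected event count hits the target (26 of 136 by default); an
  optional `censor_rate` adds uniform early dropout. The cohort's
  censoring-time distribution is not otherwise constrained.
* **Genome and reads.** A small synthetic genome (two 300-kb chromosomes
  by default) carries non-overlapping gene models and hidden transcribed
  intergenic loci ≥3 kb away from any gene, with log-normal expression.
  Reads are 50 bp (a round fixture length for short-read runs), Poisson in
  number per locus and patient, uniform in start position, never crossing
  a chromosome end, and labelled by patient.
* **Two platforms.** Paired noisy measurements of one set of true log
  hazard ratios, for exercising the concordance statistics.

One integer seed drives everything; identical configs give byte-identical
output.

What the generator does *not* emulate: FFPE degradation chemistry,
mapping ambiguity and strand errors, GC/length biases, non-proportional
hazards, or informative censoring. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to these real-data pathologies (the robust SE is expected, but
not shown here, to help with the latter two).

## Problem sizes used in validation

The replicated suites fix their own conditions: FDR control uses 100 null
cohorts of 2,000 features × 136 patients (26 expected events); estimator
recovery uses 200 cohorts of 500 patients × 50 features with one feature
driving the hazard at per-SD log HR = log 2 — a joint design in which
dozens of independent log-2 effects would be attenuated into
unrecoverability by their combined frailty, so one driver per cohort is
what makes "mean beta ≈ log 2" a well-posed check. RTM improvement is also
verified at the estimate level (effects N(0, 0.2²), SEs varied 0.1–0.4).
Interval operations are checked against brute-force oracles on 10-kb
fixtures; end-to-end intergenic recovery uses the default synthetic genome
(16 hidden loci, 8 patients, depth scale 8, at which every locus clears
the retention thresholds by construction).

## Known limitations

* With ties the robust SE is a Breslow-style approximation (percent-scale
  deviation); the point estimate remains fully Efron.
* The t-referenced Wald p is conservative in the extreme tail at very low
  event counts — the cost of FDR control there.
* π0 estimation at λ = 0.5 is noisy for small feature sets.
* At 26 events, genome-wide power against moderate effects is genuinely
  low: on default-structure synthetic cohorts many seeds identify nothing
  at FDR < 10%, which is the statistically honest behavior, not a defect.
* The merge-cutoff objective assumes annotated genes are transcribed;
  a cohort expressing few annotated genes would make the Jaccard surface
  flat and the tie-break (smallest candidate) decisive.
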