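# Methods

## The mixture model and its threshold

The observable is the per-patient difference Δ = lesional − non-lesional
epidermal thickness (μm), one biopsy pair per patient. Patients whose
lesional skin is not thicker than their non-lesional skin are excluded
before fitting (psoriatic plaques are hyperplastic by definition, so
Δ ≤ 0 indicates a measurement problem); the exclusion report lists every
removed patient and the reason.

Δ is modeled as a k-component univariate Gaussian mixture with unequal
variances. The EM fit uses:

* **Initialization** — evenly spaced sample quantiles for the means
  (restarts beyond the first add N(0, (sd(x)/2)²) jitter), uniform
  weights, overall SD for every component SD. The likelihood surface is
  multimodal; `n_restarts` (default 10 for final fits, 2–5 inside the
  bootstrap) with the best log-likelihood kept makes the optimum stable.
* **Variance floor** — component SDs are floored at 10⁻³·sd(x). Unequal-
  variance Gaussian mixtures have unbounded likelihood spikes when a
  component collapses onto a single point; the floor removes them the
  same way mainstream mixture packages do.
* **Convergence** — relative log-likelihood change < 10⁻⁸ (10⁻⁶ inside
  the bootstrap), cap 500 (800) iterations. The E-step is computed in log
  space; the log-likelihood trace is non-decreasing and is asserted so in
  tests.

**Model selection.** k is chosen by sequentially testing k vs k+1 with a
parametric bootstrap of the likelihood-ratio statistic 2(ℓ_{k+1} − ℓ_k):
each replicate simulates n observations from the fitted null model and
refits both models. The p-value uses the (1 + #{boot ≥ obs})/(B + 1)
convention, so it is never exactly 0 at finite B. B defaults to 1000 and
is scaled down to 99–199 in tests and the acceptance script purely to
keep desk runs short; calibration does not depend on B beyond p-value
granularity. Testing stops at the first non-rejection (α = 0.05; the
source analysis reports a rejection at p = 0.007 but states no α, so the
conventional level is used). A replicate whose EM fails to converge is
refit once with fresh restarts and counted; more than 10% retries raises
a warning.

**Threshold.** For k = 2 the thin/thick cut τ solves
λ₁N(x; μ₁, σ₁²) = λ₂N(x; μ₂, σ₂²). On the log scale this is a quadratic
in x when σ₁ ≠ σ₂ (linear when equal); the root strictly between the
component means is taken and verified by direct density evaluation
(relative difference < 10⁻⁸). When no root lies between the means (one
component dominates everywhere) a ThresholdError instructs the caller to
classify by posterior responsibility instead. *Thick* is defined strictly
above τ, so a patient sitting exactly on the threshold is labelled thin.
A fixed τ (e.g. the published 250 μm) can be imposed for reproduction
runs, in which case model selection is skipped entirely.

## Synthetic cohort generator

The generator encodes the cohort conditions reported for the 609-patient
study population and is the test bed for every downstream stage. Defaults:

| parameter | value | provenance |
| --- | --- | --- |
| n_patients | 609 | published cohort size |
| mix_weights | (285/609, 324/609) | published thin/thick counts |
| diff_means | (165.5, 360.8) μm | published lesional − non-lesional means |
| diff_sds | (60, 93) μm | published per-group dispersion row |
| nl_mean, nl_sd | 89.9, 24.7 μm | published NL mean; SD from the total SEM 1.0·√609 |

The published summary table prints a per-group "SEM" row of 59.6/93.4 μm
for lesional skin alongside a total SEM of 5.1 μm; these cannot both be
standard errors at the printed group sizes. Treating the per-group values
as SDs is the internally consistent reading — a mixture with those SDs
has total SD ≈ 125.5 μm, i.e. SEM ≈ 5.08 at n = 609, matching the printed
5.1 — and the non-lesional row, by the same arithmetic, is a true SEM.
The generator adopts that reading rather than asserting it about the
source. At these defaults the weighted component densities intersect at
≈ 250.8 μm, so a correct end-to-end run recovers the published threshold
to the nearest 10 μm.

Thickness values are drawn from untruncated Gaussians with negative draws
resampled. At the defaults the thin component mean sits 2.8 SDs above
zero, so the truncation bias is < 0.3% of that component's left tail and
far below sampling noise; the moment-convergence test bounds it.

**Expression.** One LS and one NL sample per subject. Signature genes
(half up, half down, default 200 of 2000) have E[LS − NL] = ±base_lfc
(1.5 log2 units) in thin subjects and ±amplitude·base_lfc (amplitude 1.6)
in thick subjects — the two groups share one signature dysregulated to
different degrees, which is the hypothesis the interaction contrast
tests. Subject random intercepts (SD 0.3) are shared by a subject's two
samples; residual noise SD 0.25; baselines uniform on (4, 12) log2 units
so the probe filter is exercised. What the generator does *not* emulate:
probe-level structure, correlated gene-gene noise, batch effects,
mean-variance trends, or missing pairs — so passing tests demonstrate the
estimators' correctness under the assumed model, not robustness to those
real-data features.

**Clinical tables.** Cell counts are intercept + slope × thickness +
noise, floored at 0 (slopes 0.15–0.35 cells/μm, noise SD 15 — chosen to
give the thick/thin LS separation a moderate signal at n≈60). Cytokines
are log-normal (log-mean 1.0, log-SD 0.7) with additive thick-group
shifts of 0.4 (TNF-α) and 1.0 (IL-6, IL-8) log units, mirroring the
reported pattern of a TNF-α trend and clearly higher downstream
cytokines. PASI courses have baseline N(21, 5²) clipped to (0, 72] —
moderate-to-severe disease — and week-12 values at (1 − improvement) ×
baseline with improvements 0.70/0.75 for the two biologics; TNF-α change
under treatment is thick-specific under etanercept (+0.6 vs +0.15 log
units) and shared under ustekinumab (−0.5), reproducing the reported
direction-of-effect pattern. Sub-tables draw from independently spawned
RNG streams of a single seed, so each table is reproducible on its own.

## Differential expression

With exactly one LS and one NL sample per subject, the mixed model
`y ~ tissue * group + (1 | subject)` decomposes into two orthogonal
strata: within-subject differences d = y_LS − y_NL (variance 2σ²_e) and
subject means m (variance σ²_b + σ²_e/2). Pooled within-group variances
of d and m give the REML estimates in closed form, vectorized across
genes; fixed effects are the cell means. Subjects with an incomplete pair
are dropped and counted. σ²_b is truncated at 0 when the subject-mean
variance falls below σ²_e/2 (the classical boundary case, equivalent to
collapsing to OLS) and flagged per gene. All contrasts use the residual
df n − 2 (n − 1 in the single-group reduction); the df a moderated mixed
model "should" use is not well defined, and this choice is exact for the
within-subject contrasts, which carry the biology of interest.

A consequence of pooling σ²_e across groups: the within-group LS-vs-NL t
equals the classical paired t-test exactly in a single-group study, and
equals the pooled-variance paired t in the two-group model. Both
identities are asserted in tests.

**Moderation.** Per-gene residual variances are shrunk toward a common
prior by the standard empirical-Bayes construction: the prior df d₀ and
scale s₀² are estimated by matching the mean and variance of log s² via
digamma/trigamma identities (trigamma inverted by bisection), and
s̃² = (d₀s₀² + d·s²)/(d₀ + d) replaces s² in each contrast's standard
error, with reference df d₀ + d. When the spread of log s² is no larger
than χ² sampling noise, d₀ = ∞ and the geometric-mean variance is used
for all genes (so identical input variances pass through unchanged). The
subject-variance component of between-group contrast SEs is left
unshrunk; only the residual part is moderated.

**Calling and summaries.** DEGs require |linear FC| > 2 AND p < 0.05 AND
FDR < 0.05 (Benjamini–Hochberg step-up, implemented from the definition
and cross-checked against an independent oracle). Negative fold changes
are reported as −2^|lfc| (signed convention). Because published overlap
percentages rarely define their denominator, the overlap report gives
both |A∩B|/|A∪B| (headline) and |A∩B|/min(|A|,|B|), plus the fraction of
an optional reference list called in both groups. Heatmap ordering uses
WPGMA (McQuitty) clustering on Euclidean distances via
`scipy.cluster.hierarchy.linkage(method="weighted")`, verified against a
brute-force implementation of the (d(u,w)+d(v,w))/2 update in tests.

## Transcriptome scores

Genes are standardized to mean 0, SD 1 across all samples pooled (LS and
NL on a common scale, as the score figures require); the population-SD
convention (divide by n) is fixed and matters only in the third decimal
of desk arithmetic. The per-sample score is w(Σ_up z − Σ_down z) with
w = 1/k by default; the combined z-score literature the method descends
from uses 1/√k, so `weight="sqrt"` is available and the convention used
is recorded with the scores. Up- and down-gene sub-scores are also
emitted (each with its own local k) in the *raw* orientation — the down
sub-score is the weighted mean z of the down genes, so it is negative
where those genes are suppressed, matching a down-regulation panel — and
the signed total satisfies total = up_part − down_part when all weights
use the combined k. Score group-comparisons reuse the paired mixed-model
machinery with scores as the response.

## Clinical models

Cell counts are compared by one-way ANOVA over the four group × tissue
cells per marker with Tukey's HSD post-hoc (scipy's studentized-range
implementation; Tukey–Kramer harmonic-mean handling of unequal cells);
markers with any cell under two observations are skipped with a warning.
Thickness regression is pure forward stepwise selection — at each step
the candidate with the smallest partial-F p-value enters if below
entry_alpha = 0.05; no removal step — with a condition-number guard
(10⁸) dropping collinear candidates. Because "partial correlation
measured by beta coefficients" is ambiguous, both standardized
coefficients and classical partial correlations are reported, labelled
separately. With m independent null candidates the probability that
nothing enters is (1 − α)^m, not a fixed 90%; the null-behavior test uses
a single candidate where the two coincide.

Serum cytokines are modeled on the log scale (concentrations are positive
and right-skewed; the modeling scale is an explicit, documented
assumption) as log c ~ group with a random intercept per study cohort
(statsmodels MixedLM). A single-cohort panel, or a singular mixed fit,
degrades to a pooled two-sample t-test with a warning and a method tag in
the output.

Treatment courses have two visits (weeks 0 and 12), so the mixed model
`PASI ~ week × group + (1 | patient)` within each treatment arm is
algebraically the paired model above with week 0 in the NL role; the
implementation reuses that closed form, which cannot fail to converge
even on degenerate (zero-variance) inputs. Least-squares means equal cell
means on the balanced grid; percent improvement is
100·(LSmean₀ − LSmean₁₂)/LSmean₀, invariant to rescaling PASI by a
positive constant. Cytokine change-from-baseline contrasts use the same
machinery on log concentrations; the reported estimate is the group
difference in change (the week × group interaction).

## Problem sizes and numerical choices

Test-suite and acceptance-script runs use scaled-down problem sizes
chosen as the package's own desk-scale defaults: B = 99–199 bootstrap
replicates (B = 1000 remains the library default), a 65-subject
expression subcohort with 2000 genes, and 100–200 simulation seeds for
calibration checks. Ties at the classification threshold go to thin;
ties in quantile normalization receive the average reference value; BH
uses a stable mergesort so permutation invariance is exact. All
randomness flows from `numpy.random.default_rng` seeds, spawned
hierarchically (SeedSequence) so each stage and sub-table is
independently reproducible.

## Known limitations

* The per-patient thickness data behind the published cohort table is
  distributed as a PDF supplement and is not bundled; the two
  reproduction tests that need it fail with an explanatory message unless
  the user supplies `data/s1_thickness.csv`.
* The expression model assumes complete LS/NL pairs and gene-wise
  independence; probe-set-level analysis, GCRMA preprocessing and GEO
  retrieval are out of scope, so published probe-set counts and
  GEO-dependent statistics (overlap percentage, r = 0.979, specific fold
  changes) are covered by direction-of-effect simulations only.
* The bootstrap LRT inherits EM's restart stochasticity; with very small
  B the p-value granularity (1/(B+1)) limits attainable significance.
* Forward selection replicates the stated procedure, not any particular
  statistical package's removal-step refinements.
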