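# Methods

## The joint log-normal model

Each patient is a vector x of p covariates. Continuous covariates are
positive biological quantities; categorical covariates are encoded as
consecutive integer codes starting at 1 (codes must be strictly positive
because the pipeline takes their logarithms). Continuous variables whose
observed minimum is ≤ 0 receive an automatic positivity offset
`1 − min(observed)`, recorded in the schema and removed again on output.

The encoded matrix is log-transformed elementwise and modelled as
multivariate normal with mean μ and covariance Σ, i.e. the data themselves
are multivariate log-normal. μ is the sample mean (1/n) and Σ the sample
covariance (1/(n−1)). A `legacy_mean` flag switches the mean to a
1/(n−1) normalisation, reproducing a variant of the estimator seen in some
published pipelines; it biases μ upward by n/(n−1) and is off by default.

Sampling uses the eigendecomposition Σ = U Λ Uᵀ and the sampling matrix
K = U Λ^{1/2}: a virtual patient is x' = exp(μ + K Z), Z ~ N(0, I_p).
Taking standard-normal latents *in log space* and exponentiating is the
standard log-normal construction: it reproduces Σ exactly in log space and
guarantees positivity, so no rejection filtering of "faulty" negative
draws is needed (rejection would distort the joint distribution and is
deliberately not implemented). Note the latent vectors are normal, not
log-normal: drawing literally log-normal latents inside x' = μ + K Z would
not reproduce Σ.

Numerical choices:

- Σ is symmetrised before decomposition; eigenvalues below
  `1e−12 · max(Λ)` (including tiny negatives from rounding on collinear
  covariates) are clipped to zero. After repair K Kᵀ = Σ within 1e−8.
- A Cholesky backend (Σ = L Lᵀ, K = L) is available; both factorizations
  satisfy K Kᵀ = Σ, so the sampled distribution is identical. For exactly
  singular Σ the Cholesky route adds the smallest diagonal jitter that
  lets the factorization succeed.

## Categorical discretization

Simulated categorical covariates come out continuous and are mapped to
integer codes by critical values (CrV). Two rules are provided:

- **midpoint** (default): the boundary between codes j and j+1 is
  (j + (j+1))/2, applied after the back-transform to the original scale —
  e.g. any simulated value in [0.5, 1.5) becomes code 1. Ties at a
  boundary go to the upper code (a measure-zero event needing only a fixed
  convention); the extremes are clamped, so discretization is total.
- **lognormal_quantile**: boundaries CrV(μ, σ, P) = exp(μ + σ Φ⁻¹(P)) with
  μ, σ the mean and SD of the log codes and P the cumulative empirical
  category proportions.

The two rules trade different invariances. The quantile rule is exactly
calibrated by construction: the generated category proportions equal the
source proportions up to Monte-Carlo noise. The midpoint rule — the
default, matching the established normal-system practice — thresholds a
Gaussian fitted to a two-point log-code distribution and therefore
mis-calibrates mid-prevalence binary variables by up to ~8 percentage
points; this is the size of real-vs-virtual categorical differences
typically reported for this class of generator and is visible in the
validation tables. Tests assert the ±3-point calibration property for the
quantile rule and the distributional (gof) agreement bound for the
midpoint default.

## Least-norm imputation

A source row with missing entries constrains only some components of
x' = μ + K Z, leaving an underdetermined linear system in Z. The latent
vector of least Euclidean norm ‖Z‖ = √(ΣZ_j²) satisfying the known-entry
constraints is computed with the Moore–Penrose pseudoinverse of the
known-row submatrix of K — for a consistent underdetermined system the
pseudoinverse solution *is* the least-norm solution, so no iterative
optimizer is involved. Missing entries are read off μ + K Z,
exponentiated, offset-corrected, and (for categoricals) discretized with
the same rules and tie convention as generation.

Properties and edge cases:

- Known entries are reproduced exactly (residual ≤ 1e−8 per row; the
  residual is reported per row). A rank-deficient known subsystem — possible
  when repaired eigenvalues are zero — is solved in the
  least-squares-then-least-norm sense and flagged by its residual.
- Because K Kᵀ = Σ, the least-norm reconstruction of the missing block
  equals the Gaussian conditional mean E[x_miss | x_obs] under the fitted
  model; imputation accuracy therefore grows with the strength of the
  correlations, and under weak correlations it degrades gracefully toward
  the (log-space) marginal mean.
- Chicken-and-egg: the model needed for imputation must itself be fitted
  on incomplete data. μ and Σ are estimated from pairwise-complete
  observations (each covariance from the rows where both covariates are
  present), the possibly indefinite result is projected to the PSD cone by
  eigenvalue clipping, and imputation runs once. An optional iterative mode
  refits on the completed cohort (at most 10 rounds, stopping when the
  largest cell change is below 1e−6).
- Imputation is single and deterministic; no multiple imputation or
  uncertainty quantification is attempted.

## Record linkage and population assembly

Datasets: A (virtual clinical records), B (geometry records), C (bridge
cohort carrying both). Each (A, C) and (B, C) pair receives an additive
matching weight: per compared field, an agreement weight if the comparator
agrees (exact equality for categorical fields, |a − c| ≤ tolerance for
numeric ones) else a disagreement weight; a missing field contributes 0.
Weights and thresholds are configuration — a helper derives
log₂(m/u)-style weights from labelled field statistics. For each bridge
record c_k the candidate sets V_AC^k, V_BC^k collect records whose weight
is *strictly* above the threshold (ties excluded). The assembled
population is the de-identified C (re-keyed ids, provenance `bridge`) plus
the Cartesian product V_AC^k × V_BC^k per c_k (provenance `linked`,
clinical fields verbatim from A, geometry fields verbatim from B), so its
size is |C| + Σ_k |V_AC^k|·|V_BC^k|. Raising a threshold can only shrink
the population; lowering thresholds is the intended dial for variety — no
noise is injected. No blocking/indexing is implemented; intended scales
are ≤ 10⁵ records.

## Validation metrics

Per variable: the two-sample Kolmogorov–Smirnov statistic
sup|F̂_real − F̂_virtual| (computed for categorical variables on the
integer codes — still a valid sup-difference on a discrete support), and
mean, SD (1/(n−1)), skewness m₃/m₂^{3/2} and kurtosis m₄/m₂². Kurtosis is
Pearson (normal → 3) by default with a Fisher (excess) toggle; the
convention is printed in the report header because published moment tables
rarely state theirs. Categorical variables additionally get a percentage
table per category. Correlation structure is compared by the elementwise
maximum absolute difference of the two Pearson correlation matrices of the
log-transformed encoded values. The report also carries a "legacy pooled"
block (pooled mean/SD of all data cells per cohort) mirroring a summary
style found in prior reports; it is descriptive only and is not a
correlation measure. Only the KS statistic itself is reported, not
p-values.

## Synthetic ground truth

`smartool_like()` emulates a ~186-patient coronary-CT cohort: 10 positive
continuous covariates specified by (typical value, log-SD) — age 60 y
(0.15), BMI 27 (0.15), LDL 130 mg/dL (0.30), HDL 48 (0.25), total
cholesterol 200 (0.20), triglycerides 140 (0.45), glucose 100 (0.18),
systolic BP 135 mmHg (0.12), creatinine 0.9 mg/dL (0.20), CRP 2 mg/L
(0.80) — and 10 binary risk factors at prevalences matching a published
coronary cohort (male 56.99%, family history 49.46%, current smoking
20.97%, past smoking 45.70%, diabetes 16.13%, dyslipidemia 69.35%,
hypertension 63.98%, metabolic syndrome 0.54%, obesity 17.74%, statins
46.77%). Binary covariates act through unit-variance latent Gaussian
columns cut at the quantiles of their prevalence. The correlation matrix
encodes plausible epidemiology (LDL–total cholesterol 0.85, BMI–obesity
0.8, glucose–diabetes 0.6, BP–hypertension 0.6, HDL–triglycerides −0.45,
…) and is projected to the nearest unit-diagonal PSD matrix.

What the generator does *not* emulate: measurement error and reporting
heaps, non-log-normal marginal shapes, missingness that depends on the
data (only MCAR masking is provided, with at least one observed cell per
row), and any mechanistic plaque biology — the geometry table is a
monotone random-increment stenosis curve per patient whose final value
exceeds the 50% stenosis inclusion filter, an explicit stand-in for a
mechanistic plaque-growth simulator, not a model of one. Passing tests
therefore demonstrate statistical self-consistency of the pipeline, not
clinical validity on real data.

For categorical columns the stored values are discretized codes, not the
latent draws, so latent-covariance recovery is asserted on the
continuous×continuous block; categorical columns are checked through their
marginal prevalences instead.

## Problem sizes and determinism

Tests and the acceptance script use a 186-patient source, 10,000-patient
virtual cohorts, 10⁴–10⁵-draw Monte-Carlo recovery checks and toy linkage
instances (≤ 5×5×5 against brute-force enumeration) — sizes chosen so the
full pipeline, including validation, runs in seconds on one CPU while
keeping Monte-Carlo bounds tight (recovery tolerances scale as
5·max(diag Σ)/√n). All randomness flows through explicit integer seeds
(one per generate/simulate call); the only random source in generation is
the latent draw.

## Known limitations

- The joint model is a single multivariate log-normal: no mixtures, no
  copulas, no conditional generation given fixed covariate values.
- Midpoint discretization biases mid-prevalence categorical marginals (see
  above); use the quantile rule when marginal calibration matters.
- Pairwise-complete moment estimation before imputation assumes enough
  jointly observed rows per covariate pair (≥ 2, and practically far more).
- Linkage weights are user configuration; the package supplies structure
  and defaults, not a fitted matching model.
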