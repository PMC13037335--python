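# Methods

## The polyconnectomic score

A disorder-specific connectome template assigns every connection (edge) of a
fixed parcellation a meta-analytic effect size β_i (Cohen's d contrasting
patients and controls).  Given an individual's functional connectivity
C_i — the Pearson correlation between the mean BOLD series of the two
parcels forming edge i — the polyconnectomic score (PCS) is the weighted
average over the informative edges:

    PCS = (1/n) * Σ_i β_i · C_i,     n = #{i : β_i ≠ 0}.

Only edges with a non-zero template weight enter the average; the test for
"non-zero" is exact equality against 0 (weights are stored values, not
computed quantities), with an optional tolerance knob that defaults to 0.
Correlations are used raw — no Fisher-Z transform — and no additional
scaling is applied to the score, so its units are d × r.  Higher values mean
stronger alignment of the individual connectome with the disorder-related
pattern; the score is a continuous alignment index, not a diagnosis.

Edge identity is pinned by one convention everywhere: the strict upper
triangle of the symmetric FC matrix, row-major, 0-based, so edge k is the
k-th pair (i, j) with i < j.  Templates are distributed as an edge TSV
(`parcel_i`, `parcel_j`, `weight`) plus a JSON sidecar naming the atlas,
the ordered parcel labels and the parcel → network partition; a symmetric
square-CSV form is accepted as an alternative.  Loading resolves labels
against the declared atlas, so scoring never depends on row order in the
file.

### Degenerate input policy

A parcel whose series has zero variance (or missing samples) has no defined
correlation.  Two policies are provided: `strict` (default) raises an error
naming the parcel; `lenient` zero-fills that parcel's correlations and logs
a warning.  Neither is claimed to match any particular study's handling —
published pipelines rarely state it.

### Template contribution summaries

Contribution analyses operate on the template alone.  `top_edges` ranks the
k strongest positive (descending) or negative (ascending) weights with ties
broken by canonical edge order.  `network_aggregate` folds the weights into
K × K within/between-network blocks over the partition; the default
statistic is the block **mean** (comparable across blocks of different
sizes), with **sum** retained because it conserves the template total — a
useful invariant check.  Which of the two a given published map's
network-level figures use is generally unstated; both are computed.

## Inference layer

All models honor family clustering with a random intercept per family
(`statsmodels` MixedLM, REML); the `ols` engine drops the random term for
unrelated samples such as the clinical arm.  Continuous variables are
z-scored (n−1 denominator) inside each fit so coefficients are standardized
betas; binary covariates stay 0/1.  Inference is Wald: z for mixed models,
t for OLS.  Satterthwaite-type degree-of-freedom corrections are not
implemented.

Moderation fits Y ~ X + W + X·W (+ covariates); the product is formed from
the z-scored X and W.  Two quantities summarise the interaction:

* **ΔR²** — the paper-style "increment in explained variance" has no single
  canonical definition for mixed models.  Here R² is the squared correlation
  between the fixed-effect predictions Xβ̂ and the observed outcome,
  differenced between the full and the no-interaction fit (clipped at 0).
  This fixed-effects (marginal-style) definition is engine-agnostic and
  reduces to the usual ΔR² under OLS.
* **Conditional slopes** — the simple slope of X at W = mean ± 1 SD, with
  delta-method standard errors from the fitted covariance of the estimates.
  By construction slope(+1 SD) − slope(−1 SD) = 2·SD(W)·β_interaction; this
  identity is asserted in the tests on every fit.

Non-convergence of a mixed fit is not an exception: the default optimizer is
tried first, then Powell, then an OLS fallback, and the result carries a
`converged` flag (the `lbfgs` path can step into regions where the profiled
covariance is singular, so it is avoided).

Change scores are follow-up minus baseline per variable, defined only for
subjects observed at both waves; subjects without follow-up are excluded and
counted, and a follow-up age not exceeding the baseline age is a hard
data-integrity error.  Follow-up duration (years) is the age difference.

Bonferroni correction multiplies p by the family size m (capped at 1), with
m = the number of outcomes in the analysis block: 2 for the emotional
outcomes, 6 for the cognition subscales.  Missing data are handled
complete-case per model.

Tertile subgrouping sorts scores (stable sort, so ties keep input order) and
cuts three groups whose sizes differ by at most one, the lower groups
absorbing the remainder.  The group ANCOVA is an OLS fit of score on the
group factor plus age and sex, reporting the type-II F test and
covariate-adjusted group means.

## The synthetic cohort

The generator produces the statistical skeleton the analyses need, with
known ground truth, at desk scale.  It emulates:

* **Family clustering** — twin pairs share a family intercept u ~ N(0, σ_f²)
  in every outcome, plus a shared age and follow-up interval.
* **A planted moderation structure** — on a standardized latent scale,
  symptom change follows
  Δ = b0 + b1·Δstress + b2·v + b3·Δstress·v + u_family + ε,
  with the analogous cross-sectional form at baseline; v is the latent
  vulnerability.  Cognition subscales couple to stress only weakly
  (coefficient 0.05), mirroring the near-null cognitive findings such
  designs typically produce.
* **A connectome readout of v** — each subject's parcel series are T draws
  from N(0, Σ(v)) with Σ(v) = Σ₀ + α·v·W̃, where W̃ is the symmetrized
  template weight matrix scaled to unit spectral norm and Σ₀ a
  well-conditioned base correlation (constant off-diagonal 0.05).  The PCS
  computed from the simulated series therefore increases in v by
  construction, making the score a noisy proxy of the true moderator.
* **Attrition** — follow-up keeps a fraction of subjects (default 298/407);
  deterministic thinning hits the count exactly, a stochastic mode keeps it
  in expectation.

Latent variables are mapped linearly onto instrument-like ranges (stress
22.10 ± 11.63, anxiety 24.79 ± 13.94, depression 4.25 ± 3.47, cognition
subscales ≈ 100 ± 15–21) so tables look like questionnaire data while
standardized coefficients remain directly comparable to the planted b
values.  An optional discretization mode rounds and clips to instrument
bounds for robustness checks; the default keeps Gaussian outcomes.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| families × twins | 204 × 2, roster truncated to 407 | the two-wave cohort scenario (407 baseline / 298 follow-up) |
| atlas parcels P | 20 | keeps the suite desk-fast; one 400-parcel, 7-network smoke test runs once |
| series length T | 600 | enough frames that sampling noise in C_i does not dominate the planted shift |
| b1, b2, b3 | 0.50, 0.20, 0.15 | moderate stress main effect, small vulnerability effect, small interaction; with σ_f = 0.45 and σ_ε = 0.66 the latent outcome variance is ≈ 1, so planted b's read as standardized betas |
| α (fc_coupling) | 0.30 | strong enough that the score tracks v (r ≈ 0.99 at T = 600), chosen for test power rather than physiological realism — no published anchor links score variance to symptom variance |
| v truncation | ± 3 SD | keeps Σ(v) inside the valid correlation cone at the default α, so ridge repair is a safety net, not a routine step |

When a shifted covariance does leave the positive-semidefinite cone, the
repair adds λI with λ = |min eigenvalue| + 1e−6 and renormalizes the
diagonal to 1; the relative Frobenius distortion is logged per subject and a
configurable bound (default 5%) turns excessive distortion into a
configuration error advising a smaller coupling.

The three alternative disorder templates used by the sensitivity stage
live on the same atlas but draw independent weights *and* rotate the
designated block structure onto different network pairs, so each map
targets a distinct connectivity motif; only the primary map shapes the
simulated covariance shift, making the alternatives behave as negative
controls.

The clinical-like arm is a small (n = 80), older, mostly-female,
cross-sectional sample of unrelated subjects whose latent vulnerability is
shifted up by 0.5 SD, with severity on clinical-instrument-like scales.

What the generator does **not** emulate: fMRI noise physics (drift, motion
spikes, physiological confounds), zygosity-specific genetic covariance
(family structure is a single random intercept), site or scanner effects,
floor/ceiling artifacts of real questionnaires (unless discretization is
on), and non-random attrition.  Passing tests therefore demonstrate that
the estimators are correct and calibrated under the stated model — not that
real adolescent cohorts satisfy that model.

## Reproducibility and problem sizes

Every random draw descends from one seed through named `SeedSequence`
streams (template, vulnerabilities, outcomes, attrition, time series,
clinical arm), so identical configurations give bit-identical cohorts and
two full pipeline runs produce byte-identical result tables; the run
manifest records a config hash, per-stage row counts, model formulas and
convergence counts (only its timestamp differs between runs).

The simulation-based checks in the test suite use 200 replicates at 400
subjects in 200 families for interaction recovery (bias < 0.03, CI coverage
≥ 90%), 500 replicates for type-I calibration of the interaction test
(rejection rate within (0.025, 0.075), mean ΔR² < 0.005), and a single
600-subject cohort for end-to-end recovery through the scoring path — sizes
chosen so the whole suite stays in the minutes range on one core while the
Monte-Carlo error of each check remains well under its assertion band.

## Known limitations

* Wald intervals for mixed models are first-order; small-family-count
  designs would warrant Satterthwaite or parametric-bootstrap refinements.
* The ΔR² definition is one defensible choice among several (marginal,
  conditional, OLS-style); values are comparable within this package, not
  across definitions.
* The score-vs-vulnerability correlation is deliberately high at the
  default coupling; real connectome scores are far noisier proxies of any
  latent liability, so real-data interaction estimates would attenuate far
  more than the end-to-end test exhibits.
* Scores are reported raw; any cross-cohort comparison of raw scores
  assumes identical preprocessing and acquisition, which the ANCOVA stage
  only partially addresses via covariates.
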