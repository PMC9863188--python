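# Methods

## Model

The core model is a latent class (finite mixture) model for J
categorical indicators. Individual *i* belongs to one of C unobserved
classes with prevalences γ (on the simplex); conditional on class *c*,
the indicators are independent and item *j* takes level *k* with
probability ρ<sub>j,k|c</sub>. The observed-data log-likelihood is

```
ℓ(γ, ρ) = Σ_i log Σ_c γ_c Π_{j ∈ obs(i)} ρ_{j, y_ij | c}
```

with the product over *observed* items only. Item-level missingness is
therefore handled under the missing-at-random assumption without
imputation: a missing item contributes an empty product (factor 1), and
a fully missing row contributes zero to the log-likelihood and has its
prior γ as posterior. Rows missing on *all* indicators are dropped at
the recoding stage (they carry no information and would otherwise
inflate n in the information criteria).

### Estimation

EM with multiple random starts:

- **Starts.** γ ~ Dirichlet(1), each ρ row ~ Dirichlet(1), each chain
  drawing from a spawned substream of a single master seed
  (`numpy.random.SeedSequence`), so a fit is a pure function of
  (data, C, n_starts, seed).
- **E-step** in log space; **M-step** in closed form; all chains advance
  together as one batched array computation and a chain freezes once
  converged. Default 100 starts, matching common practice for
  multimodal mixture likelihoods.
- **Convergence**: max absolute parameter change < 1e-6 *and* relative
  log-likelihood change < 1e-9, capped at 5000 iterations. These are
  deliberately strict defaults; the simulation suites relax them
  (tol 1e-5, fewer iterations) where the extra digits are irrelevant.
- **Boundary handling**: after every M-step probabilities are clipped to
  [ε, 1−ε] (ε = 1e-6) and renormalised, which keeps the log-likelihood
  finite on sparse cells at a negligible bias cost.
- **Ascent check**: EM guarantees a non-decreasing log-likelihood; a
  chain whose log-likelihood drops by more than 1e-8 is flagged as a
  numerical failure and excluded rather than silently kept.
- **Label switching**: classes are relabelled by descending γ (ties
  broken by the first item's last-level ρ) so replicate fits and
  recovery tests are comparable. Recovery tests additionally align
  fitted to generating classes by minimum-cost assignment on ρ, since
  prevalence order alone is ambiguous when γ values are close.
- **Degenerate classes**: a class whose posterior mass falls below
  1e-8·n kills that chain (not the whole fit); the best *converged*
  chain is returned, and the fit errors only if no chain converges.

### Model comparison

For each candidate C the sweep reports the degrees of freedom
(Π K_j − P − 1 with P = (C−1) + Σ_j C(K_j−1), computed in exact integer
arithmetic — 3<sup>16</sup>-scale numbers overflow no-where), the
likelihood-ratio statistic G² = 2(ℓ_sat − ℓ) against the saturated
multinomial over *observed* response patterns, AIC and BIC on both the
G² basis (AIC = G² + 2P) and the −2ℓ basis (AIC = −2ℓ + 2P), relative
entropy, smallest class prevalence, and the percentage of starts whose
final log-likelihood is within 0.01 of the best ("stability"; the
tolerance defines a tie in log-likelihood units). The two IC bases
differ by the constant 2ℓ_sat, so between-model differences are
identical; both are printed because software conventions differ. The
saturated term keys patterns on the missingness pattern as well, which
keeps G² well defined under partial missingness.

Relative entropy is E = 1 − Σ_i H(p_i)/(n ln C) with H the Shannon
entropy of a posterior row (0·log 0 ≡ 0); E is 1 for one-hot posteriors
and 0 for uniform ones, and is undefined at C = 1. The AvePP matrix
averages posterior columns within modal-assignment groups (ties to the
lower class index); diagonals above 0.7 are the conventional
"well-separated" reading. No criterion picks C automatically: the sweep
emits a report restating all criteria and the analyst chooses.

## Three-step (BCH) estimation

Modal assignment misclassifies a share of individuals, attenuating any
downstream association. The BCH correction estimates the
classification-error matrix D, D<sub>cj</sub> = Σ_i p<sub>ic</sub>
1(m_i = j) / Σ_i p<sub>ic</sub>, and gives individual *i* the weight
vector u_i = (D⁻¹)<sub>m_i,·</sub> over the C classes. Rows of D sum
to 1, hence rows of u sum to exactly 1; entries can be negative. D with
condition number above 1e8 is rejected with a message that separation
is too low for BCH.

- **Distal outcomes**: the class-c share of outcome category q is
  Σ_i u<sub>ic</sub> 1(Y_i = q) / Σ_i u<sub>ic</sub>. Negative cell
  estimates (possible with negative weights) are clipped to zero and the
  class renormalised, with a logged warning. 95% CIs come from a
  nonparametric bootstrap over individuals (default 500 resamples),
  reusing the fixed D — one mechanism that extends unchanged to the
  IP-weighted variant.
- **Covariate model**: a multinomial logistic regression maximising the
  weighted log-likelihood Σ_i Σ_c u<sub>ic</sub> log P(c | x_i; β),
  reference class defaulting to the largest. Because weights can be
  negative no standard GLM fitter applies; the likelihood is maximised
  directly by L-BFGS with analytic gradients, restarting from random
  perturbations if a (rare) non-concave surface stalls the first
  attempt, and |β| > 15 is reported as (quasi-)separation. Categorical
  covariates are dummy-coded against their first level. Odds ratios are
  exp(β) with bootstrap percentile CIs; p-values are deliberately not
  produced.
- **IP weights**: stabilized weights w<sub>ic</sub> = P̂(c)/P̂(c|x_i)
  from the fitted covariate model (marginal from the BCH-weighted class
  shares), multiplied onto u for the doubly weighted analysis. Balance
  is diagnosed by absolute standardized mean differences per dummy-coded
  covariate term and class contrast, before (BCH only) and after
  (BCH × IP); |SMD| < 0.1 is the conventional balance threshold. The
  SMD moments use the signed weights clipped at zero — pseudo-population
  moments need non-negative mass; the clip affects diagnostics only,
  never the estimates. Predicted class probabilities below 1e-6 abort
  with the offending individuals listed rather than producing extreme
  weights silently. Weight truncation beyond that guard is not applied.

The ordering is fixed: the covariate model is fitted with BCH weights
first, then reused to build IP weights.

## Recoding rules

- Combination ("any urinary" from 2 items, "any bowel" from 3): all
  observed responses never → never; else any often → often; else any
  sometimes → sometimes; else rarely. Missing source items are ignored
  (the rule applies to observed items only — a choice; the alternative
  of propagating any missingness would discard most of the signal in the
  pair); all-missing → missing.
- Collapse: never/rarely → 0, sometimes → 1, often → 2.
- Service windows: GP/specialist visits and admissions are counted in
  the half-open window [survey return date, +365 days) — half-open to
  avoid double-counting an anniversary-day visit; unique medications
  (distinct ATC level-5 codes) in the fixed 1 April – 30 September
  window of the survey year, which dodges the end-of-year safety-net
  stockpiling artefact in dispensing data.
- Admissions with a pregnancy-related primary diagnosis are excluded;
  the ICD-10 category range O00–O9A is tested on the three-character
  prefix with digits ordered before letters in the third position, so
  O9A is the inclusive upper bound (O9B is outside).
- GP visits are counted from provided visit dates; upstream claim-item
  filtering is an input contract, not this package's job. Jurisdictional
  under-capture of hospital records is likewise not modelled.

## Synthetic cohorts

The generator draws classes from γ, raw four-level responses
class-conditionally (source items within the urinary/bowel groups
independent given class — this is what makes the implied three-level
truth computable in closed form by enumeration, and is a documented
simplification), covariates from class-conditional categorical tables,
outcome bins from class-conditional distributions rendered as dated
visit/dispensing/admission records (with decoy records outside the
windows and pregnancy-coded decoy admissions, so the recode filters are
actually exercised), and item-level MCAR missingness at 2% by default.
MNAR mechanisms are out of scope: the fitting side assumes MAR, and the
generator emulates the data structure, not violations of that
assumption.

Scenarios (`scenario_library()`):

- **paper_like** — four classes at prevalences (0.366, 0.219, 0.262,
  0.153): a low-everything class, a menstrual-elevated/mood-suppressed
  class, a mood-elevated/menstrual-suppressed class, and an
  elevated-everywhere class, with a monotone service-use gradient
  across them. Default n = 7797 to reproduce realistic sampling noise
  at the analysed-cohort scale. The profile shapes and gradients are
  designed fixtures, not estimates.
- **high_separation** — concentrated profiles (≥ 0.8 on one level per
  item and class), near-balanced prevalences (0.30, 0.26, 0.24, 0.20);
  fitted entropy ≈ 0.99. Used for parameter-recovery checks, which it
  is sized to support: at n = 5000 the maximum elementwise ρ error is
  expected below 0.03.
- **low_separation** — three overlapping profiles calibrated to a
  fitted entropy around 0.65–0.70, the regime where modal assignment
  visibly attenuates associations and the BCH correction earns its
  keep.
- **null_covariates** — covariates drawn independently of class, for
  interval-calibration studies.
- **confounded** — strongly class-dependent covariates, for balance
  diagnostics.

Truth labels are returned separately and never written into pipeline
input files.

## What the simulations show — and what they don't

The test suite and `scripts/acceptance.py` verify, at simulation sizes
chosen to keep a full run in minutes on one CPU (sweep studies at
n = 1200 across 20 seeds and 20 starts; BCH replication at n = 1500
with 60 replicates and 200 bootstrap resamples; null-covariate
calibration at n = 2000 over 100 runs; recovery at n = 5000):

- exact degrees-of-freedom arithmetic and the BIC − AIC = P(ln n − 2)
  identity at n = 7797;
- likelihood agreement with brute-force pattern enumeration to 1e-10;
- EM ascent on every chain and recovery of the generating γ (±0.02) and
  ρ (±0.03);
- BIC selecting the generating class count in ≥ 80% of sweeps;
- unbiasedness of the BCH distal estimator at Monte-Carlo precision
  under entropy ≈ 0.7, with the naive modal estimator measurably
  attenuated toward the marginal (attenuation slope ≈ 0.85 vs ≈ 1.0),
  and bootstrap coverage in the 90–98% band;
- ~95% coverage of 1 by odds-ratio CIs under a null;
- post-IP-weighting |SMD| < 0.1 under confounding, and < 2 percentage
  points of difference between BCH and BCH+IP distal estimates when
  covariates are class-independent.

Passing these says the machinery is correct under its own generative
assumptions. It does not certify behaviour on real survey data, where
items are not conditionally independent within combined groups,
missingness need not be MCAR (nor MAR), covariate effects are not
categorical-table-shaped, and entropy, class shapes and class counts
are unknown. Those are properties of data, not of code; the scenario
parameters here are designed fixtures chosen once, not estimates of any
real cohort.

## Numerical choices and degenerate inputs

- Probabilities clipped at ε = 1e-6; posteriors computed via
  log-sum-exp; saturated log-likelihood from exact pattern counts.
- Modal-assignment ties break toward the lower class index,
  deterministically.
- Stability tolerance: 0.01 log-likelihood units.
- D condition-number guard: 1e8.
- Separation guard in the weighted multinomial logit: |β| > 15.
- Bootstrap: percentile intervals, resampling individuals; resamples
  that fail to fit (separation in a resample) are skipped.
- Empty indicator matrices, all-missing rows, single-category outcomes,
  n < C, K_j < 2 and off-simplex inputs all raise informative errors or
  have defined behaviour covered by tests.

## Known limitations

- The BCH variant implemented is the modal-assignment one (weights from
  D⁻¹ rows); posterior-proportional assignment and the ML three-step
  variant are out of scope.
- Bootstrap rather than sandwich standard errors throughout: one
  verifiable mechanism, at some computational cost.
- The generator's within-group conditional independence makes combined
  indicators slightly "cleaner" than real urinary/bowel items would be.
- No survey design weights, no longitudinal transitions, no record
  linkage: inputs are assumed already linked and keyed by participant.
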