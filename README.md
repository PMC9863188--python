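# symptomlca

Latent class analysis of recurring-symptom patterns and their association
with health-service use.

Symptom surveys ask how often each of a list of symptoms was experienced
(never / rarely / sometimes / often). Counting symptoms hides which ones
co-occur; latent class analysis (LCA) instead models the population as a
finite mixture of *C* classes, each with its own response profile. For
individual *i* with categorical indicators *y<sub>i1</sub> … y<sub>iJ</sub>*,

P(y_i) = Σ_c γ_c Π_j ρ_{j, y_ij | c}

where γ_c are class prevalences and ρ_{j,k|c} the item-response
probabilities, with items conditionally independent given class. The
package covers the full analysis workflow for this kind of study:

- **Recoding** (`symptomlca.recode`): 19 raw four-level symptom items →
  16 three-level indicators (a priority rule combines the two urinary and
  three bowel items into "any urinary" / "any bowel"; never and rarely
  are collapsed), plus recoding of linked administrative records into
  GP-visit, specialist-visit, medication-count and hospital-admission
  categories over fixed windows (pregnancy-coded admissions, ICD-10
  O00–O9A, excluded).
- **Model fitting** (`symptomlca.lca`): `LatentClassModel`, a
  scikit-learn-style estimator fitting the mixture by EM from many random
  starts, with item-level missingness handled under MAR (observed items
  only enter the likelihood).
- **Model comparison** (`symptomlca.selection`): G² against the saturated
  pattern multinomial, AIC/BIC on both the G² and −2·log L bases, relative
  entropy, average posterior probabilities (AvePP) by modal class, and
  multi-start stability. Class-count choice is left to the analyst.
- **Three-step associations** (`symptomlca.three_step`): the BCH
  correction — weight each individual's class pseudo-records by the rows
  of D⁻¹, where D is the modal-assignment classification-error matrix —
  feeding a weighted multinomial logistic regression (odds ratios with
  bootstrap CIs) and weighted distal-outcome tables, optionally combined
  with stabilized inverse-propensity weights and SMD balance diagnostics.
- **Synthetic cohorts** (`symptomlca.synthetic`): fully specified
  generative scenarios (raw responses, covariates, dated service records,
  missingness) with closed-form implied truth tables, since the real
  survey data this design targets are access-restricted.
- **Pipeline and CLI** (`symptomlca.pipeline`, `symptomlca.cli`):
  `symptomlca simulate|recode|sweep|threestep|distal|run`, tidy-CSV
  artifacts and a manifest for bit-identical re-runs.

## Worked example

Simulate a four-class cohort (n = 2000) and sweep one- to six-class
models:

```sh
symptomlca simulate --scenario paper_like --n 2000 --seed 42 --outdir demo/
```

```python
import pandas as pd
from symptomlca import build_indicator_matrix, fit_sweep, avepp_matrix
from symptomlca.selection import selection_report

survey = pd.read_csv("demo/survey.csv")
indicators = build_indicator_matrix(survey)
table, fits = fit_sweep(indicators, C_range=range(1, 7), n_starts=20, seed=42)
print(selection_report(table, avepp_matrix(fits[4].result_.posteriors)))
```

```
Model comparison (choose C by judgement, not by a single criterion):
  C=1: AIC(G2)=30765.46 BIC(G2)=30944.69 entropy=undefined smallest class=1.000 stability=100%
  C=2: AIC(G2)=25135.06 BIC(G2)=25499.12 entropy=0.936 smallest class=0.400 stability=80%
  C=3: AIC(G2)=21773.57 BIC(G2)=22322.46 entropy=0.966 smallest class=0.162 stability=100%
  C=4: AIC(G2)=19987.00 BIC(G2)=20720.71 entropy=0.948 smallest class=0.161 stability=90%
  C=5: AIC(G2)=19976.38 BIC(G2)=20894.93 entropy=0.949 smallest class=0.015 stability=15%
  C=6: AIC(G2)=19981.56 BIC(G2)=21084.93 entropy=0.953 smallest class=0.007 stability=5%
  AvePP diagonal: [0.966, 0.981, 0.965, 0.996] (all > 0.7)
```

BIC is minimised at four classes; the five- and six-class models buy a
tiny AIC gain at the price of a near-empty class and collapsing
stability — the pattern an analyst reads as "choose 4". The fitted
prevalences `fits[4].gamma_` come back as `[0.357 0.259 0.224 0.161]`,
recovering the generating values (0.366, 0.262, 0.219, 0.153) to within
sampling error. From there, `bch_weights` / `bch_multinomial_regression`
/ `bch_distal` estimate covariate and service-use associations corrected
for the residual classification error, and `symptomlca run --config …`
executes the whole chain with a reproducibility manifest.

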