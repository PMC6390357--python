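# illdeath

Illness-death frailty modelling of local control (LC) and overall survival
(OS) after stereotactic body radiotherapy (SBRT) for colorectal liver and
lung metastases.

## The problem

After SBRT of an oligometastatic colorectal cancer patient, two outcomes
compete and interact: a treated lesion may regrow (local failure) and the
patient may die — possibly *because* local control was lost.  Treating
local failure as an ordinary covariate conflates these processes.  This
package models them jointly as a three-state **illness-death model**,

```
  treated ──h1──> local failure
     │                 │
     h2                h3
     ▼                 ▼
   death             death
```

with proportional cause-specific hazards per transition g ∈ {1, 2, 3}:

```
h_g(t | x, w_i) = h_0g(t) · exp(xᵀβ_g + w_ig),        w_ig ~ N(0, σ_g²)
```

where `w_ig` is a shared random intercept ("frailty") of the treating
hospital i, accounting for between-centre heterogeneity in a multicentre
registry.  The death hazard switches from `h2` to `h3` when the first
relapse occurs, on the shared time-since-treatment clock (Markov,
clock-forward).  Transition 1 is lesion-level, transitions 2–3
patient-level; transition 3 uses delayed entry at the relapse time.

Key ingredients, all implemented here:

* **BED dosimetry** — prescriptions `n × d Gy @ X%` are mapped to the
  biologically effective dose at the isocenter,
  `BED_iso = n·d·(1 + d/(α/β))` with `d` the isocenter fraction dose and
  α/β = 10 Gy, and back (quadratic inversion to a schedule).
* **Frailty Cox regression** — maximum integrated partial likelihood via
  the Laplace approximation: an inner Newton step over (β, w), an outer
  profile over σ², Breslow ties, delayed entry, Wald inference.
* **Penalized M-spline baseline hazards** — `h_0g(t) = Σ c_k M_k(t)` on
  cubic M-splines (c_k ≥ 0), maximum penalized full likelihood with
  curvature penalty κ∫h₀″², κ chosen by an approximate
  leave-one-out cross-validation score; 9 knots per transition.
* **Predictions** — tumour control probability TCP(t|x) =
  exp(−H₀₁(t)·e^{xᵀβ₁}); the dose achieving a target TCP (inverted
  through the 2-SD standardisation of BED and converted to a schedule);
  the explanatory baseline hazard ratio h₀₃/h₀₂ over time; cumulative
  probabilities of dying without/after relapse by Gauss–Legendre
  quadrature; 95% bands from 500 Monte-Carlo parameter draws.
* **Cohort preparation** — counting-process datasets, 2-SD
  standardisation of continuous covariates, chained-equation imputation
  (predictive mean matching, correlation-and-usability predictor screening, Rubin
  pooling), Fisher/Wilcoxon descriptives.
* **Synthetic cohorts** — a fully parameterised generator of clustered
  illness-death registries (27 hospitals, ~388 patients, ~500 lesions by
  default, with registry-like covariate marginals, censoring and
  covariate missingness), so every estimator is testable against known
  truth.

## Worked example

```python
import numpy as np
from illdeath import (paper_like_config, simulate_illness_death,
                      build_transition_datasets, fit_frailty_cox,
                      fit_penalized_hazard, tcp_curve, dose_for_tcp,
                      average_profile)

cfg = paper_like_config(seed=1)
cohort = simulate_illness_death(cfg)
# 387 patients, 499 lesions, 115 local failures, 216 deaths

ds = build_transition_datasets(cohort.lesions, cohort.patients)
fit1 = fit_frailty_cox(ds[1])          # treatment -> local failure
print(fit1.summary()[["hr", "hr_lo", "hr_hi", "p"]].round(3))
```

```
                    hr  hr_lo  hr_hi      p
site_lung        0.445  0.282  0.703  0.001
chemo            2.600  1.344  5.028  0.005
volume_std       1.618  1.018  2.573  0.042
motion_advanced  0.733  0.479  1.122  0.153
algo_advanced    1.146  0.780  1.685  0.488
bed_std          0.357  0.235  0.543  0.000
```

Hazard ratios are per 2 SD for the standardised continuous covariates:
higher BED strongly protects against local failure (HR 0.36), lung
lesions fail less often than liver lesions (HR 0.45), prior chemotherapy
raises the failure hazard (HR 2.6) — the generator's built-in effects,
recovered from one simulated registry.  The fitted hospital frailty
variance here is 0.018.

```python
spl = fit_penalized_hazard(ds[1], kappa=1e5, sigma2=0.0)
prof = average_profile(ds[1])          # mean/mode covariate profile
band = tcp_curve(spl, prof, np.array([12.0, 24.0]), mc_samples=500, seed=1)
# TCP = 0.814 at 1 year, 0.706 (95% band 0.625-0.803) at 2 years

rx, bed = dose_for_tcp(spl, prof, target_tcp=0.9, horizon=24.0,
                       n_fractions=3, prescription_isodose=65.0)
# BED for 90% TCP at 2 years: 244.6 Gy10  ->  3 x 15.6 Gy @ 65%
```

The same stages are available from a shell:

```bash
illdeath bed -n 5 -d 13 -i 65        # BED_iso = 300.0 Gy_10
illdeath schedule -b 300 -n 5 -i 65  # 5 x 13.0 Gy @ 65%
illdeath simulate --seed 1 --out cohort/
illdeath run-all --seed 1 --out run/   # full analysis with reports
```

`run-all` writes the cohort tables with a data dictionary, a
Table-1-style descriptive comparison, pooled per-transition hazard-ratio
tables, the dose-for-TCP table, and delimited-text figure data for the
TCP curves, the baseline hazard ratio over time and the cumulative
transition probabilities, plus a manifest with config hash and seed.

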