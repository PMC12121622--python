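# zicount

Zero-inflated and hurdle count regression for colonoscopy polyp data — and,
more generally, for any zero-heavy count outcome compared between two groups.

## The problem

Colon-cancer screening studies record, for each patient, the number of
polyps detected at colonoscopy.  Most analyses dichotomize this count into
"any polyp vs none" (a logistic regression on the polyp detection rate,
PDR) or feed the raw counts to a Poisson or negative binomial regression.
Both lose information, because the zeros are a *mixture*: a zero can mean
the patient truly has no polyps (a structural zero), or that an existing
polyp was missed by the procedure (a sampling zero).  With more than half
of subjects at zero, single-distribution count models absorb the structural
zeros into the count mean and attenuate group effects toward the null.

A zero-inflated model separates the two processes:

```
P(Y = 0) = π + (1 − π)·f(0)          logit(π) = b₀ + b₁X₁ + … + bₙXₙ
P(Y = y) = (1 − π)·f(y),  y > 0      log E(Y | no excess zero) = β₀ + β₁X₁ + …
```

where `f` is Poisson, NB2 (variance μ + αμ²), or generalized Poisson.
Exponentiated count-part coefficients are risk ratios (RR) for the number
of detected polyps; exponentiated inflation-part coefficients are odds
ratios (OR) for an excess zero.  The hurdle variant instead routes *all*
zeros through a logistic part and models positives with a zero-truncated
count distribution, so its binary part is an ordinary logistic regression.

`zicount` implements the full workflow:

* **ten models** — LR, PR, RP (Poisson + Huber–White sandwich variance),
  NB, GP, ZIP, ZIRP (ZIP + sandwich), ZINB, ZIGP, ZHP, ZHNB — all fit by
  direct maximum likelihood with analytic gradients;
* **diagnostics** — score test for zero inflation, bias-corrected Vuong
  test, deterministic excess-zero removal, auxiliary-regression and NB2
  boundary dispersion tests, chi-square goodness of fit on count
  categories, AIC/BIC, and a model-selection flowchart;
* **marginal standardization** — G-computation of the marginal PDR
  difference and marginal odds ratio, harmonizing the estimand across all
  model families, with seeded percentile-bootstrap CIs;
* **a simulation engine** — the Bernoulli × count generative design
  (structural-zero probability TZ, count-component zero mass calibrated to
  SZ) and a Monte Carlo evaluator reporting bias, relative bias, mean 95%
  CI width, and coverage.

## Worked example

```python
import numpy as np
from zicount import REFERENCE_SCENARIOS, fit_model, generate_dataset

data, _ = generate_dataset(REFERENCE_SCENARIOS[1], seed=2024)   # N=425, ~61% zeros
for kind in ["PR", "ZIP"]:
    m = fit_model(kind, data)
    b, lo, hi = m.group_effect("group", part="count")
    print(kind, f"RR = {np.exp(b):.2f} [{np.exp(lo):.2f}-{np.exp(hi):.2f}]")
```

prints (true count-part effect exp(0.40) = 1.49):

```
PR RR = 1.13 [0.92-1.38]
ZIP RR = 1.49 [1.16-1.93]
```

The Poisson RR is attenuated toward 1 because half the sample are
structural zeros; the ZIP count part recovers the effect among subjects at
risk of polyps.  `examples/` contains short scripts for each capability
(model comparison, flowchart selection, marginal PDR contrast, Monte Carlo
estimator evaluation), and a `zicount` command-line tool exposes the same
workflow for CSV inputs (`zicount fit/diagnose/compare/select/simulate`).

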