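"""Small Monte Carlo comparison of estimators on a zero-inflated scenario.

Scenario: N = 425, 52.5% structural zeros, Poisson counts with 18% zero
mass, true count-part group coefficient 0.40.  Single-distribution models
are biased (they absorb structural zeros into the count mean) and
under-cover; correctly specified zero-inflated fits are unbiased with
near-nominal coverage.  100 replications here for speed — the reference
evaluation uses 1000.
"""

from zicount import REFERENCE_SCENARIOS, run_monte_carlo
from zicount.simulate import summary_table

results = run_monte_carlo(REFERENCE_SCENARIOS[1], ["PR", "RP", "ZIP", "ZIRP", "ZHP"],
                          n_replications=100, seed=11)
print(summary_table(results).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nbias = mean(beta_hat) - 0.40; coverage = fraction of 95% CIs "
      "containing 0.40 (nominal 0.95).")
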