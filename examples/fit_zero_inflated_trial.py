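"""Fit the ten candidate models to one synthetic colonoscopy trial.

Builds a randomized-trial-like dataset (425 subjects, ~61% of them with no
polyps: 52.5% structural zeros plus Poisson counts whose zero mass is 18%)
and contrasts the group effect across model families.  The count-part RR of
the zero-inflated fits estimates the effect on the number of detected
polyps among subjects without a structural zero; the single-distribution
RRs are attenuated because they treat every zero as a low count.
"""

import numpy as np

from zicount import REFERENCE_SCENARIOS, fit_model, generate_dataset

data, _ = generate_dataset(REFERENCE_SCENARIOS[1], seed=2024)
print(f"N = {data.n_subjects}, zero fraction = {(data.outcome == 0).mean():.3f}, "
      f"true count-part group coefficient = {REFERENCE_SCENARIOS[1].true_beta}\n")

print(f"{'model':<6} {'RR (count part)':<22} {'OR (zero part)':<22}")
for kind in ["PR", "RP", "NB", "ZIP", "ZIRP", "ZINB", "ZHP", "ZHNB"]:
    m = fit_model(kind, data)
    b, lo, hi = m.group_effect("group", part="count")
    rr = f"{np.exp(b):.2f} [{np.exp(lo):.2f}-{np.exp(hi):.2f}]"
    if m.n_inflate:
        ob, olo, ohi = m.group_effect("group", part="inflate")
        orr = f"{np.exp(ob):.2f} [{np.exp(olo):.2f}-{np.exp(ohi):.2f}]"
    else:
        orr = "-"
    print(f"{m.kind:<6} {rr:<22} {orr:<22}")

print("\nThe inflated/hurdle count-part RRs bracket exp(0.40) = "
      f"{np.exp(0.4):.2f}; the single-distribution RRs are pulled toward 1 "
      "by the excess zeros.")
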