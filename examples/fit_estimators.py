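"""Fit all causal estimators to one simulated clustered dataset.

Simulates one draw from the heavily-confounded study design (80% of
clusters observed in a single treatment arm), then estimates the average
causal effect Delta = beta1 - beta0 with plain IPTW, trimming, the two
augmented estimators and the nonparametric contrast.
"""

import aiptw

cfg = aiptw.PRESETS["setting1_80"]       # beta = (35, 40), so true Delta = 5
coeffs = aiptw.calibrate_assignment(cfg)
gen = aiptw.generate_dataset(cfg, coeffs, seed=7)
data = gen.dataset

print(f"dataset: {data.n_units} units in {data.n_clusters} clusters, "
      f"{gen.violating_fraction:.0%} of clusters in one arm only\n")
print(f"{'estimator':<22}{'beta0_hat':>10}{'beta1_hat':>10}{'delta_hat':>10}")
for name, est in [
    ("IPTW (original)", aiptw.iptw_orig(data)),
    ("IPTW (trimmed)", aiptw.iptw_trim(data)),
    ("AIPTW-SATC", aiptw.aiptw(data, model="satc")),
    ("AIPTW-RSATC", aiptw.aiptw(data, model="rsatc")),
    ("AIPTW nonparametric", aiptw.aiptw_nonparametric(data)),
]:
    print(f"{name:<22}{est.beta0_hat:>10.3f}{est.beta1_hat:>10.3f}"
          f"{est.delta_hat:>10.3f}")

print("\nbeta0/beta1 are the population control/treated arm means "
      "(truth 35 and 40); delta is the average causal effect (truth 5). "
      "On a single draw every estimate carries sampling noise of a few "
      "points; the augmented estimators remove the systematic part that "
      "confounded single-arm clusters induce.")
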