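"""Small Monte Carlo comparison of estimator bias under confounding.

Replicates the second study design with opposite-signed confounding
(treatment positively correlated with the control-arm effect, negatively
with the treated-arm effect) and reports percentage bias and empirical SE
for each estimator.  Uses 60 replicates for a quick desk run; the shipped
metric grids use hundreds.
"""

from aiptw import PRESETS, run_replications

cfg = PRESETS["setting2_r4m4"]           # beta = (12, 15)
rep = run_replications(cfg, methods=("iptw_orig", "iptw_trim", "aiptw_satc",
                                     "aiptw_rsatc"),
                       R=60, master_seed=5, se="none")

print(f"{'estimator':<14}{'pb(beta0)':>10}{'pb(beta1)':>10}"
      f"{'s_se(beta0)':>12}{'s_se(beta1)':>12}")
for m in ("iptw_orig", "iptw_trim", "aiptw_satc", "aiptw_rsatc"):
    print(f"{m:<14}"
          f"{rep.metric(m, 'beta0', 'pb'):>10.3f}"
          f"{rep.metric(m, 'beta1', 'pb'):>10.3f}"
          f"{rep.metric(m, 'beta0', 's_se'):>12.3f}"
          f"{rep.metric(m, 'beta1', 's_se'):>12.3f}")

print("\npb is (mean estimate - truth)/truth, so 0.01 = 1% bias. Plain "
      "IPTW is strongly biased for the treated arm here; trimming trades "
      "bias for much larger variance; SATC augmentation keeps the "
      "control arm nearly unbiased.")
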