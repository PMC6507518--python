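"""Inspect propensities, IPT weights and the data augmentation step.

Builds a tiny clustered dataset by hand, shows the per-cluster empirical
propensities and unit weights, then augments the single-arm cluster with a
model-predicted pseudo-observation and shows how the weights change.
"""

import numpy as np

from aiptw import (ClusteredDataset, build_augmented_data,
                   compute_unit_weights, estimate_propensity,
                   summarize_clusters)

data = ClusteredDataset(
    cluster_id=np.array(["s1"] * 6 + ["s2"] * 4 + ["s3"] * 5, dtype=object),
    t=np.array([1, 1, 0, 0, 0, 0,  1, 0, 0, 0,  0, 0, 0, 0, 0]),
    y=np.array([9.5, 10.2, 6.0, 6.4, 5.8, 6.1,
                8.8, 6.2, 5.9, 6.3,
                5.5, 6.0, 5.7, 6.2, 5.9]))

summaries = summarize_clusters(data)
prop = estimate_propensity(summaries)
print(f"normalization constant c = N1/N = {prop.N1}/{prop.N} = {prop.c:.3f}")
for s in summaries:
    print(f"  cluster {s.cluster_id}: n={s.n} treated={s.n1} "
          f"pi_hat={s.n1 / s.n:.2f} status={s.status}")

ws = compute_unit_weights(data, prop)
codes, labels = data.cluster_codes()
print("\nper-cluster weight sums (mixed clusters sum to n_k):")
for j, lab in enumerate(labels):
    print(f"  {lab}: sum w = {ws.w[codes == j].sum():.3f}")

aug = build_augmented_data(data, model="rsatc")
print(f"\naugmentation added {aug.n_violating} pseudo-row(s):")
for lab, pred in aug.predictions.items():
    print(f"  cluster {lab}: predicted missing-arm outcome = {pred:.3f}")
prop_a = estimate_propensity(summarize_clusters(aug.dataset))
print(f"augmented propensity for s3: {prop_a.pi_for('s3'):.3f} "
      "(= 1/6, strictly inside (0,1) so the cluster now contributes "
      "to both arm estimates)")
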