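"""Derive and inspect applicability-domain exclusion rules.

A cluster of 8 chemicals with a distinct descriptor signature (f > 2) is
given 10x larger LOOCV errors; the CART-on-errors procedure should isolate
them in one conjunctive rule and exclude them from the domain.
"""

import numpy as np

import placperm as pp

rng = np.random.default_rng(0)
n, n_cluster = 60, 8
f = rng.uniform(-1.0, 1.4, size=n)
f[:n_cluster] = rng.uniform(2.0, 3.0, size=n_cluster)  # the odd cluster
g = rng.normal(size=n)
ci = np.abs(rng.normal(1.0, 0.5, size=n))
err = np.abs(rng.normal(0.05, 0.01, size=n))
err[:n_cluster] *= 10
loocv_preds = ci + rng.choice([-1.0, 1.0], size=n) * err

table = pp.DescriptorTable(
    chemical_ids=[f"chem_{i}" for i in range(n)],
    feature_names=["f", "g"],
    values=np.column_stack([f, g]),
    ci=ci,
)
ad = pp.derive_ad(table, ["f", "g"], loocv_preds, threshold=0.01)

for rule in ad.rules:
    conds = " AND ".join(str(c) for c in rule.conditions)
    print(f"{rule.id}: exclude if {conds}  "
          f"(leaf mean |error| {rule.leaf_mean_abs_error:.3f}, "
          f"matches {rule.n_train_matched} training chemicals)")
print(f"training coverage: {ad.training_coverage:.2%}")

in_ad, matched, coverage = pp.apply_ad(ad, table)
print(f"excluded chemicals: {[i for i, ok in enumerate(in_ad) if not ok]}")
# The rule threshold lands in the gap between the cluster (f > 2) and the
# rest (f < 1.4); excluding those chemicals raises the retained-set r, which
# is exactly the acceptance test each candidate rule must pass.
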