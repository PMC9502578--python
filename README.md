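# placperm

QSAR modelling of **ex vivo human placental barrier permeability**.

Chemicals that cross the placenta can harm the fetus, but measuring
placental transfer in vivo is rarely possible. Ex vivo placental perfusion
experiments report a **clearance index**

> CI = clearance of the chemical / clearance of antipyrine,

a dimensionless, nonnegative permeability relative to the antipyrine
reference. `placperm` builds predictive CI models from precomputed 1D/2D
molecular descriptors (e.g. PaDEL tables) in the regime such data actually
comes in — tens of chemicals, hundreds of descriptor columns:

* **pruning** of useless descriptors (extreme values, ≥30% zeros, <12
  distinct values),
* **z-score normalization** with training-derived parameters only,
* **sequential forward selection** driven by leave-one-out cross-validated
  Pearson r, stopping when one more descriptor gains < 0.01 in r,
* a **voting ensemble** ŷ = ½·OLS(x) + ½·forest(x) of ordinary least
  squares and bagged unpruned regression trees (all features per split),
* a **rule-based applicability domain** (AD): a CART tree fitted to the
  training LOOCV errors yields conjunctive exclusion rules, accepted
  greedily while they raise the retained-set correlation — derived from
  training data only, no information leak from test chemicals,
* **variation-aware external evaluation** against reported CI and the
  minimum CI (mCI) within experimental variation.

A synthetic-data generator reproduces the statistical structure of such
tables (planted informative descriptors, noise, filter decoys) so the whole
pipeline is testable without any proprietary data.

## Worked example

```python
import placperm as pp

# 66 chemicals x 120 descriptors: 5 informative, 95 noise, 20 filter decoys
table, truth = pp.generate(pp.SyntheticSpec(seed=3, n_noise=15))

config = pp.RunConfig(model=pp.ModelSpec(kind="ensemble", n_trees=30, seed=1))
art = pp.run_train(table, config)

print(art.trace.selected)
print(f"fit r = {art.eval_fit.pearson_r:.3f}, "
      f"LOOCV r = {art.eval_loocv['pearson_r']:.3f}, "
      f"AD coverage = {art.ad.training_coverage:.2%}")
```

prints

```
['sig_02', 'sig_01', 'sig_03', 'sig_05', 'sig_04']
fit r = 0.990, LOOCV r = 0.958, AD coverage = 100.00%
```

Selection found exactly the five planted informative descriptors (`sig_*`)
and none of the 35 irrelevant columns that survived filtering. The fitting
correlation (0.990) exceeds the LOOCV correlation (0.959), as expected —
the forest half of the ensemble partially memorizes its training set, and
the LOOCV value is the honest estimate for unseen chemicals. An empty
exclusion-rule set (coverage 100%) means no region of descriptor space
showed systematically inflated cross-validation errors.

The scripts in `examples/` walk through each capability: filtering,
ensemble training and feature ranking, applicability-domain rules, and
variation-aware external evaluation. A thin CLI mirrors the workflow:

```bash
placperm simulate --seed 7 --out table.csv
placperm train table.csv --kind ensemble --seed 1 --out-dir run/
placperm predict new.csv --model run/model.json --training-table table.csv \
    --ad run/ad_model.json --out preds.csv
placperm evaluate new.csv --predictions preds.csv
```

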