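"""Summarise treatment-effect heterogeneity: BLP, CLAN and importance.

Run after fitting the forest and constructing doubly robust scores; the
planted modifier x1 should dominate every summary.
"""

import warnings

import ivforest as iv

sds = iv.generate(iv.make_config("planted_binary", n=4000, seed=7))
ds = sds.dataset
params = iv.ForestParams(num_trees=200, min_node_size=25, seed=1)
nu = iv.estimate_nuisances(ds, params, exclude_supply_from_e=False)
model = iv.fit_iv_forest(ds, nu, params)
clates = iv.predict_clate(model)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    cs = iv.compliance_score(ds, nu, params)
gamma = iv.dr_score(ds, clates, nu, cs)

print("Best linear predictor of the scores (partial associations):")
print(iv.blp(gamma, ds.x).table.round(3))

print("\nClassification analysis (most vs least affected quartile, "
      "ranked by the estimated CLATE):")
print(iv.clan(gamma, ds.x, rank_by=clates.tau).table.round(3))

print("\nSplit-frequency variable importance (ranking only is meaningful):")
print(iv.variable_importance(model).top(5).round(3))
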