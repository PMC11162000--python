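"""Full pipeline on the default synthetic study.

150 compounds and 30 proteins in 3 archetypes, 5% label-flip noise, 1:10
positive:negative imbalance; held-out entities (20%) form an
entity-disjoint test set attached transductively to the training graph.
Takes ~half a minute.
"""

from sgcpi.pipeline import RunConfig, run_end_to_end

result = run_end_to_end(RunConfig())
print(f"train pairs: {result.n_train}, held-out pairs: {result.n_test}")
for name, value in result.test_metrics.items():
    print(f"  {name:<10} {value:.4f}")
print("propagation precomputes:", result.model_info["propagation_precomputes"])
# AUC/AUPR well above the 0.09 positive prevalence show the 3-hop pure
# SGC recovers the planted archetype-compatibility signal on unseen
# compounds and proteins; precision/recall use a fixed 0.5 threshold and
# are conservative under imbalance.
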