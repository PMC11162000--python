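"""Ablation harnesses: stack combinations and class imbalance.

Uses a reduced fixture (60 compounds, 18 proteins) so the sweeps finish
in about a minute. Stack rows share one fixture and embedding table, so
differences reflect the classifier alone; the imbalance sweep
regenerates fixtures at each positive:negative ratio.
"""

from sgcpi.embedding import SkipgramConfig
from sgcpi.models import TrainConfig
from sgcpi.pipeline import RunConfig, ablate_imbalance, ablate_stacks
from sgcpi.synthetic import SynthConfig

cfg = RunConfig(
    synth=SynthConfig(n_compounds=60, n_proteins=18, seed=5, seq_length_range=(60, 100)),
    embed=SkipgramConfig(d=32, epochs=6, window=4),
    train=TrainConfig(epochs=80, patience=None),
    knn=8,
    seed=5,
    split_mode="pair_disjoint",
)

stacks = ablate_stacks(cfg, ["SGCN", "SGCN+SGCN+SGCN", "GCN+SGCN+SGCN", "GCN+GCN+GCN"])
cols = ["stack", "auc", "aupr", "propagation_precomputes", "total_propagations"]
print(stacks[cols].round(3).to_string(index=False))
# pure-SGC rows always show exactly one propagation precompute

ratios = ablate_imbalance(cfg, ["1:1", "1:5", "1:10"])
print("\n" + ratios[["ratio", "auc", "aupr", "n_test"]].round(3).to_string(index=False))
# AUPR falls with imbalance much faster than AUC: under rare positives
# the precision-recall area is the informative metric.
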