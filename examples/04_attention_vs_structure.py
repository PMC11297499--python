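"""Relate reciprocal-attention weights to residue-residue distances.

Trains the attention model with the concat-then-pad chain encoding (so
chain positions map onto residues), builds synthetic complex structures
whose contacts sit at the planted motif positions, and tests whether the
model puts more attention mass on close residue pairs (< 10 A) than on
far ones (> 25 A).
"""

import warnings

from tcrbind.workflows import interpretation_benchmark

warnings.filterwarnings("ignore")

res = interpretation_benchmark(seed=3)
print(f"attention model held-out ROC-AUC: {res['auc_attention']:.3f}")
print(f"mean attention on close pairs (<10 A): {res['mean_close']:.4f}")
print(f"mean attention on far pairs  (>25 A): {res['mean_far']:.4f}")
print(f"{res['test_variant']} t = {res['t_statistic']:.2f}, p = {res['p_value']:.2e} "
      f"over {res['n_complexes']} complexes")
# mean_close > mean_far with a small p-value means the trained attention
# concentrates on the residue pairs that are spatially close in the
# (synthetic) complex structures - the planted binding interface.
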