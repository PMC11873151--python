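"""Stage 2: federated communication rounds with DDBL and distillation.

Three centers run the full two-stage pipeline at desk scale: Stage-1
transfer and freezing, then federated rounds in which each center selects
its low-heterogeneity batches and distills common knowledge from the
shared model into its non-frozen parameters.  The cross-center matrix
shows every local model evaluated on every center's test split; the
diagonal is in-center performance, off-diagonal entries measure
generalization across acquisition signatures.
"""

from dataclasses import replace

from vfmgl.config import PRESETS
from vfmgl.experiment import (federation_config, run_federated_rounds,
                              train_stage1_centers, _test_sets)
from vfmgl.evaluation import cross_center_matrix
from vfmgl.synthetic import generate_federation

cfg = replace(PRESETS["toy-classification"], rounds=2)
federation = generate_federation(federation_config(cfg))
stage1 = train_stage1_centers(cfg, federation)
for cid, s in stage1.items():
    print(f"{cid}: frozen layers {s['criticality'].frozen_layers()}")

clients, shared = run_federated_rounds(cfg, federation, stage1)
models = {c.center_id: c.model.eval() for c in clients}
matrix = cross_center_matrix(models, _test_sets(federation), "auc")
print("\ncross-center AUC (rows: model, columns: test center)")
print(matrix.round(3))
print(f"\nmean cross-center AUC: {matrix.values.mean():.3f} "
      f"(0.5 = chance, 1.0 = perfect ranking)")
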