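"""Stage 1: transfer general knowledge from a transformer teacher into a
small residual student and freeze the robustness-critical layers.

The transfer plan starts with uniform weights on all teacher-block x
student-stage pairs; the meta-network reweights them while the student
trains on task + transfer loss.  Layer criticality is the share of
transfer-weight mass each student stage received — the top half is frozen
so the general knowledge survives the federated stage.
"""

from vfmgl.hgkt import (Stage1Config, enumerate_pairs, score_and_freeze,
                        stage1_train)
from vfmgl.model_zoo import ModelSpec, build_model
from vfmgl.synthetic import SyntheticConfig, generate_federation

syn = SyntheticConfig(task="classification", n_centers=1, n_samples=48,
                      image_size=32, split_ratios=(1.0,), seed=42)
data = next(iter(generate_federation(syn).values()))["train"]

teacher = build_model(ModelSpec("classification", "tiny-vit",
                                (32, 32, 3), 2), seed=7)
student = build_model(ModelSpec("classification", "residual-18",
                                (32, 32, 3), 2, width=4), seed=42)
plan = enumerate_pairs(teacher.spec, student.spec)

student, plan, history = stage1_train(
    data, teacher, student, plan,
    Stage1Config(epochs=3, lr=0.01, batch_size=8, seed=42))
print("per-epoch training loss:", [round(h, 3) for h in history])

criticality = score_and_freeze(plan, top_fraction=0.5)
for layer, score in criticality.scores.items():
    flag = "frozen" if criticality.frozen[layer] else "free"
    print(f"{layer}: criticality {score:.3f}  -> {flag}")
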