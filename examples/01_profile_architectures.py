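"""Profile the teacher and student architectures.

Prints exact parameter counts and module-level MACs for the ViT-B/14
foundation-model teacher and the residual-18 student at 224x224x3, plus
their compression ratios.  The student needs ~1/8 of the parameters and
~1/12 of the inference compute of the teacher, which is the point of
transferring the teacher's general knowledge into it.
"""

from vfmgl.model_zoo import ModelSpec
from vfmgl.profiler import count_macs, count_params, profile

student = ModelSpec("classification", "residual-18", (224, 224, 3), 2)
teacher = ModelSpec("classification", "vit-b-14", (224, 224, 3), 2)

for name, spec in [("residual-18 student", student),
                   ("vit-b-14 teacher", teacher)]:
    rep = profile(spec)
    print(f"{name:20s}  params {rep.n_params:>10,d} ({rep.n_params_M} M)"
          f"  MACs {rep.macs_G} G")

print(f"parameter ratio  1:{count_params(teacher) / count_params(student):.1f}")
print(f"compute ratio    1:{count_macs(teacher) / count_macs(student):.1f}")
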