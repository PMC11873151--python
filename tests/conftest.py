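import numpy as np
import pytest

from vfmgl.model_zoo import ModelSpec, build_model


@pytest.fixture(scope="session")
def tiny_student_spec():
    return ModelSpec("classification", "residual-18", (32, 32, 3), 2, width=2)


@pytest.fixture(scope="session")
def tiny_teacher():
    return build_model(
        ModelSpec("classification", "tiny-vit", (32, 32, 3), 2), seed=11)


@pytest.fixture()
def tiny_student(tiny_student_spec):
    return build_model(tiny_student_spec, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
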