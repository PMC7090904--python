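import numpy as np
import pytest

from limbssm.soft_tissue import builtin_offset_models
from limbssm.ssm import build_ssm
from limbssm.synthetic import (FEMUR_TEMPLATE, TIBIA_TEMPLATE, generate_bone,
                               generate_population)


@pytest.fixture(scope="session")
def femur_bone():
    return generate_bone(FEMUR_TEMPLATE)


@pytest.fixture(scope="session")
def tibia_bone():
    return generate_bone(TIBIA_TEMPLATE)


@pytest.fixture(scope="session")
def pop12():
    """Small femur population shared by shape-model tests."""
    return generate_population(12, seed=11, noise_sd=0.1)


@pytest.fixture(scope="session")
def ssm12(pop12):
    return build_ssm(pop12.cset)


@pytest.fixture(scope="session")
def offset_table():
    return builtin_offset_models()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
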