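"""Shared fixtures: a seeded synthetic plant and the (expensive) activation
dataset are built once per session."""

import numpy as np
import pytest
from hypothesis import settings

import synbias as sb
from synbias.synergy_gen import build_activation_dataset
from synbias.training import TrainConfig

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

BASE_PLANT_SEED = 1
DATASET_SEED = 7


@pytest.fixture(scope="session")
def base_plant() -> sb.Plant:
    """The standard 22-muscle synthetic plant with |t_pl| = 0.5 Nm."""
    return sb.make_synthetic_plant(22, 0.5, seed=BASE_PLANT_SEED)


@pytest.fixture(scope="session")
def tiny_plant() -> sb.Plant:
    """Hand-built 4-muscle plant spanning the plane, for analytic checks."""
    D = np.array([[1.0, 0.0, -1.0, 0.0], [0.0, 1.0, 0.0, -1.0]])
    return sb.Plant(D=D, t_pl=np.array([0.2, 0.1]))


@pytest.fixture(scope="session")
def dataset(base_plant) -> sb.ActivationDataset:
    """The 120-direction activation dataset on the base plant."""
    return build_activation_dataset(base_plant, TrainConfig(seed=DATASET_SEED))
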