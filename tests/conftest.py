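import numpy as np
import pytest

import hpakit as hk
from hpakit.optimize import EvaluationConfig


@pytest.fixture(scope="session")
def minimal():
    return hk.minimal_model()


@pytest.fixture(scope="session")
def receptor():
    return hk.receptor_model()


@pytest.fixture(scope="session")
def delayed():
    return hk.delayed_model()


@pytest.fixture(scope="session")
def stress_drivers(minimal):
    """Flat circadian drive plus the canonical 20-min stress episode."""
    return hk.Drivers(
        circadian=hk.CircadianDrive(mesor=1.0),
        stress=hk.canonical_tsst_protocol(),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return hk.synth_tsst_cohort(12, anomaly_fraction=0.0, seed=7)


@pytest.fixture(scope="session")
def fast_config():
    """Short pre-roll evaluation config used to keep optimisation tests quick."""
    return EvaluationConfig(burn_in=60.0)


def rng(seed=0):
    return np.random.default_rng(seed)
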