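import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gudpeck import RunConfig, SimConfig, generate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from gudpeck.datatypes import INTERVALS_COLUMNS, PECKS_COLUMNS, TRIALS_COLUMNS


def make_pecks(rows):
    """rows: (tray_id, species, class_tag, t_seconds)."""
    return pd.DataFrame(rows, columns=PECKS_COLUMNS)


def make_intervals(rows):
    return pd.DataFrame(rows, columns=INTERVALS_COLUMNS)


def make_trials(rows):
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


@pytest.fixture
def tiny_trials():
    return make_trials(
        [
            ("T1", "Y1", "mesic", "bush", 20.0, 86400.0, 4.5),
            ("T2", "Y1", "mesic", "open", 20.0, 86400.0, 12.25),
        ]
    )


@pytest.fixture
def tiny_pecks():
    return make_pecks(
        [
            ("T1", "ABTO", "unknown", 10.0),
            ("T1", "ABTO", "unknown", 20.0),
            ("T1", "HOSP", "male", 30.0),
            ("T1", "ABTO", "unknown", 40.0),
            ("T1", "HOSP", "male", 50.0),
            ("T2", "CBTH", "unknown", 100.0),
            ("T2", "CBTH", "unknown", 130.0),
            ("T2", "CBTH", "unknown", 300.0),
            ("T2", "HOFI", "female", 400.0),
            ("T2", "HOFI", "female", 410.0),
        ]
    )


@pytest.fixture
def tiny_intervals():
    return make_intervals(
        [
            ("T1", "ABTO", "unknown", 5.0, 45.0),
            ("T1", "HOSP", "male", 25.0, 55.0),
            ("T2", "CBTH", "unknown", 90.0, 310.0),
            ("T2", "HOFI", "female", 395.0, 420.0),
        ]
    )


@pytest.fixture(scope="session")
def sim_study():
    """One seeded diminishing-returns study with ground truth (shared)."""
    return generate_study(cfg=SimConfig(), seed=42)


@pytest.fixture(scope="session")
def sim_study_constant():
    """One seeded constant-yield, noise-free study with ground truth."""
    cfg = SimConfig(depletion="constant_yield", gud_weighing_sd=0.0)
    return generate_study(cfg=cfg, seed=7)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
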