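import warnings

import numpy as np
import pytest

from antforage.arena import build_arena
from antforage.colony import SimConfig
from antforage.pipeline import train_replicas

warnings.filterwarnings("ignore", category=FutureWarning)

# Desk-scale study conditions: a 1.2 x 0.8 m lattice (262 decision nodes)
# holds the full three-phase dynamics while keeping replica fits and Glauber
# experiments fast; trials are cut at 3600 s, which spans all of exploration
# and exploitation and a relaxation tail (training uses exploitation only).
STUDY_ARENA = (1000.0, 800.0, 50.0)
STUDY_DURATION_S = 3600.0
STUDY_TRIALS = 3
DET_SEED, STO_SEED = 11, 12


@pytest.fixture(scope="session")
def arena_tiny():
    return build_arena(500, 400, 50)


@pytest.fixture(scope="session")
def arena_study():
    return build_arena(*STUDY_ARENA)


@pytest.fixture(scope="session")
def study_config():
    return SimConfig(duration_s=STUDY_DURATION_S)


@pytest.fixture(scope="session")
def det_replicas(arena_study, study_config):
    """(full, null, training occupancy) fitted to deterministic-condition trials."""
    return train_replicas(arena_study, "deterministic", STUDY_TRIALS,
                          study_config, DET_SEED)


@pytest.fixture(scope="session")
def sto_replicas(arena_study, study_config):
    return train_replicas(arena_study, "stochastic", STUDY_TRIALS,
                          study_config, STO_SEED)
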