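from datetime import date, datetime

import numpy as np
import pytest

from felidcam import camera_records as cr
from felidcam.synthetic_data import (
    LagAvoidance,
    SimulationConfig,
    simulate_detection_data,
    simulate_landscape,
    simulate_survey,
)

SEED = 20251


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def null_config():
    """No lag avoidance: subordinate detections independent of dominant visits."""
    return SimulationConfig(lag_avoidance=LagAvoidance(length_days=0, suppression=1.0))


@pytest.fixture(scope="session")
def survey(default_config):
    """One fully processed synthetic survey under the default (avoidance) mechanism."""
    return simulate_survey(default_config, SEED)


@pytest.fixture(scope="session")
def null_survey(null_config):
    return simulate_survey(null_config, SEED + 1)


@pytest.fixture(scope="session")
def fr_design():
    """Survey design of the 92-day study area (1 Oct - 31 Dec 2010)."""
    return cr.SurveyDesign(date(2010, 10, 1), date(2010, 12, 31))


def make_history(Y, effort=None, sites=None):
    """Small helper: DetectionHistory from a plain array (effort 1 where observed)."""
    Y = np.asarray(Y, dtype=float)
    if effort is None:
        effort = np.where(np.isnan(Y), 0.0, 1.0)
    if sites is None:
        sites = [f"s{i}" for i in range(Y.shape[0])]
    return cr.DetectionHistory(list(sites), Y, np.asarray(effort, dtype=float))


@pytest.fixture
def tiny_history():
    return make_history([[1, 0, 1], [0, 0, 0], [1, 1, 1]])
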