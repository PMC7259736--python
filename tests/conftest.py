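"""Shared fixtures: small simulated datasets and sampler configurations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nutcracker_occupancy.data_model import DesignMatrix
from nutcracker_occupancy.occupancy_mcmc import (
    ModelConfig,
    build_occupancy_data,
)

#: no random-effect layers: a plain occupancy GLM, matching simulations
#: whose heterogeneity sds are all zero
SIMPLE_CONFIG = ModelConfig(
    site_effect=False,
    year_stage_detection_effect=False,
    observation_effect=False,
    year_varying_coefficients=False,
)


def make_history_data(h: np.ndarray, stage: str = "fall_harvest", year: int = 2020):
    """Wrap an (n, 3) history array as covariate-free OccupancyData."""
    n = len(h)
    units = pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n)],
            "year": year,
            "stage": stage,
            "count1": h[:, 0],
            "count2": h[:, 1],
            "count3": h[:, 2],
        }
    )
    design = DesignMatrix(X=np.empty((n, 0)), columns=[], terms={}, column_stats={})
    return build_occupancy_data(units, design)


def simulate_homogeneous(n: int, psi: float, p: float, seed: int) -> np.ndarray:
    """Constant-probability detection histories (n, 3)."""
    rng = np.random.default_rng(seed)
    z = rng.random(n) < psi
    return (rng.random((n, 3)) < (z[:, None] * p)).astype(np.int8)


@pytest.fixture
def simple_config():
    return SIMPLE_CONFIG
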