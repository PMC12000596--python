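"""Shared fixtures.

The expensive end-to-end trainings (full-scale parameter recovery) are
session-scoped so the recovery, importance-ranking and acceptance checks all
reuse the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from maizeyield.config import NetworkConfig
from maizeyield.evaluation import SplitSpec, fit_evaluate
from maizeyield.synthetic import SyntheticConfig, generate_panel


def tiny_network_config(seed: int = 0, **kwargs) -> NetworkConfig:
    """A small architecture for fast structural tests."""
    defaults = dict(
        conv_filters=(4, 3), kernel_size=2, bottleneck_units=3, gru_layers=2,
        gru_hidden=3, input_channels=2, sequence_length=5, epochs=3, seed=seed,
    )
    defaults.update(kwargs)
    return NetworkConfig(**defaults)


@pytest.fixture(scope="session")
def small_panel():
    """6 counties x 5 years; structurally complete, fast to generate."""
    panel, truth = generate_panel(
        SyntheticConfig(n_counties=6, year_start=2001, year_end=2005, seed=11)
    )
    return panel, truth


@pytest.fixture(scope="session")
def study_panel():
    """Full study conditions: 150 counties x 2001-2021, drought year 2014."""
    panel, truth = generate_panel(SyntheticConfig(seed=1))
    return panel, truth


@pytest.fixture(scope="session")
def midscale_panel():
    """60 counties x 2001-2012: the scaled-down harness panel."""
    panel, truth = generate_panel(
        SyntheticConfig(seed=7, n_counties=60, year_start=2001, year_end=2012)
    )
    return panel, truth


@pytest.fixture(scope="session")
def recovery_runs():
    """Three seeded held-out-year trainings at full study scale.

    Each run generates its own panel (seed s), trains the default network
    (seed s) and scores the held-out year 2021.  Shared by the
    parameter-recovery and importance-ranking checks.
    """
    runs = []
    for seed in (1, 2, 3):
        panel, truth = generate_panel(SyntheticConfig(seed=seed))
        result = fit_evaluate(
            panel, SplitSpec(strategy="holdout_year", test_year=2021, seed=seed),
            NetworkConfig(seed=seed),
        )
        runs.append({"panel": panel, "truth": truth, "result": result})
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
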