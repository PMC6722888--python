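"""Shared fixtures: the default synthetic experiment is expensive, so it is
generated once per session and reused read-only by many tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from imcprofiler import synthetic as syn
from imcprofiler.synthetic import experiment_table

EXPERIMENT_SEED = 42


@pytest.fixture(scope="session")
def default_experiment():
    """The 8-ROI default synthetic experiment (master seed 42)."""
    return syn.generate_experiment(master_seed=EXPERIMENT_SEED)


@pytest.fixture(scope="session")
def truth_table(default_experiment):
    """Pooled ground-truth cell table of the default experiment."""
    return experiment_table(default_experiment)


@pytest.fixture(scope="session")
def control_roi(default_experiment):
    """The single nontreated control ROI of the default experiment."""
    for roi in default_experiment:
        if roi.stack.condition == "nontreated":
            return roi
    raise AssertionError("no nontreated ROI in default experiment")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def toy_table(values: dict[str, list], condition: str = "c") -> pd.DataFrame:
    """Small hand-built cell table with the mandatory bookkeeping columns."""
    n = len(next(iter(values.values())))
    base = {
        "cell_id": list(range(1, n + 1)),
        "roi_id": "toy",
        "condition": condition,
    }
    return pd.DataFrame({**base, **values})
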