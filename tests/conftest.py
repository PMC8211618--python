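"""Shared fixtures: small seeded synthetic datasets generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from prpddm.design import preset
from prpddm.simulate import default_population, simulate_experiment


@pytest.fixture(scope="session")
def serial_small():
    """Exp-1 geometry, 6 subjects/condition, both conditions serial.

    Small but large enough that the PRP signature (RT2 rising at short SOA)
    is unmistakable.  Returns (trials, ground-truth sidecar).
    """
    configs = {c: preset("exp1", c, n_subjects_per_condition=6) for c in ("SF", "LF")}
    pops = {c: default_population("serial") for c in ("SF", "LF")}
    return simulate_experiment(configs, pops, seed=101)


@pytest.fixture(scope="session")
def exp3_small():
    """Exp-3 geometry (17.5% no-go), 3 subjects/condition, serial."""
    configs = {c: preset("exp3", c, n_subjects_per_condition=3) for c in ("SF", "LF")}
    pops = {c: default_population("serial") for c in ("SF", "LF")}
    return simulate_experiment(configs, pops, seed=202)


@pytest.fixture()
def toy_trials():
    """Hand-enumerated 6-trial table: 1 error trial, 1 fast rt1, 1 slow rt2."""
    return pd.DataFrame({
        "subject_id": ["s1"] * 6,
        "condition": ["SF"] * 6,
        "block": [1] * 6,
        "trial": range(1, 7),
        "soa_ms": [100.0, 100.0, 300.0, 300.0, 800.0, 800.0],
        "is_nogo": [False] * 6,
        "correct1": [True, True, False, True, True, True],
        "correct2": [True] * 6,
        "rt1_ms": [500.0, 150.0, 520.0, 530.0, 540.0, 550.0],
        "rt2_ms": [600.0, 610.0, 620.0, 2500.0, 640.0, 650.0],
    })
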