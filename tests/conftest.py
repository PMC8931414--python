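"""Shared fixtures: stimulus inventory, deterministic observers, small datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emofusion import (
    DesignConfig,
    ObserverParams,
    PopulationConfig,
    enumerate_stimuli,
    simulate_dataset,
)
from emofusion.design import EMOTIONS, LEVELS, MODALITIES


@pytest.fixture(scope="session")
def inventory():
    return enumerate_stimuli(DesignConfig())


def zero_variance_config(**overrides) -> PopulationConfig:
    """Population with every between-subject/stimulus SD collapsed to zero."""
    base = dict(
        subject_mu_sd=0.0,
        stimulus_mu_sd=0.0,
        sim_a_sd=0.0,
        sim_b_sd=0.0,
        sim_c_sd=0.0,
        sim_tau_sd=0.0,
        reliance_sd=0.0,
        intercept_sd=0.0,
        acc_kappa=0.0,
    )
    base.update(overrides)
    return PopulationConfig(**base)


def flat_mu(value: float) -> dict:
    """A latent-mean table with one constant value everywhere."""
    return {
        (m, e, lv): float(value) for m in MODALITIES for e in EMOTIONS for lv in LEVELS
    }


def level_mu(neutral: float = 1.78, weak: float = 4.43, strong: float = 5.99) -> dict:
    vals = {"neutral": neutral, "weak": weak, "strong": strong}
    return {
        (m, e, lv): vals[lv] for m in MODALITIES for e in EMOTIONS for lv in LEVELS
    }


def make_observer(**overrides) -> ObserverParams:
    """A deterministic observer with equal-weight fusion unless overridden."""
    defaults = dict(
        subject_id="T001",
        mu=level_mu(),
        sigma_v=0.0,
        sigma_a=0.0,
        sigma_m=0.0,
        lapse=0.0,
        w={
            (state, emotion): (0.5, 0.5, 0.0)
            for state in ("unified", "segregated")
            for emotion in EMOTIONS
        },
    )
    defaults.update(overrides)
    obs = ObserverParams(**defaults)
    obs.validate()
    return obs


@pytest.fixture(scope="session")
def small_dataset():
    """Eight default-population subjects; shared by pipeline-level tests."""
    return simulate_dataset(PopulationConfig(n_subjects=8), seed=11)
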