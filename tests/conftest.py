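"""Shared fixtures: published parameter truth, small synthetic datasets and
pre-computed fits reused across test modules (fitting is the expensive step,
so session scope matters)."""

import numpy as np
import pandas as pd
import pytest

from ilapop.data import (PopPKDataset, SimulationTruth, builtin_designs,
                         simulate_trial)
from ilapop.estimation import CovariateEffect, PopPKModel
from ilapop.structural import DoseEvent, PKParameters


@pytest.fixture(scope="session")
def typical_params() -> PKParameters:
    """Final-model typical subject parameters."""
    return PKParameters(V=6.795, Vp=5.544, CL=3.394, CLp=13.086)


@pytest.fixture(scope="session")
def truth() -> SimulationTruth:
    return SimulationTruth()


@pytest.fixture(scope="session")
def final_effects() -> list[CovariateEffect]:
    return [CovariateEffect("Vp", "WT", "continuous"),
            CovariateEffect("CL", "SEX", "categorical"),
            CovariateEffect("CL", "DIS", "categorical"),
            CovariateEffect("Vp", "DIS", "categorical")]


@pytest.fixture(scope="session")
def truth_values() -> dict:
    """Generating parameters keyed by model parameter names."""
    return {"tv_V": 6.795, "tv_Vp": 5.544, "tv_CL": 3.394, "tv_CLp": 13.086,
            "WT_Vp": 1.545, "SEX_CL": -0.213, "DIS_CL": 0.290,
            "DIS_Vp": 0.356, "omega2_V": 0.013, "omega2_Vp": 0.032,
            "omega2_CL": 0.059, "sigma_mult": 0.184}


@pytest.fixture(scope="session")
def high_dose_dataset(truth) -> PopPKDataset:
    """One 30 mg single-dose arm, 10 subjects."""
    return simulate_trial(builtin_designs()["high_dose"], truth, seed=11)


@pytest.fixture(scope="session")
def mixed_dataset(truth) -> PopPKDataset:
    """High-dose plus ulcer arms (20 subjects) — has covariate contrast in
    both disease status and weight."""
    rng = np.random.default_rng(17)
    a = simulate_trial(builtin_designs()["high_dose"], truth, rng)
    b = simulate_trial(builtin_designs()["ulcer"], truth, rng, id_offset=10)
    return PopPKDataset(pd.concat([a.frame, b.frame], ignore_index=True))


@pytest.fixture(scope="session")
def base_fit(high_dose_dataset):
    """Base two-compartment fit (no covariates) on the small arm."""
    model = PopPKModel(high_dose_dataset)
    return model.fit(preset="fast", compute_se=False)


def tiny_dataset(n_subjects=2, times=(1.0, 4.0, 12.0), dose=20.0, seed=3,
                 sigma=0.15, omega_cl=0.25) -> PopPKDataset:
    """Hand-rolled miniature dataset for likelihood-level tests."""
    from ilapop.structural import concentration_2cmt

    rng = np.random.default_rng(seed)
    rows = []
    for sid in range(1, n_subjects + 1):
        rows.append(dict(ID=sid, TIME=0.0, AMT=dose, DUR=0.75, DV=0.0,
                         EVID=1, MDV=1, BLQ=0, SEX=0, DIS=0, AGE=25.0,
                         HT=168.0, WT=60.6, SCR=0.8))
        p = PKParameters(6.795, 5.544, 3.394 * np.exp(rng.normal(0, omega_cl)),
                         13.086)
        prof = concentration_2cmt(p, [DoseEvent(dose, 0.0, 0.75)], times)
        for t, f in zip(times, prof.concentrations):
            rows.append(dict(ID=sid, TIME=float(t), AMT=0.0, DUR=0.0,
                             DV=float(f * (1 + rng.normal(0, sigma))),
                             EVID=0, MDV=0, BLQ=0, SEX=0, DIS=0, AGE=25.0,
                             HT=168.0, WT=60.6, SCR=0.8))
    return PopPKDataset(pd.DataFrame(rows))
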