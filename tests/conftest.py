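"""Shared fixtures: reference parameters, study-replica cohorts and fits,
and the independent ODE oracle for the analytic PK solution."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from dalbapk import (
    CohortConfig,
    ModelSpec,
    PKDataset,
    VAD_TYPICAL,
    fit,
    generate_cohort,
    impute_bql,
    micro_rates,
    sample_population,
    vad_population_model,
)
from dalbapk.dataset import COLUMNS


@pytest.fixture(scope="session")
def typical():
    return VAD_TYPICAL


@pytest.fixture(scope="session")
def popmodel():
    return vad_population_model()


@pytest.fixture(scope="session")
def pop10k(popmodel):
    return sample_population(popmodel, 10_000, seed=1)


@pytest.fixture(scope="session")
def study_cohort():
    """One 13-subject study-replica dataset with ground truth."""
    d, gt = generate_cohort(CohortConfig(n_subjects=13), seed=202)
    imputed, report = impute_bql(d)
    return {"raw": d, "imputed": imputed, "report": report, "truth": gt}


@pytest.fixture(scope="session")
def study_fit(study_cohort):
    """A fitted study replica, shared across diagnostic tests."""
    return fit(study_cohort["imputed"], ModelSpec(), seed=0)


def ode_concentration(p, doses, t_eval, rtol=1e-11, atol=1e-13):
    """Independent oracle: numerically integrate the two-compartment ODE
    system (amounts in central/peripheral compartments) across infusion
    segments and return central concentrations at ``t_eval``."""
    k = micro_rates(p)

    def rhs(t, y):
        rate = sum(a / du for (s, a, du) in doses if s <= t < s + du)
        return [
            rate - (k.k10 + k.k12) * y[0] + k.k21 * y[1],
            k.k12 * y[0] - k.k21 * y[1],
        ]

    t_eval = np.asarray(t_eval, dtype=float)
    bounds = sorted(
        {0.0}
        | {s for s, _, _ in doses}
        | {s + du for s, _, du in doses}
        | set(t_eval.tolist())
    )
    y = np.array([0.0, 0.0])
    out = {0.0: 0.0}
    for a, b in zip(bounds[:-1], bounds[1:]):
        sol = solve_ivp(rhs, (a, b), y, rtol=rtol, atol=atol, dense_output=True)
        y = sol.y[:, -1]
        for t in t_eval:
            if a < t <= b:
                out[float(t)] = float(sol.sol(t)[0]) / p.V1
    return np.array([out[float(t)] for t in t_eval])


def make_dataset(rows: list[dict]) -> PKDataset:
    """Build a PKDataset from partial row dicts, filling default covariates."""
    base = {c: np.nan for c in COLUMNS}
    base.update({"WT": 76.0, "BSA": 1.95, "AGE": 57.0, "CRCL": 90.0, "ALB": 42.0,
                 "PB": 97.0, "BQL": 0, "ANALYTE": "total"})
    full = []
    for r in rows:
        row = dict(base)
        row.update(r)
        full.append(row)
    return PKDataset(pd.DataFrame(full, columns=list(COLUMNS)))


def dose_row(sid, t=0.0, amt=1500.0, dur=0.5, **kw):
    return {"ID": sid, "TIME": t, "EVID": 1, "AMT": amt, "DUR": dur, "DV": np.nan, **kw}


def obs_row(sid, t, dv, analyte="total", bql=0, **kw):
    return {"ID": sid, "TIME": t, "EVID": 0, "DV": dv, "ANALYTE": analyte, "BQL": bql, **kw}
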