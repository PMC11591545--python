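"""Study-emulating synthetic cohorts with known ground truth.

The default configuration replicates the ventricular-assist-device
suppressive-therapy study design: 13 male VAD patients, 1500 mg
dalbavancin infused over 0.5 h on day 1 and day 8 of a 6-week cycle (one
engineered low-renal-function subject receives 1000 mg), and three sparse
samples per patient — 30 min after the end of the day-1 infusion, the
trough immediately before the day-8 dose (168 h) and the trough
immediately before the next cycle (day 43, 1008 h).  Total and unbound
concentrations are emulated with proportional residual error and flagged
against their assay quantification limits (12.5 and 1 mg/L).

Covariates are drawn to match the reported cohort demographics (age
57 ± 9 y, BSA 1.95 ± 0.17 m², CrCl 90.8 ± 34.7 mL/min, albumin
42.5 ± 5.7 mg/dL, weight median 76 kg with IQR 20 kg, protein binding
96-98%) but carry no effect on the PK parameters by default, matching the
null covariate result of the cohort analysis; an explicit covariate-
effect mode exists to power covariate-selection experiments.  Every draw
is recorded so parameter-recovery tests can compare against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import COLUMNS, PKDataset, QL_TOTAL, QL_UNBOUND
from .model import conc_many
from .population import PopModel, vad_population_model
from .util import substream

__all__ = ["CohortConfig", "CovariateModel", "GroundTruth", "sample_covariates",
           "generate_cohort", "summarize_cohort"]

_PARAM_ORDER = ("CL", "V1", "Q", "V2")


@dataclass(frozen=True)
class CovariateModel:
    """Optional power-law covariate effects on the typical parameters.

    ``effects`` holds (parameter, covariate-column, exponent) triples:
    the subject's typical value is multiplied by
    ``(cov / median(cov)) ** exponent``.  Empty by default.
    """

    effects: tuple[tuple[str, str, float], ...] = ()


@dataclass(frozen=True)
class CohortConfig:
    """Design of one synthetic study cohort (times in h, amounts in mg)."""

    n_subjects: int = 13
    truth: PopModel = field(default_factory=vad_population_model)
    dose_days: tuple[float, ...] = (1.0, 8.0)
    dose_amount: float = 1500.0
    reduced_amount: float = 1000.0
    crcl_cutoff: float = 30.0
    infusion_h: float = 0.5
    sample_times: tuple[float, ...] | None = None  # default: EOI+0.5, 168, 1008
    pb_range: tuple[float, float] = (96.0, 98.0)
    ql_total: float = QL_TOTAL
    ql_unbound: float = QL_UNBOUND
    n_low_crcl: int = 1
    n_missing: int = 0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.pb_range
        if not (0 <= lo <= hi < 100):
            raise ValueError(f"pb_range must lie within [0, 100), got {self.pb_range}")
        horizon = 24.0 * (max(self.dose_days) - 1.0) + 6 * 168.0
        for t in self.resolved_sample_times:
            if not (0 <= t <= horizon):
                raise ValueError(f"sample time {t} h outside the simulated horizon")

    @property
    def resolved_sample_times(self) -> tuple[float, ...]:
        if self.sample_times is not None:
            return self.sample_times
        return (self.infusion_h + 0.5, 168.0, 1008.0)

    @property
    def dose_starts(self) -> tuple[float, ...]:
        return tuple(24.0 * (d - 1.0) for d in self.dose_days)


@dataclass
class GroundTruth:
    """Generating values returned alongside a synthetic dataset."""

    params: pd.DataFrame          # ID + CL, V1, Q, V2
    etas: np.ndarray              # (n, k) log-scale random effects
    eta_names: tuple[str, ...]
    true_conc: pd.DataFrame       # ID, time_h, conc_total_true
    pb: np.ndarray                # per-subject protein binding, %
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "eta_names": list(self.eta_names),
            "params": self.params.to_dict(orient="list"),
            "etas": self.etas.tolist(),
            "true_conc": self.true_conc.to_dict(orient="list"),
            "pb": self.pb.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_covariates(cfg: CohortConfig, seed: int = 0) -> pd.DataFrame:
    """Draw per-subject covariates matching the cohort demographics.

    Age, BSA, CrCl and albumin are truncated normals; weight is log-normal
    calibrated to median 76 kg and IQR 20 kg; protein binding is uniform
    on ``pb_range``.  ``n_low_crcl`` randomly chosen subjects get an
    engineered low creatinine clearance on [15, 30) mL/min (triggering the
    reduced dose); all other CrCl draws are truncated to [30, 200].
    """
    n = cfg.n_subjects
    rng = substream(seed, "covariates")
    age = _truncnorm(rng, 57.0, 9.0, 30.0, 84.0, n)
    bsa = _truncnorm(rng, 1.95, 0.17, 1.4, 2.6, n)
    alb = _truncnorm(rng, 42.5, 5.7, 25.0, 60.0, n)
    crcl = _truncnorm(rng, 90.8, 34.73, 30.0, 200.0, n)
    # log-normal weight: median 76 kg; sigma solves 2*76*sinh(0.6745*sigma) = IQR 20
    sigma = np.arcsinh(20.0 / (2.0 * 76.0)) / 0.6745
    wt = 76.0 * np.exp(sigma * rng.standard_normal(n))
    pb = rng.uniform(cfg.pb_range[0], cfg.pb_range[1], n)
    n_low = min(cfg.n_low_crcl, n)
    if n_low > 0:
        low_idx = rng.choice(n, size=n_low, replace=False)
        crcl[low_idx] = rng.uniform(15.0, 30.0, n_low)
    return pd.DataFrame(
        {
            "ID": np.arange(1, n + 1),
            "WT": wt,
            "BSA": bsa,
            "AGE": age,
            "CRCL": crcl,
            "ALB": alb,
            "PB": pb,
        }
    )


def generate_cohort(cfg: CohortConfig, seed: int = 0) -> tuple[PKDataset, GroundTruth]:
    """Simulate one cohort: dataset (doses + noisy flagged observations)
    plus the generating ground truth.

    Observations are ``truth * (1 + b*eps)`` with independent standard-
    normal ``eps`` per record and analyte; unbound observations are the
    free fraction ``(1 - PB/100)`` of the true total concentration with
    their own residual error and quantification limit.  BQL flags are set
    where the simulated value falls below the analyte's limit; values are
    *not* imputed here — that is the estimation pipeline's first step.
    """
    n = cfg.n_subjects
    truth = cfg.truth
    cov = sample_covariates(cfg, seed)
    rng_eta = substream(seed, "etas")
    rng_err = substream(seed, "residual")

    eta_names = truth.eta_names
    sds = np.array([truth.omega[p] for p in eta_names])
    etas = rng_eta.standard_normal((n, len(eta_names))) * sds[None, :]
    typ = truth.typical.as_dict()
    params: dict[str, np.ndarray] = {}
    for p in _PARAM_ORDER:
        base = np.full(n, typ[p])
        for prm, col, expo in cfg.covariate_model.effects:
            if prm == p:
                vals = cov[col].to_numpy(float)
                base = base * (vals / np.median(vals)) ** expo
        if p in truth.omega:
            base = base * np.exp(etas[:, eta_names.index(p)])
        params[p] = base

    starts = np.array(cfg.dose_starts)
    amounts = np.where(
        cov["CRCL"].to_numpy(float) < cfg.crcl_cutoff, cfg.reduced_amount, cfg.dose_amount
    )[:, None] * np.ones((1, len(starts)))
    durs = np.full((n, len(starts)), cfg.infusion_h)
    times = np.asarray(cfg.resolved_sample_times)
    conc = conc_many(
        params["CL"], params["V1"], params["Q"], params["V2"],
        np.tile(starts, (n, 1)), amounts, durs, times,
    )  # (n, n_times)

    b = truth.error_b
    y_total = conc * (1.0 + b * rng_err.standard_normal(conc.shape))
    pbv = cov["PB"].to_numpy(float)
    free_true = conc * (1.0 - pbv[:, None] / 100.0)
    y_unbound = free_true * (1.0 + b * rng_err.standard_normal(conc.shape))

    rows = []
    for i in range(n):
        sid = int(cov["ID"].iloc[i])
        covariates = {c: float(cov[c].iloc[i]) for c in ("WT", "BSA", "AGE", "CRCL", "ALB", "PB")}
        events = []
        for j, t in enumerate(starts):
            events.append((t, 1, {"AMT": amounts[i, j], "DUR": durs[i, j]}))
        for j, t in enumerate(times):
            events.append(
                (t, 0, {"DV": y_total[i, j], "BQL": int(y_total[i, j] < cfg.ql_total),
                        "ANALYTE": "total"})
            )
            events.append(
                (t, 0, {"DV": y_unbound[i, j], "BQL": int(y_unbound[i, j] < cfg.ql_unbound),
                        "ANALYTE": "unbound"})
            )
        events.sort(key=lambda e: (e[0], e[1]))
        for t, evid, extra in events:
            row = {c: np.nan for c in COLUMNS}
            row.update({"ID": sid, "TIME": t, "EVID": evid, "BQL": 0})
            row.update(covariates)
            row.update(extra)
            if evid == 1:
                row["DV"] = np.nan
                row["ANALYTE"] = "total"
                row["BQL"] = 0
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(COLUMNS))

    if cfg.n_missing > 0:
        rng_miss = substream(seed, "missingness")
        total_obs_idx = df.index[(df["EVID"] == 0) & (df["ANALYTE"] == "total")].to_numpy()
        drop = rng_miss.choice(total_obs_idx, size=min(cfg.n_missing, len(total_obs_idx)),
                               replace=False)
        df = df.drop(index=drop).reset_index(drop=True)

    dataset = PKDataset(df)
    tc = pd.DataFrame(
        {
            "ID": np.repeat(cov["ID"].to_numpy(), len(times)),
            "time_h": np.tile(times, n),
            "conc_total_true": conc.ravel(),
        }
    )
    gt = GroundTruth(
        params=pd.DataFrame({"ID": cov["ID"], **{p: params[p] for p in _PARAM_ORDER}}),
        etas=etas,
        eta_names=eta_names,
        true_conc=tc,
        pb=pbv,
        seed=seed,
    )
    return dataset, gt


def summarize_cohort(
    d: PKDataset,
    ql_total: float = QL_TOTAL,
    ql_unbound: float = QL_UNBOUND,
) -> dict:
    """Cohort-level concentration summary at the three nominal occasions.

    Total-concentration means and SDs at the end-of-infusion sample
    (t < 24 h), the day-8 trough (24-500 h) and the week-6 trough
    (>= 500 h), with QL/2 substituted for below-limit values before
    averaging, plus the matching unbound (free) summaries.  Deterministic
    given the dataset.
    """
    obs = d.observations()
    if len(obs) == 0:
        raise ValueError("dataset has no observations to summarize")

    def impute(series, flags, ql):
        v = series.to_numpy(float).copy()
        v[(v < ql) | (flags.to_numpy() == 1)] = ql / 2.0
        return v

    out: dict = {}
    windows = {"eoi": (0.0, 24.0), "day8_trough": (24.0, 500.0), "week6_trough": (500.0, np.inf)}
    for analyte, ql in (("total", ql_total), ("unbound", ql_unbound)):
        sub = obs[obs["ANALYTE"] == analyte]
        for wname, (lo, hi) in windows.items():
            sel = sub[(sub["TIME"] >= lo) & (sub["TIME"] < hi)]
            if len(sel) == 0:
                continue
            vals = impute(sel["DV"], sel["BQL"], ql)
            key = f"{analyte}_{wname}"
            out[f"{key}_mean"] = float(np.mean(vals))
            out[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out[f"{key}_n"] = int(len(vals))
            out[f"{key}_n_bql"] = int(((sel["DV"] < ql) | (sel["BQL"] == 1)).sum())
    return out
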