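"""Model diagnostics: goodness of fit, visual predictive check,
nonparametric bootstrap, eta-shrinkage, and estimate-correlation
conditioning.

All simulation-based diagnostics reuse the study design of the dataset
(doses, sampling times) and apply the same quantification-limit censoring
and QL/2 imputation as the estimation pipeline, so simulated and observed
summaries are comparable near the assay limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PKDataset, QL_TOTAL
from .estimation import (
    FitResult,
    ModelSpec,
    SAEMSettings,
    _Design,
    _predict,
    _prior_mean,
    fit as _fit,
)
from .util import substream

__all__ = [
    "VPCResult",
    "BootstrapResult",
    "ConditionRatio",
    "gof",
    "vpc",
    "bootstrap",
    "shrinkage",
    "condition_ratio",
]


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def gof(fit_result: FitResult, d: PKDataset) -> dict:
    """Observed-vs-predicted R² for population and individual predictions.

    Population predictions use the typical parameters (plus covariate
    effects, if any); individual predictions use each subject's empirical
    Bayes parameter estimates.  R² is from ordinary least-squares
    regression of observed on predicted concentrations.  Individual R²
    exceeding population R² is the expected signature of informative
    empirical Bayes conditioning.
    """
    design = _Design(d, fit_result.spec)
    if design.n_obs < 3:
        raise ValueError("need at least 3 observations for a goodness-of-fit summary")
    spec = fit_result.spec
    mu = np.log([fit_result.estimates[p] for p in spec.iiv])
    m_prior = _prior_mean(design, spec, mu, fit_result.betas)
    f_pop = _predict(design, spec, m_prior)

    if fit_result.ebe is None:
        raise ValueError("fit has no empirical Bayes estimates (ebe)")
    ebe = fit_result.ebe.set_index("ID")
    eta = np.column_stack(
        [ebe.loc[design.ids, f"eta_{p}_mean"].to_numpy(float) for p in spec.iiv]
    )
    f_ind = _predict(design, spec, m_prior + eta)

    obs = design.obs_dv[design.mask]
    pred_pop = f_pop[design.mask]
    pred_ind = f_ind[design.mask]
    r2_pop = float(stats.linregress(pred_pop, obs).rvalue ** 2)
    r2_ind = float(stats.linregress(pred_ind, obs).rvalue ** 2)
    ids = np.repeat(design.ids, design.mask.sum(axis=1))
    table = pd.DataFrame(
        {
            "ID": ids,
            "time_h": design.obs_times[design.mask],
            "observed": obs,
            "pred_population": pred_pop,
            "pred_individual": pred_ind,
        }
    )
    return {"r2_population": r2_pop, "r2_individual": r2_ind, "table": table}


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------


@dataclass
class VPCResult:
    """Observed percentiles per time bin with simulated prediction bands."""

    bins: np.ndarray                    # representative time per bin
    percentiles: tuple[float, ...]
    observed: np.ndarray                # (n_bins, n_pct)
    band_lower: np.ndarray              # (n_bins, n_pct), 2.5th of simulated pct
    band_median: np.ndarray
    band_upper: np.ndarray              # 97.5th of simulated pct
    n_sim: int
    seed: int

    def coverage(self) -> float:
        """Fraction of observed percentile points inside their bands."""
        inside = (self.observed >= self.band_lower) & (self.observed <= self.band_upper)
        return float(np.mean(inside))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, t in enumerate(self.bins):
            for pi, q in enumerate(self.percentiles):
                rows.append(
                    {
                        "time_h": t,
                        "percentile": q,
                        "observed": self.observed[bi, pi],
                        "band_lower": self.band_lower[bi, pi],
                        "band_median": self.band_median[bi, pi],
                        "band_upper": self.band_upper[bi, pi],
                    }
                )
        return pd.DataFrame(rows)


def vpc(
    fit_result: FitResult,
    d: PKDataset,
    n_sim: int = 10_000,
    percentiles: tuple[float, ...] = (10.0, 50.0, 90.0),
    seed: int = 0,
    ql_total: float = QL_TOTAL,
    max_exact_bins: int = 12,
) -> VPCResult:
    """Visual predictive check on the observed design (total analyte).

    ``n_sim`` replicate datasets are simulated at the observed doses and
    sampling times, with residual error and the same QL censoring + QL/2
    imputation as the real pipeline.  Within each replicate the requested
    percentiles are computed per time bin; the 2.5th-97.5th percentile
    envelope of those simulated percentiles forms the prediction band that
    the observed percentiles are compared against.  Binning is by exact
    nominal time when there are few distinct times, otherwise by time
    quantiles.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    design = _Design(d, fit_result.spec)
    if design.n_obs == 0:
        raise ValueError("dataset has no observations")
    spec = fit_result.spec
    rng = substream(seed, "vpc")
    k = len(spec.iiv)
    mu = np.log([fit_result.estimates[p] for p in spec.iiv])
    omega = np.array([fit_result.omega[p] for p in spec.iiv])
    m_prior = _prior_mean(design, spec, mu, fit_result.betas)

    times_flat = design.obs_times[design.mask]
    obs_flat = design.obs_dv[design.mask]
    uniq = np.unique(times_flat)
    if len(uniq) <= max_exact_bins:
        bin_idx = np.searchsorted(uniq, times_flat)
        bin_times = uniq
    else:
        edges = np.quantile(times_flat, np.linspace(0, 1, max_exact_bins + 1))
        edges = np.unique(edges)
        bin_idx = np.clip(np.searchsorted(edges, times_flat, side="right") - 1, 0, len(edges) - 2)
        bin_times = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(bin_times)

    # simulate: (n_sim, n_obs_total)
    sim_rows = np.empty((n_sim, design.n_obs))
    counts = design.mask.sum(axis=1)
    col_ofs = np.concatenate([[0], np.cumsum(counts)])
    chunk = max(1, int(2_000_000 // max(design.n_obs, 1)))
    b_err = fit_result.error.get("b", 0.0)
    a_err = fit_result.error.get("a", 0.0)
    for lo in range(0, n_sim, chunk):
        hi = min(lo + chunk, n_sim)
        nb = hi - lo
        for i in range(design.n):
            eta = rng.standard_normal((nb, k)) * omega[None, :]
            phi = m_prior[i][None, :] + eta
            from .model import conc_many

            exp_phi = np.exp(phi)
            cols = {p: exp_phi[:, j] for j, p in enumerate(spec.iiv)}
            fixed = spec.fixed_map

            def get(name):
                return cols[name] if name in cols else np.full(nb, fixed[name])

            CL, V1 = get("CL"), get("V1")
            if spec.n_compartments == 1:
                Q, V2 = np.zeros(nb), np.ones(nb)
            else:
                Q, V2 = get("Q"), get("V2")
            t_i = design.obs_times[i][design.mask[i]]
            fv = conc_many(CL, V1, Q, V2, design.dose_starts[i], design.dose_amts[i],
                           design.dose_durs[i], t_i)
            eps = rng.standard_normal(fv.shape)
            y = fv + (a_err + b_err * fv) * eps if spec.error_model != "proportional" else fv * (1 + b_err * eps)
            y = np.where(y < ql_total, ql_total / 2.0, y)
            sim_rows[lo:hi, col_ofs[i]:col_ofs[i + 1]] = y

    sim_pct = np.empty((n_sim, n_bins, len(percentiles)))
    obs_pct = np.empty((n_bins, len(percentiles)))
    for bi in range(n_bins):
        sel = bin_idx == bi
        if not np.any(sel):
            raise ValueError(f"empty time bin at t={bin_times[bi]}")
        obs_pct[bi] = np.percentile(obs_flat[sel], percentiles)
        sim_pct[:, bi, :] = np.percentile(sim_rows[:, sel], percentiles, axis=1).T
    return VPCResult(
        bins=bin_times,
        percentiles=tuple(percentiles),
        observed=obs_pct,
        band_lower=np.percentile(sim_pct, 2.5, axis=0),
        band_median=np.percentile(sim_pct, 50.0, axis=0),
        band_upper=np.percentile(sim_pct, 97.5, axis=0),
        n_sim=n_sim,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Nonparametric bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Per-parameter re-estimates from subject-resampled replicates."""

    replicates: pd.DataFrame
    mean: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    n_requested: int
    n_failed: int
    quality_warning: bool
    seed: int


def bootstrap(
    d: PKDataset,
    spec: ModelSpec | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    settings: SAEMSettings | None = None,
    init: dict | None = None,
    n_jobs: int = 1,
) -> BootstrapResult:
    """Nonparametric bootstrap by whole-subject resampling.

    Subjects (not records) are resampled with replacement to the original
    cohort size and the model refitted on each replicate; sparse repeated
    measures make record-level resampling invalid.  Failed refits are
    excluded and counted; more than 20% failures raises the quality flag.
    Confidence intervals are 2.5th/97.5th percentiles of the replicate
    estimates.  Bit-reproducible for a given seed in serial mode; the
    parallel path uses the same per-replicate substreams.
    """
    spec = spec or ModelSpec()
    settings = settings or SAEMSettings.fast()
    ids = sorted(d.records["ID"].unique().tolist())
    if len(ids) < 3:
        raise ValueError("bootstrap needs at least 3 subjects")

    def one(b: int):
        rng = substream(seed, "bootstrap", str(b))
        chosen = rng.choice(len(ids), size=len(ids), replace=True)
        frames = []
        for new_id, idx in enumerate(chosen, start=1):
            block = d.records[d.records["ID"] == ids[idx]].copy()
            block["ID"] = new_id
            frames.append(block)
        rep = PKDataset(pd.concat(frames, ignore_index=True))
        try:
            fr = _fit(rep, spec, init=init, settings=settings, seed=int(rng.integers(2**31 - 1)))
        except Exception:
            return None
        row = {f"theta_{p}": fr.estimates[p] for p in spec.iiv}
        row.update({f"omega_{p}": fr.omega[p] for p in spec.iiv})
        row.update({f"error_{n}": v for n, v in fr.error.items()})
        row.update({f"beta_{k}": v for k, v in fr.betas.items()})
        return row

    if n_jobs > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(one)(b) for b in range(n_boot))
    else:
        rows = [one(b) for b in range(n_boot)]
    ok = [r for r in rows if r is not None]
    n_failed = n_boot - len(ok)
    if not ok:
        raise RuntimeError("all bootstrap replicates failed")
    reps = pd.DataFrame(ok)
    return BootstrapResult(
        replicates=reps,
        mean={c: float(reps[c].mean()) for c in reps.columns},
        ci_lower={c: float(np.percentile(reps[c], 2.5)) for c in reps.columns},
        ci_upper={c: float(np.percentile(reps[c], 97.5)) for c in reps.columns},
        n_requested=n_boot,
        n_failed=n_failed,
        quality_warning=n_failed > 0.2 * n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Shrinkage and conditioning
# ---------------------------------------------------------------------------


def shrinkage(fit_result: FitResult) -> dict[str, float]:
    """Eta-shrinkage (%) per random effect: ``100 * (1 - SD(EBE eta)/omega)``.

    Near 0% when the data inform every individual's random effect; near
    100% when empirical Bayes estimates collapse to the population mean
    (flat individual likelihoods).
    """
    if fit_result.ebe is None:
        raise ValueError("fit has no empirical Bayes estimates")
    out = {}
    for p, w in fit_result.omega.items():
        eta = fit_result.ebe[f"eta_{p}_mean"].to_numpy(float)
        if w <= 0:
            out[p] = float("nan")
        else:
            out[p] = float(100.0 * (1.0 - np.std(eta, ddof=1) / w))
    return out


@dataclass
class ConditionRatio:
    value: float
    capped: bool


def condition_ratio(fit_result: FitResult, cap: float = 1e12) -> ConditionRatio:
    """Max/min eigenvalue ratio of the estimates' correlation matrix.

    Requires a covariance estimate (run :func:`standard_errors` with the
    FIM method first, or attach a bootstrap correlation).  Ratios at or
    above ``cap`` — including non-positive minimum eigenvalues — are
    returned capped and flagged as a sign of overparameterization.
    """
    corr = fit_result.correlation
    if corr is None:
        raise ValueError(
            "no covariance estimate on this fit; run standard_errors(..., method='fim') first"
        )
    evals = np.linalg.eigvalsh(corr)
    lo, hi = float(np.min(evals)), float(np.max(evals))
    if lo <= 0 or hi / lo >= cap:
        return ConditionRatio(value=cap, capped=True)
    return ConditionRatio(value=hi / lo, capped=False)
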