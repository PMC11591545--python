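"""Nonlinear mixed-effects estimation by stochastic approximation EM (SAEM).

The statistical model: for subject i with log-parameter vector
``phi_i = mu + Beta * x_i + eta_i``, ``eta_i ~ N(0, diag(omega**2))``
(log-normal inter-individual variability, optional power-law covariate
effects on the median-normalized covariates), observed concentrations

    y_ij = f(exp(phi_i), t_ij) * (1 + b * eps_ij)       (proportional)

or with constant / combined residual error.  ``f`` is the closed-form
one- or two-compartment infusion model, so each SAEM iteration is cheap
and fully vectorized across subjects.

The SAEM loop alternates Metropolis-Hastings sampling of the individual
``phi_i`` from their conditional distributions (an independence kernel
from the prior plus adaptive random-walk kernels) with stochastic-
approximation updates of the sufficient statistics and exact M-steps
(linear regression for ``mu``/``Beta``, moment updates for ``omega``,
closed form for the residual SD).  Variance estimates are annealed during
the exploration phase so they cannot collapse before the individual
samples have found the high-likelihood region.

Marginal likelihood (OFV = -2 log L) is computed after fitting, either by
Monte Carlo importance sampling around the per-subject conditional modes
(the default, mirroring common practice) or by the Laplace approximation
(deterministic; used for covariate selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .dataset import PKDataset
from .model import PKParams, conc_many
from .util import substream

__all__ = [
    "ModelSpec",
    "SAEMSettings",
    "FitResult",
    "LikelihoodResult",
    "CovariateSearchResult",
    "fit",
    "log_likelihood",
    "covariate_search",
    "standard_errors",
    "result_from_popmodel",
]

_LOG2PI = math.log(2.0 * math.pi)

#: Default initial typical values (published dalbavancin estimates from
#: earlier cohorts, deliberately away from any particular dataset's truth).
DEFAULT_INIT = {"CL": 0.057, "V1": 10.0, "Q": 0.476, "V2": 10.0}
DEFAULT_INIT_1CMT = {"CL": 0.057, "V1": 20.0}


@dataclass(frozen=True)
class ModelSpec:
    """Structural / stochastic model specification.

    ``fixed`` maps parameter names to constants excluded from estimation
    and from IIV (the final dalbavancin model fixes Q = 0.476 L/h).
    Every non-fixed structural parameter must carry IIV — the estimation
    scheme samples individual log-parameters, so purely fixed-effect free
    parameters are not supported.  ``covariates`` lists (parameter,
    covariate-column) pairs entering as power models on the
    median-normalized covariate.
    """

    n_compartments: int = 2
    fixed: tuple[tuple[str, float], ...] = (("Q", 0.476),)
    error_model: str = "proportional"
    iiv: tuple[str, ...] = ("CL", "V1", "V2")
    covariates: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise NotImplementedError(
                "only one- and two-compartment structural models are supported"
            )
        if self.error_model not in ("proportional", "constant", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        fixed_names = {k for k, _ in self.fixed}
        if fixed_names & set(self.iiv):
            raise ValueError("fixed parameters cannot carry IIV")
        for name in self.structural_names:
            if name not in fixed_names and name not in self.iiv:
                raise ValueError(
                    f"free structural parameter {name!r} must carry IIV "
                    "(or be fixed)"
                )
        for name in self.iiv:
            if name not in self.structural_names:
                raise ValueError(f"IIV on unknown parameter {name!r}")
        for p, _ in self.covariates:
            if p not in self.iiv:
                raise ValueError(f"covariate effect on non-IIV parameter {p!r}")

    @property
    def structural_names(self) -> tuple[str, ...]:
        return ("CL", "V1") if self.n_compartments == 1 else ("CL", "V1", "Q", "V2")

    @property
    def fixed_map(self) -> dict[str, float]:
        return dict(self.fixed)

    @property
    def n_error_params(self) -> int:
        return 2 if self.error_model == "combined" else 1

    @property
    def n_free(self) -> int:
        """Free parameters counted by AIC/BIC: typical values with IIV,
        their omegas, residual error parameters and covariate exponents."""
        return 2 * len(self.iiv) + self.n_error_params + len(self.covariates)

    def with_covariate(self, param: str, cov: str) -> "ModelSpec":
        return dc_replace(self, covariates=self.covariates + ((param, cov),))

    def without_covariate(self, param: str, cov: str) -> "ModelSpec":
        new = tuple(pc for pc in self.covariates if pc != (param, cov))
        return dc_replace(self, covariates=new)


@dataclass(frozen=True)
class SAEMSettings:
    """Iteration schedule and numerical controls of the SAEM fit."""

    n_exploration: int = 400
    n_smoothing: int = 200
    mh_random_walk: int = 2
    anneal: float = 0.95
    tol: float = 1e-3
    omega_floor: float = 0.02
    error_floor: float = 1e-4
    ebe_burn: int = 100
    ebe_samples: int = 300

    @classmethod
    def fast(cls) -> "SAEMSettings":
        """Reduced schedule for bootstraps and repeated-fit experiments."""
        return cls(n_exploration=160, n_smoothing=80, ebe_burn=50, ebe_samples=150)


@dataclass
class LikelihoodResult:
    ofv: float
    aic: float
    bic: float
    mc_se: float
    n_mc: int
    method: str
    seed: int | None


@dataclass
class FitResult:
    """Population estimates with diagnostics hooks.

    ``estimates`` holds every structural parameter (fixed ones included),
    ``omega`` the IIV standard deviations, ``error`` the residual error
    parameters, ``betas`` the covariate exponents keyed ``"param~COV"``.
    ``ebe`` carries per-subject empirical Bayes summaries (conditional
    means and SDs of the random effects and the individual parameters).
    """

    spec: ModelSpec
    estimates: dict[str, float]
    omega: dict[str, float]
    error: dict[str, float]
    betas: dict[str, float]
    cov_medians: dict[str, float]
    converged: bool
    trajectory: pd.DataFrame | None
    ebe: pd.DataFrame | None
    seed: int | None
    settings: SAEMSettings | None
    n_free: int
    ofv: float | None = None
    aic: float | None = None
    bic: float | None = None
    mc_se: float | None = None
    rse: dict[str, float] | None = None
    covariance: np.ndarray | None = None
    correlation: np.ndarray | None = None
    psi_names: list[str] | None = None

    @property
    def pk_params(self) -> PKParams:
        e = self.estimates
        if self.spec.n_compartments == 1:
            return PKParams(CL=e["CL"], V1=e["V1"], Q=0.0, V2=1.0)
        return PKParams(CL=e["CL"], V1=e["V1"], Q=e["Q"], V2=e["V2"])

    def to_json_dict(self) -> dict:
        return {
            "spec": {
                "n_compartments": self.spec.n_compartments,
                "fixed": dict(self.spec.fixed),
                "error_model": self.spec.error_model,
                "iiv": list(self.spec.iiv),
                "covariates": [list(pc) for pc in self.spec.covariates],
            },
            "estimates": self.estimates,
            "omega": self.omega,
            "error": self.error,
            "betas": self.betas,
            "cov_medians": self.cov_medians,
            "converged": self.converged,
            "n_free": self.n_free,
            "ofv": self.ofv,
            "aic": self.aic,
            "bic": self.bic,
            "rse": self.rse,
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "FitResult":
        s = payload["spec"]
        spec = ModelSpec(
            n_compartments=s["n_compartments"],
            fixed=tuple(sorted(s["fixed"].items())),
            error_model=s["error_model"],
            iiv=tuple(s["iiv"]),
            covariates=tuple(tuple(pc) for pc in s["covariates"]),
        )
        return cls(
            spec=spec,
            estimates={k: float(v) for k, v in payload["estimates"].items()},
            omega={k: float(v) for k, v in payload["omega"].items()},
            error={k: float(v) for k, v in payload["error"].items()},
            betas={k: float(v) for k, v in payload.get("betas", {}).items()},
            cov_medians={k: float(v) for k, v in payload.get("cov_medians", {}).items()},
            converged=bool(payload.get("converged", True)),
            trajectory=None,
            ebe=None,
            seed=payload.get("seed"),
            settings=None,
            n_free=int(payload["n_free"]),
            ofv=payload.get("ofv"),
            aic=payload.get("aic"),
            bic=payload.get("bic"),
            rse=payload.get("rse"),
        )

    def summary_table(self) -> str:
        """Human-readable estimates table (parameter, estimate, RSE%)."""
        lines = [f"{'Parameter':<12}{'Estimate':>12}{'RSE %':>10}"]

        def rse_of(key: str) -> str:
            if not self.rse or key not in self.rse:
                return "-"
            return f"{self.rse[key]:.3g}"

        for p in self.spec.structural_names:
            tag = " (fixed)" if p in self.spec.fixed_map else ""
            lines.append(f"{p + tag:<12}{self.estimates[p]:>12.4g}{rse_of('theta_' + p):>10}")
        for key, g in self.betas.items():
            lines.append(f"{'beta ' + key:<12}{g:>12.4g}{rse_of('beta_' + key):>10}")
        for p, w in self.omega.items():
            lines.append(f"{'omega_' + p:<12}{w:>12.4g}{rse_of('omega_' + p):>10}")
        for name, v in self.error.items():
            lines.append(f"{name:<12}{v:>12.4g}{rse_of('error_' + name):>10}")
        return "\n".join(lines)


def result_from_popmodel(m, spec: ModelSpec | None = None) -> FitResult:
    """Wrap a known population model as a FitResult (for simulation-based
    diagnostics without an estimation step)."""
    spec = spec or ModelSpec()
    estimates = m.typical.as_dict()
    if spec.n_compartments == 1:
        estimates = {k: estimates[k] for k in ("CL", "V1")}
    return FitResult(
        spec=spec,
        estimates=estimates,
        omega=dict(m.omega),
        error={"b": m.error_b},
        betas={},
        cov_medians={},
        converged=True,
        trajectory=None,
        ebe=None,
        seed=None,
        settings=None,
        n_free=spec.n_free,
    )


# ---------------------------------------------------------------------------
# Internal design matrices
# ---------------------------------------------------------------------------


class _Design:
    """Padded per-subject dose and observation arrays for vectorized math."""

    def __init__(self, d: PKDataset, spec: ModelSpec):
        recs = d.records
        ids = sorted(recs["ID"].unique().tolist())
        self.ids = ids
        self.n = len(ids)
        doses, obs = [], []
        for sid in ids:
            sub = recs[recs["ID"] == sid]
            dr = sub[sub["EVID"] == 1]
            orows = sub[(sub["EVID"] == 0) & (sub["ANALYTE"] == "total")]
            if len(orows) == 0:
                raise ValueError(f"subject {sid}: no total-concentration observations")
            doses.append(
                (dr["TIME"].to_numpy(float), dr["AMT"].to_numpy(float), dr["DUR"].to_numpy(float))
            )
            obs.append((orows["TIME"].to_numpy(float), orows["DV"].to_numpy(float)))
        dmax = max(len(s) for s, _, _ in doses)
        mmax = max(len(t) for t, _ in obs)
        self.dose_starts = np.zeros((self.n, dmax))
        self.dose_amts = np.zeros((self.n, dmax))
        self.dose_durs = np.ones((self.n, dmax))
        self.obs_times = np.zeros((self.n, mmax))
        self.obs_dv = np.ones((self.n, mmax))
        self.mask = np.zeros((self.n, mmax), dtype=bool)
        for i, ((s, a, du), (t, y)) in enumerate(zip(doses, obs)):
            self.dose_starts[i, : len(s)] = s
            self.dose_amts[i, : len(a)] = a
            self.dose_durs[i, : len(du)] = du
            self.obs_times[i, : len(t)] = t
            self.obs_dv[i, : len(y)] = y
            self.mask[i, : len(t)] = True
        self.n_obs = int(self.mask.sum())

        # covariate designs: one column per (param, covariate) pair
        self.cov_values: dict[str, np.ndarray] = {}
        self.cov_medians: dict[str, float] = {}
        cov_table = d.covariates()
        needed = sorted({c for _, c in spec.covariates})
        problems = []
        for c in needed:
            if c not in cov_table.columns:
                problems.append(f"covariate column {c!r} absent from dataset")
                continue
            vals = cov_table.loc[ids, c].to_numpy(float)
            bad = [ids[j] for j in np.flatnonzero(~np.isfinite(vals) | (vals <= 0))]
            if bad:
                problems.append(f"covariate {c!r} missing/nonpositive for subjects: {bad}")
                continue
            med = float(np.median(vals))
            self.cov_medians[c] = med
            self.cov_values[c] = np.log(vals / med)
        if problems:
            raise ValueError("covariate problems:\n  " + "\n  ".join(problems))

        # regression design Z_p = [1 | x_cols] per IIV parameter
        self.Z: dict[str, np.ndarray] = {}
        self.z_covs: dict[str, list[str]] = {}
        for p in spec.iiv:
            cols = [c for q, c in spec.covariates if q == p]
            self.z_covs[p] = cols
            self.Z[p] = np.column_stack(
                [np.ones(self.n)] + [self.cov_values[c] for c in cols]
            )


def _predict(design: _Design, spec: ModelSpec, phi: np.ndarray) -> np.ndarray:
    """Model concentrations (n, mmax) from individual log-parameters."""
    exp_phi = np.exp(phi)
    cols = {p: exp_phi[:, j] for j, p in enumerate(spec.iiv)}
    fixed = spec.fixed_map

    def get(name, default):
        if name in cols:
            return cols[name]
        return np.full(design.n, fixed.get(name, default))

    CL = get("CL", np.nan)
    V1 = get("V1", np.nan)
    if spec.n_compartments == 1:
        Q = np.zeros(design.n)
        V2 = np.ones(design.n)
    else:
        Q = get("Q", np.nan)
        V2 = get("V2", np.nan)
    return conc_many(
        CL, V1, Q, V2, design.dose_starts, design.dose_amts, design.dose_durs, design.obs_times
    )


def _loglik_obs(design: _Design, spec: ModelSpec, f: np.ndarray, error: dict) -> np.ndarray:
    """Per-subject observation log-likelihood (n,); -inf where infeasible."""
    y = design.obs_dv
    if spec.error_model == "proportional":
        sd = error["b"] * f
    elif spec.error_model == "constant":
        sd = np.full_like(f, error["a"])
    else:
        sd = error["a"] + error["b"] * f
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = -0.5 * ((y - f) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI
    ll = np.where(design.mask, ll, 0.0)
    bad = design.mask & ~np.isfinite(ll)
    out = np.where(np.any(bad, axis=1), -np.inf, np.nansum(np.where(design.mask, ll, 0.0), axis=1))
    return out


def _prior_mean(design: _Design, spec: ModelSpec, mu: np.ndarray, betas: dict) -> np.ndarray:
    """Per-subject prior means of phi (n, k)."""
    m = np.tile(mu, (design.n, 1))
    for j, p in enumerate(spec.iiv):
        for c in design.z_covs[p]:
            m[:, j] += betas[f"{p}~{c}"] * design.cov_values[c]
    return m


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------


def _init_values(spec: ModelSpec, init: dict | None) -> dict[str, float]:
    base = dict(DEFAULT_INIT_1CMT if spec.n_compartments == 1 else DEFAULT_INIT)
    base.update(spec.fixed_map)
    if init:
        base.update(init)
    for p in spec.iiv:
        if base.get(p, 0) <= 0:
            raise ValueError(f"initial value for {p} must be positive")
    return base


def _mstep_error(spec: ModelSpec, s_res, s_fbar, s_ebar, design, error):
    """Closed-form (or 1-2 dim numeric) residual-error M-step."""
    if spec.error_model == "proportional":
        return {"b": math.sqrt(max(s_res / design.n_obs, 0.0))}
    if spec.error_model == "constant":
        return {"a": math.sqrt(max(s_res / design.n_obs, 0.0))}
    mask = design.mask

    def nll(logab):
        a, b = np.exp(logab)
        sd = a + b * s_fbar
        with np.errstate(divide="ignore"):
            val = np.where(mask, np.log(sd) + s_ebar / (2.0 * sd**2), 0.0)
        return float(np.sum(val))

    x0 = np.log([max(error.get("a", 1.0), 1e-6), max(error.get("b", 0.1), 1e-6)])
    res = minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-8})
    a, b = np.exp(res.x)
    return {"a": float(a), "b": float(b)}


def fit(
    d: PKDataset,
    spec: ModelSpec | None = None,
    init: dict | None = None,
    settings: SAEMSettings | None = None,
    seed: int = 0,
) -> FitResult:
    """Maximum-marginal-likelihood fit of the population model by SAEM.

    Only total-concentration observation records enter the fit; the
    dataset is expected to have been BQL-imputed beforehand (see
    :func:`dalbapk.dataset.impute_bql`).  Subjects are processed in sorted
    ID order, so record order in the input never affects the result.
    Deterministic given ``seed`` and ``settings``; a fit that fails the
    relative-change convergence check is returned with
    ``converged=False`` rather than raising.
    """
    spec = spec or ModelSpec()
    settings = settings or SAEMSettings()
    design = _Design(d, spec)
    rng = substream(seed, "saem")
    k = len(spec.iiv)
    init_vals = _init_values(spec, init)

    mu = np.log([init_vals[p] for p in spec.iiv])
    omega = np.full(k, 0.3)
    betas = {f"{p}~{c}": 0.0 for p, c in spec.covariates}
    if spec.error_model == "proportional":
        error = {"b": 0.2}
    elif spec.error_model == "constant":
        error = {"a": 10.0}
    else:
        error = {"a": 5.0, "b": 0.1}

    m_prior = _prior_mean(design, spec, mu, betas)
    phi = m_prior + 0.1 * rng.standard_normal((design.n, k))
    f = _predict(design, spec, phi)
    ll_obs = _loglik_obs(design, spec, f, error)

    # smoothed sufficient statistics
    s_phi = phi.copy()
    s_phi2 = phi**2
    s_res = 0.0
    s_fbar = f.copy()
    s_ebar = (design.obs_dv - f) ** 2
    step = 0.4
    traj_rows = []
    n_iter = settings.n_exploration + settings.n_smoothing

    for it in range(1, n_iter + 1):
        explor = it <= settings.n_exploration
        gamma = 1.0 if explor else 1.0 / (it - settings.n_exploration)

        # --- MH kernel 1: independence proposal from the prior -------------
        prop = m_prior + omega[None, :] * rng.standard_normal((design.n, k))
        f_prop = _predict(design, spec, prop)
        ll_prop = _loglik_obs(design, spec, f_prop, error)
        acc = np.log(rng.random(design.n)) < (ll_prop - ll_obs)
        phi[acc] = prop[acc]
        f[acc] = f_prop[acc]
        ll_obs[acc] = ll_prop[acc]

        # --- MH kernel 2: adaptive random walk ------------------------------
        for _ in range(settings.mh_random_walk):
            prop = phi + step * omega[None, :] * rng.standard_normal((design.n, k))
            f_prop = _predict(design, spec, prop)
            ll_prop = _loglik_obs(design, spec, f_prop, error)
            dprior = -0.5 * np.sum(
                ((prop - m_prior) ** 2 - (phi - m_prior) ** 2) / omega[None, :] ** 2, axis=1
            )
            acc = np.log(rng.random(design.n)) < (ll_prop - ll_obs + dprior)
            phi[acc] = prop[acc]
            f[acc] = f_prop[acc]
            ll_obs[acc] = ll_prop[acc]
            rate = float(np.mean(acc))
            step *= 1.1 if rate > 0.35 else (1 / 1.1 if rate < 0.2 else 1.0)
            step = min(max(step, 0.01), 2.0)

        # --- stochastic approximation of sufficient statistics --------------
        s_phi = (1 - gamma) * s_phi + gamma * phi
        s_phi2 = (1 - gamma) * s_phi2 + gamma * phi**2
        if spec.error_model == "proportional":
            resid = np.where(design.mask, ((design.obs_dv - f) / np.where(f > 0, f, 1.0)) ** 2, 0.0)
            s_res = (1 - gamma) * s_res + gamma * float(resid.sum())
        elif spec.error_model == "constant":
            resid = np.where(design.mask, (design.obs_dv - f) ** 2, 0.0)
            s_res = (1 - gamma) * s_res + gamma * float(resid.sum())
        else:
            s_fbar = (1 - gamma) * s_fbar + gamma * f
            s_ebar = (1 - gamma) * s_ebar + gamma * (design.obs_dv - f) ** 2

        # --- M-step ----------------------------------------------------------
        new_omega2 = np.empty(k)
        for j, p in enumerate(spec.iiv):
            Z = design.Z[p]
            zt_s = Z.T @ s_phi[:, j]
            coef = np.linalg.solve(Z.T @ Z, zt_s)
            mu[j] = coef[0]
            for c_idx, c in enumerate(design.z_covs[p], start=1):
                betas[f"{p}~{c}"] = coef[c_idx]
            new_omega2[j] = (
                float(np.mean(s_phi2[:, j]))
                - 2.0 * float(coef @ zt_s) / design.n
                + float(coef @ (Z.T @ Z) @ coef) / design.n
            )
        new_omega2 = np.maximum(new_omega2, settings.omega_floor**2)
        if explor:
            new_omega2 = np.maximum(new_omega2, (settings.anneal * omega) ** 2)
        omega = np.sqrt(new_omega2)

        new_error = _mstep_error(spec, s_res, s_fbar, s_ebar, design, error)
        for name, v in new_error.items():
            v = max(v, settings.error_floor)
            if explor:
                v = max(v, settings.anneal * error.get(name, 0.0))
            error[name] = v

        m_prior = _prior_mean(design, spec, mu, betas)
        row = {"iteration": it}
        row.update({f"mu_{p}": math.exp(mu[j]) for j, p in enumerate(spec.iiv)})
        row.update({f"omega_{p}": omega[j] for j, p in enumerate(spec.iiv)})
        row.update({f"error_{n}": v for n, v in error.items()})
        row.update({f"beta_{kk}": v for kk, v in betas.items()})
        traj_rows.append(row)

    traj = pd.DataFrame(traj_rows)
    est_cols = [c for c in traj.columns if c != "iteration"]
    lookback = min(10, settings.n_smoothing - 1) if settings.n_smoothing > 1 else 1
    last = traj[est_cols].iloc[-1]
    prev = traj[est_cols].iloc[-1 - lookback]
    denom = np.maximum(np.abs(last.to_numpy()), 1e-12)
    converged = bool(np.max(np.abs(last.to_numpy() - prev.to_numpy()) / denom) < settings.tol * lookback)

    # --- empirical Bayes pass (conditional means / SDs at final estimates) --
    ebe = _ebe_pass(design, spec, mu, omega, betas, error, settings, seed)

    estimates = {}
    for p in spec.structural_names:
        if p in spec.fixed_map:
            estimates[p] = float(spec.fixed_map[p])
        else:
            estimates[p] = float(math.exp(mu[spec.iiv.index(p)]))
    result = FitResult(
        spec=spec,
        estimates=estimates,
        omega={p: float(omega[j]) for j, p in enumerate(spec.iiv)},
        error={n: float(v) for n, v in error.items()},
        betas={kk: float(v) for kk, v in betas.items()},
        cov_medians=dict(design.cov_medians),
        converged=converged,
        trajectory=traj,
        ebe=ebe,
        seed=seed,
        settings=settings,
        n_free=spec.n_free,
    )
    result._design = design  # cached for diagnostics on the same dataset
    return result


def _ebe_pass(design, spec, mu, omega, betas, error, settings, seed) -> pd.DataFrame:
    """Conditional means and SDs of the random effects by MCMC at fixed
    population estimates."""
    rng = substream(seed, "ebe")
    k = len(spec.iiv)
    m_prior = _prior_mean(design, spec, mu, betas)
    phi = m_prior.copy()
    f = _predict(design, spec, phi)
    ll_obs = _loglik_obs(design, spec, f, error)
    step = 0.4
    acc_mean = np.zeros((design.n, k))
    acc_sq = np.zeros((design.n, k))
    kept = 0
    for it in range(settings.ebe_burn + settings.ebe_samples):
        prop = m_prior + omega[None, :] * rng.standard_normal((design.n, k))
        f_prop = _predict(design, spec, prop)
        ll_prop = _loglik_obs(design, spec, f_prop, error)
        acc = np.log(rng.random(design.n)) < (ll_prop - ll_obs)
        phi[acc] = prop[acc]
        f[acc] = f_prop[acc]
        ll_obs[acc] = ll_prop[acc]
        for _ in range(2):
            prop = phi + step * omega[None, :] * rng.standard_normal((design.n, k))
            f_prop = _predict(design, spec, prop)
            ll_prop = _loglik_obs(design, spec, f_prop, error)
            dprior = -0.5 * np.sum(
                ((prop - m_prior) ** 2 - (phi - m_prior) ** 2) / omega[None, :] ** 2, axis=1
            )
            acc = np.log(rng.random(design.n)) < (ll_prop - ll_obs + dprior)
            phi[acc] = prop[acc]
            f[acc] = f_prop[acc]
            ll_obs[acc] = ll_prop[acc]
            rate = float(np.mean(acc))
            step *= 1.1 if rate > 0.35 else (1 / 1.1 if rate < 0.2 else 1.0)
            step = min(max(step, 0.01), 2.0)
        if it >= settings.ebe_burn:
            eta = phi - m_prior
            acc_mean += eta
            acc_sq += eta**2
            kept += 1
    eta_mean = acc_mean / kept
    eta_sd = np.sqrt(np.maximum(acc_sq / kept - eta_mean**2, 0.0))
    data = {"ID": design.ids}
    for j, p in enumerate(spec.iiv):
        data[f"eta_{p}_mean"] = eta_mean[:, j]
        data[f"eta_{p}_sd"] = eta_sd[:, j]
        data[f"{p}_individual"] = np.exp(m_prior[:, j] + eta_mean[:, j])
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Marginal likelihood
# ---------------------------------------------------------------------------


def _subject_closure(design: _Design, spec: ModelSpec, i: int, mu_i, omega, error):
    """Return logpost(eta) and a vectorized batch version for subject i."""
    starts = design.dose_starts[i]
    amts = design.dose_amts[i]
    durs = design.dose_durs[i]
    times = design.obs_times[i][design.mask[i]]
    y = design.obs_dv[i][design.mask[i]]
    fixed = spec.fixed_map
    iiv = spec.iiv

    def param_arrays(phi_batch):
        cols = {p: np.exp(phi_batch[:, j]) for j, p in enumerate(iiv)}

        def get(name):
            if name in cols:
                return cols[name]
            return np.full(phi_batch.shape[0], fixed[name])

        CL, V1 = get("CL"), get("V1")
        if spec.n_compartments == 1:
            return CL, V1, np.zeros_like(CL), np.ones_like(CL)
        return CL, V1, get("Q"), get("V2")

    if spec.error_model == "proportional":
        sd_fn = lambda fv: error["b"] * fv
    elif spec.error_model == "constant":
        sd_fn = lambda fv: np.full_like(fv, error["a"])
    else:
        sd_fn = lambda fv: error["a"] + error["b"] * fv

    def batch_logpost(eta_batch):
        phi_batch = mu_i[None, :] + eta_batch
        CL, V1, Q, V2 = param_arrays(phi_batch)
        fv = conc_many(CL, V1, Q, V2, starts, amts, durs, times)
        sd = sd_fn(fv)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = -0.5 * ((y[None, :] - fv) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI
        ll = np.where(np.isfinite(ll), ll, -np.inf).sum(axis=1)
        lp = -0.5 * np.sum(eta_batch**2 / omega[None, :] ** 2, axis=1) - np.sum(
            np.log(omega)
        ) - 0.5 * len(omega) * _LOG2PI
        return ll + lp

    def logpost(eta):
        return float(batch_logpost(np.asarray(eta, dtype=float)[None, :])[0])

    return logpost, batch_logpost


def _subject_mode(logpost, k, start=None):
    if start is None:
        res = minimize(lambda e: -logpost(e), np.zeros(k), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 600})
        start = res.x
    res2 = minimize(lambda e: -logpost(e), start, method="BFGS",
                    options={"gtol": 1e-8})
    return res2.x


def _numeric_hessian(fn, x, h=1e-4):
    k = len(x)
    H = np.empty((k, k))
    f0 = fn(x)
    for a in range(k):
        for b in range(a, k):
            ha = h * (1 + abs(x[a]))
            hb = h * (1 + abs(x[b]))
            if a == b:
                xp = x.copy(); xp[a] += ha
                xm = x.copy(); xm[a] -= ha
                H[a, a] = (fn(xp) - 2 * f0 + fn(xm)) / ha**2
            else:
                xpp = x.copy(); xpp[a] += ha; xpp[b] += hb
                xpm = x.copy(); xpm[a] += ha; xpm[b] -= hb
                xmp = x.copy(); xmp[a] -= ha; xmp[b] += hb
                xmm = x.copy(); xmm[a] -= ha; xmm[b] -= hb
                H[a, b] = H[b, a] = (fn(xpp) - fn(xpm) - fn(xmp) + fn(xmm)) / (4 * ha * hb)
    return H


def _m2ll(design, spec, mu, omega, betas, error, method, n_mc, seed, inflation=1.5,
          mode_cache: dict | None = None):
    """-2 log marginal likelihood by Laplace or importance sampling.

    ``mode_cache`` (subject index -> last conditional mode) warm-starts the
    inner optimizations across repeated calls with nearby parameters, e.g.
    while differentiating the objective for standard errors.
    """
    m_prior = _prior_mean(design, spec, mu, betas)
    k = len(spec.iiv)
    total = 0.0
    var_sum = 0.0
    rng = substream(seed if seed is not None else 0, "ofv")
    for i in range(design.n):
        logpost, batch_logpost = _subject_closure(design, spec, i, m_prior[i], omega, error)
        start = None if mode_cache is None else mode_cache.get(i)
        mode = _subject_mode(logpost, k, start=start)
        if mode_cache is not None:
            mode_cache[i] = mode
        H = _numeric_hessian(lambda e: -logpost(e), mode)
        H = 0.5 * (H + H.T)
        try:
            evals = np.linalg.eigvalsh(H)
            if np.min(evals) <= 0:
                raise np.linalg.LinAlgError
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"degenerate conditional curvature for subject {design.ids[i]}; "
                "consider a larger proposal inflation factor or the Laplace method"
            )
        sign, logdet = np.linalg.slogdet(H)
        if method == "laplace":
            total += -2.0 * (logpost(mode) + 0.5 * k * _LOG2PI - 0.5 * logdet)
            continue
        # importance sampling around the conditional mode
        L = np.linalg.cholesky(inflation**2 * Hinv)
        z = rng.standard_normal((n_mc, k))
        draws = mode[None, :] + z @ L.T
        lp = batch_logpost(draws)
        logq = (
            -0.5 * np.sum(z**2, axis=1)
            - 0.5 * k * _LOG2PI
            - np.sum(np.log(np.diag(L)))
        )
        logw = lp - logq
        li = logsumexp(logw) - math.log(n_mc)
        w = np.exp(logw - np.max(logw))
        var_li = float(np.var(w) / (n_mc * np.mean(w) ** 2))
        total += -2.0 * li
        var_sum += 4.0 * var_li
    return total, math.sqrt(var_sum)


def log_likelihood(
    fit_result: FitResult,
    d: PKDataset | None = None,
    n_mc: int = 10_000,
    seed: int = 0,
    method: str = "importance",
    inflation: float = 1.5,
) -> LikelihoodResult:
    """Objective function value (-2 log L) with AIC and BIC.

    ``method='importance'`` uses Monte Carlo importance sampling (``n_mc``
    draws per subject) around the per-subject conditional modes and also
    reports the Monte Carlo standard error; ``method='laplace'`` is the
    deterministic Laplace approximation.  Updates ``fit_result`` in place
    (``ofv``, ``aic``, ``bic``, ``mc_se``) and returns the summary.
    """
    if method not in ("importance", "laplace"):
        raise ValueError(f"unknown likelihood method {method!r}")
    design = _design_for(fit_result, d)
    spec = fit_result.spec
    mu = np.log([fit_result.estimates[p] for p in spec.iiv])
    omega = np.array([fit_result.omega[p] for p in spec.iiv])
    ofv, mc_se = _m2ll(
        design, spec, mu, omega, fit_result.betas, fit_result.error, method, n_mc, seed, inflation
    )
    p_free = spec.n_free
    aic = ofv + 2.0 * p_free
    bic = ofv + p_free * math.log(design.n)
    fit_result.ofv, fit_result.aic, fit_result.bic, fit_result.mc_se = ofv, aic, bic, mc_se
    return LikelihoodResult(
        ofv=ofv, aic=aic, bic=bic, mc_se=mc_se,
        n_mc=(0 if method == "laplace" else n_mc), method=method, seed=seed,
    )


def _design_for(fit_result: FitResult, d: PKDataset | None) -> _Design:
    if d is not None:
        return _Design(d, fit_result.spec)
    design = getattr(fit_result, "_design", None)
    if design is None:
        raise ValueError("no dataset available: pass the dataset explicitly")
    return design


# ---------------------------------------------------------------------------
# Covariate search
# ---------------------------------------------------------------------------


@dataclass
class CovariateSearchResult:
    final_fit: FitResult
    selected: tuple[tuple[str, str], ...]
    trace: pd.DataFrame
    base_ofv: float
    final_ofv: float


def covariate_search(
    d: PKDataset,
    spec: ModelSpec | None = None,
    covariate_columns: Sequence[str] = ("WT", "BSA", "AGE", "CRCL", "ALB"),
    params: Sequence[str] | None = None,
    forward_dofv: float = 3.84,
    backward_dofv: float = 6.63,
    settings: SAEMSettings | None = None,
    seed: int = 0,
    ofv_method: str = "laplace",
    n_mc: int = 10_000,
    init: dict | None = None,
) -> CovariateSearchResult:
    """Stepwise forward inclusion / backward elimination of power-model
    covariate effects.

    Forward: the candidate (parameter, covariate) pair with the largest
    likelihood-ratio improvement is added while ``dOFV > forward_dofv``
    (chi-square 1 df at p < 0.05).  Backward: retained effects whose
    removal costs less than ``backward_dofv`` (p < 0.01) are pruned,
    weakest first.  The full decision trace is returned.
    """
    spec = spec or ModelSpec()
    settings = settings or SAEMSettings.fast()
    params = tuple(params) if params is not None else tuple(spec.iiv)
    cov_table = PKDataset(d.records).covariates()
    missing = []
    for c in covariate_columns:
        if c not in cov_table.columns:
            missing.append(f"column {c!r} absent")
            continue
        bad = cov_table.index[~np.isfinite(cov_table[c].to_numpy(float))].tolist()
        if bad:
            missing.append(f"covariate {c!r} missing for subjects: {bad}")
    if missing:
        raise ValueError("covariate data problems:\n  " + "\n  ".join(missing))

    cache: dict[tuple, tuple[FitResult, float]] = {}

    def fitted(s: ModelSpec) -> tuple[FitResult, float]:
        key = s.covariates
        if key not in cache:
            fr = fit(d, s, init=init, settings=settings, seed=seed)
            lik = log_likelihood(fr, d, n_mc=n_mc, seed=seed, method=ofv_method)
            cache[key] = (fr, lik.ofv)
        return cache[key]

    current_spec = spec
    current_fit, current_ofv = fitted(current_spec)
    base_ofv = current_ofv
    trace_rows = []
    step_no = 0

    while True:  # forward
        step_no += 1
        candidates = [
            (p, c)
            for p in params
            for c in covariate_columns
            if (p, c) not in current_spec.covariates
        ]
        if not candidates:
            break
        best = None
        for p, c in candidates:
            cand_fit, cand_ofv = fitted(current_spec.with_covariate(p, c))
            dofv = current_ofv - cand_ofv
            trace_rows.append(
                {"step": step_no, "phase": "forward", "param": p, "covariate": c,
                 "dofv": dofv, "accepted": False}
            )
            if best is None or dofv > best[0]:
                best = (dofv, p, c, cand_fit, cand_ofv)
        if best is not None and best[0] > forward_dofv:
            _, p, c, cand_fit, cand_ofv = best
            trace_rows[-len(candidates) + candidates.index((p, c))]["accepted"] = True
            current_spec = current_spec.with_covariate(p, c)
            current_fit, current_ofv = cand_fit, cand_ofv
        else:
            break

    while current_spec.covariates:  # backward elimination
        step_no += 1
        worst = None
        for p, c in current_spec.covariates:
            red_fit, red_ofv = fitted(current_spec.without_covariate(p, c))
            dofv = red_ofv - current_ofv  # cost of removal
            trace_rows.append(
                {"step": step_no, "phase": "backward", "param": p, "covariate": c,
                 "dofv": dofv, "accepted": False}
            )
            if worst is None or dofv < worst[0]:
                worst = (dofv, p, c, red_fit, red_ofv)
        if worst is not None and worst[0] < backward_dofv:
            _, p, c, red_fit, red_ofv = worst
            current_spec = current_spec.without_covariate(p, c)
            current_fit, current_ofv = red_fit, red_ofv
        else:
            break

    return CovariateSearchResult(
        final_fit=current_fit,
        selected=current_spec.covariates,
        trace=pd.DataFrame(trace_rows),
        base_ofv=base_ofv,
        final_ofv=current_ofv,
    )


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------


def _psi_pack(fit_result: FitResult):
    spec = fit_result.spec
    names, values = [], []
    for p in spec.iiv:
        names.append(f"theta_{p}")
        values.append(math.log(fit_result.estimates[p]))
    for key, v in fit_result.betas.items():
        names.append(f"beta_{key}")
        values.append(v)
    for p in spec.iiv:
        names.append(f"omega_{p}")
        values.append(math.log(fit_result.omega[p]))
    for n_, v in fit_result.error.items():
        names.append(f"error_{n_}")
        values.append(math.log(v))
    return names, np.array(values)


def _psi_unpack(fit_result: FitResult, names, psi):
    spec = fit_result.spec
    mu = np.empty(len(spec.iiv))
    omega = np.empty(len(spec.iiv))
    betas = dict(fit_result.betas)
    error = dict(fit_result.error)
    for name, v in zip(names, psi):
        kind, _, rest = name.partition("_")
        if kind == "theta":
            mu[spec.iiv.index(rest)] = v
        elif kind == "beta":
            betas[rest] = v
        elif kind == "omega":
            omega[spec.iiv.index(rest)] = math.exp(v)
        else:
            error[rest] = math.exp(v)
    return mu, omega, betas, error


def standard_errors(
    fit_result: FitResult,
    d: PKDataset | None = None,
    method: str = "fim",
    n_boot: int = 200,
    seed: int = 0,
    h: float = 1e-3,
) -> dict[str, float]:
    """Relative standard errors (%) of every estimated parameter.

    ``method='fim'`` differentiates the Laplace objective numerically to
    form the Fisher information matrix; because differentiation is done on
    the log scale, the resulting RSEs are invariant to unit rescaling of
    the parameters.  ``method='bootstrap'`` delegates to the nonparametric
    subject-resampling bootstrap.  Updates ``fit_result.rse`` (and, for the
    FIM route, the covariance/correlation matrices used by the condition-
    number diagnostic).
    """
    if method == "bootstrap":
        from .diagnostics import bootstrap as _bootstrap

        if d is None:
            raise ValueError("bootstrap standard errors require the dataset")
        br = _bootstrap(
            d, fit_result.spec, n_boot=n_boot, seed=seed,
            settings=SAEMSettings.fast(),
        )
        rse = {}
        reps = br.replicates
        for name in reps.columns:
            est = _estimate_by_name(fit_result, name)
            if est:
                rse[name] = 100.0 * float(reps[name].std(ddof=1)) / abs(est)
        fit_result.rse = rse
        return rse
    if method != "fim":
        raise ValueError(f"unknown standard-error method {method!r}")

    design = _design_for(fit_result, d)
    spec = fit_result.spec
    names, psi0 = _psi_pack(fit_result)
    mode_cache: dict = {}

    def objective(psi):
        mu, omega, betas, error = _psi_unpack(fit_result, names, psi)
        val, _ = _m2ll(design, spec, mu, omega, betas, error, "laplace", 0, seed,
                       mode_cache=mode_cache)
        return val

    H = _numeric_hessian(objective, psi0, h=h)
    H = 0.5 * (H + H.T)
    evals = np.linalg.eigvalsh(H)
    if np.min(evals) <= 0 or np.linalg.cond(H) > 1e12:
        raise RuntimeError(
            "singular or indefinite information matrix; "
            "use method='bootstrap' for standard errors"
        )
    cov = 2.0 * np.linalg.inv(H)  # covariance of psi (log-scale mostly)
    se = np.sqrt(np.diag(cov))
    rse = {}
    for name, s in zip(names, se):
        if name.startswith("beta_"):
            b = fit_result.betas[name[len("beta_"):]]
            rse[name] = 100.0 * s / abs(b) if b != 0 else float("inf")
        else:
            rse[name] = 100.0 * s  # SE of log(x) == relative SE of x
    denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
    fit_result.rse = rse
    fit_result.covariance = cov
    fit_result.correlation = cov / denom
    fit_result.psi_names = names
    return rse


def _estimate_by_name(fit_result: FitResult, name: str) -> float | None:
    kind, _, rest = name.partition("_")
    if kind == "theta":
        return fit_result.estimates.get(rest)
    if kind == "omega":
        return fit_result.omega.get(rest)
    if kind == "error":
        return fit_result.error.get(rest)
    if kind == "beta":
        return fit_result.betas.get(rest)
    return None
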