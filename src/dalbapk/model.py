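"""Closed-form one/two-compartment intravenous-infusion pharmacokinetics.

The disposition model is the standard mammillary two-compartment model with
zero-order (constant-rate) infusion input into the central compartment,
parameterized by clearance ``CL`` (L/h), central volume ``V1`` (L),
inter-compartmental clearance ``Q`` (L/h) and peripheral volume ``V2`` (L).
Micro rate constants are ``k10 = CL/V1``, ``k12 = Q/V1`` and ``k21 = Q/V2``;
the hybrid (macro) constants ``alpha > beta > 0`` are the roots of

    s**2 - (k10 + k12 + k21) * s + k10 * k21 = 0.

Because the system is linear, the concentration produced by an arbitrary
dosing history is the superposition of time-shifted single-infusion
responses, and both the concentration and its running integral (AUC) have
exact closed forms.  All public functions operate in hours and mg/L.

``Q = 0`` is accepted as the degenerate one-compartment limit (the
peripheral compartment decouples); in that case ``beta = 0`` and the
beta-mode coefficient vanishes identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PKParams",
    "DoseEvent",
    "Regimen",
    "MicroRates",
    "MacroConstants",
    "VAD_TYPICAL",
    "micro_rates",
    "macro_constants",
    "concentration",
    "auc",
    "terminal_half_life",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class PKParams:
    """Structural parameters of the two-compartment disposition model.

    Parameters
    ----------
    CL : float
        Total body clearance, L/h.
    V1 : float
        Central volume of distribution, L.
    Q : float
        Inter-compartmental clearance, L/h.  ``Q = 0`` collapses the model
        to a one-compartment model (degenerate limit).
    V2 : float
        Peripheral volume of distribution, L.
    """

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "V2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"invalid parameter: {name}={v!r} must be strictly positive")
        if not (np.isfinite(self.Q) and self.Q >= 0):
            raise ValueError(f"invalid parameter: Q={self.Q!r} must be nonnegative")

    @property
    def vss(self) -> float:
        """Total volume of distribution at steady state, ``V1 + V2`` (L)."""
        return self.V1 + self.V2

    def as_dict(self) -> dict[str, float]:
        return {"CL": self.CL, "V1": self.V1, "Q": self.Q, "V2": self.V2}


#: Typical-subject estimates of the final dalbavancin model from the
#: ventricular-assist-device cohort (CL in L/h, volumes in L).
VAD_TYPICAL = PKParams(CL=0.050, V1=6.5, Q=0.476, V2=15.4)


@dataclass(frozen=True)
class MicroRates:
    """First-order micro rate constants, 1/h."""

    k10: float
    k12: float
    k21: float


@dataclass(frozen=True)
class MacroConstants:
    """Hybrid rate constants and unit-bolus coefficients.

    ``alpha`` and ``beta`` (1/h) are the fast and slow disposition rate
    constants; ``coefA`` and ``coefB`` (1/L) are the central-concentration
    coefficients of the unit intravenous bolus response
    ``C(t) = coefA * exp(-alpha t) + coefB * exp(-beta t)``.
    """

    alpha: float
    beta: float
    coefA: float
    coefB: float


def micro_rates(p: PKParams) -> MicroRates:
    """Micro rate constants ``k10 = CL/V1``, ``k12 = Q/V1``, ``k21 = Q/V2``."""
    return MicroRates(k10=p.CL / p.V1, k12=p.Q / p.V1, k21=p.Q / p.V2)


def macro_constants(p: PKParams) -> MacroConstants:
    """Hybrid constants of the bi-exponential disposition function.

    ``beta`` is computed as ``k10*k21/alpha`` (Vieta) rather than from the
    quadratic formula directly, which is numerically stable when
    ``beta << alpha`` — the relevant regime for dalbavancin, whose terminal
    phase is two orders of magnitude slower than its distribution phase.
    """
    k = micro_rates(p)
    s = k.k10 + k.k12 + k.k21
    prod = k.k10 * k.k21
    disc = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    beta = prod / alpha if alpha > 0 else 0.0
    denom = p.V1 * (alpha - beta)
    if denom <= 0:
        raise ValueError("degenerate parameters: alpha == beta")
    coefA = (alpha - k.k21) / denom
    coefB = (k.k21 - beta) / denom
    return MacroConstants(alpha=alpha, beta=beta, coefA=coefA, coefB=coefB)


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order intravenous infusion.

    ``start_time`` in hours from the start of therapy, ``amount`` in mg,
    ``infusion_duration`` in hours (strictly positive; use a small duration
    such as 1e-6 h to approximate a bolus).
    """

    start_time: float
    amount: float
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start_time) and self.start_time >= 0):
            raise ValueError(f"dose start_time must be nonnegative, got {self.start_time!r}")
        if not (np.isfinite(self.amount) and self.amount > 0):
            raise ValueError(f"dose amount must be strictly positive, got {self.amount!r}")
        if not (np.isfinite(self.infusion_duration) and self.infusion_duration > 0):
            raise ValueError(
                f"infusion_duration must be strictly positive, got {self.infusion_duration!r}"
            )


@dataclass(frozen=True)
class Regimen:
    """An ordered dosing schedule, optionally repeated in cycles.

    ``events`` are the doses of one cycle, sorted by start time.  When
    ``cycle_length`` (h) is set, the whole event block is repeated
    ``n_cycles`` times, each repetition shifted by one cycle length.  The
    expanded event list must have strictly increasing start times, which
    requires every event to start within the first cycle.
    """

    events: tuple[DoseEvent, ...]
    cycle_length: float | None = None
    n_cycles: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        starts = [e.start_time for e in self.events]
        if starts != sorted(starts):
            raise ValueError("regimen events must be sorted by start_time")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.cycle_length is not None and self.cycle_length <= 0:
            raise ValueError(f"cycle_length must be positive, got {self.cycle_length}")
        exp = self.expand()[0]
        if len(exp) > 1 and not np.all(np.diff(exp) > 0):
            raise ValueError("expanded regimen must have strictly increasing start times")

    def expand(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Expanded dosing history as ``(starts, amounts, durations)`` arrays."""
        if not self.events:
            z = np.empty(0)
            return z, z.copy(), z.copy()
        s0 = np.array([e.start_time for e in self.events], dtype=float)
        a0 = np.array([e.amount for e in self.events], dtype=float)
        d0 = np.array([e.infusion_duration for e in self.events], dtype=float)
        if self.cycle_length is None or self.n_cycles == 1:
            reps = 1 if self.cycle_length is None else self.n_cycles
        else:
            reps = self.n_cycles
        if reps == 1:
            return s0, a0, d0
        offs = np.arange(reps) * float(self.cycle_length)
        starts = (s0[None, :] + offs[:, None]).ravel()
        return starts, np.tile(a0, reps), np.tile(d0, reps)

    @property
    def horizon(self) -> float:
        """End of the simulated course: last cycle start + cycle length."""
        if self.cycle_length is not None:
            return self.n_cycles * float(self.cycle_length)
        starts, _, durs = self.expand()
        return float(starts[-1] + durs[-1]) if len(starts) else 0.0

    def scaled(self, factor: float) -> "Regimen":
        """Return a copy with every dose amount multiplied by ``factor``."""
        ev = tuple(
            DoseEvent(e.start_time, e.amount * factor, e.infusion_duration) for e in self.events
        )
        return Regimen(ev, self.cycle_length, self.n_cycles, self.label)


# ---------------------------------------------------------------------------
# Vectorized kernels.  Parameter arrays broadcast against per-dose and
# per-time axes: internally everything is shaped (n, n_doses, n_times) and
# summed over the dose axis.  These kernels are the computational backbone of
# the Monte Carlo simulation and estimation modules.
# ---------------------------------------------------------------------------


def _hybrid_arrays(CL, V1, Q, V2):
    CL, V1, Q, V2 = (np.asarray(x, dtype=float) for x in (CL, V1, Q, V2))
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    prod = k10 * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    beta = np.where(alpha > 0, prod / np.where(alpha > 0, alpha, 1.0), 0.0)
    denom = V1 * (alpha - beta)
    coefA = (alpha - k21) / denom
    coefB = (k21 - beta) / denom
    return alpha, beta, coefA, coefB


def _mode_conc(lam, tau, dur):
    """Unit-rate infusion response of one exponential mode, zero for tau<=0."""
    lam = np.maximum(lam, 1e-300)
    rise = -np.expm1(-lam * np.minimum(tau, dur)) / lam
    out = rise * np.exp(-lam * np.maximum(tau - dur, 0.0))
    return np.where(tau > 0, out, 0.0)


def _mode_cum(lam, tau, dur):
    """Running time-integral of :func:`_mode_conc`."""
    lam = np.maximum(lam, 1e-300)
    tc = np.minimum(tau, dur)
    te = np.maximum(tau - dur, 0.0)
    head = (tc + np.expm1(-lam * tc) / lam) / lam
    tail = (-np.expm1(-lam * tc) / lam) * (-np.expm1(-lam * te) / lam)
    return np.where(tau > 0, head + tail, 0.0)


def _prep(CL, V1, Q, V2, starts, amounts, durations, times):
    CL, V1, Q, V2 = (np.atleast_1d(np.asarray(x, dtype=float)) for x in (CL, V1, Q, V2))
    n = max(x.shape[0] for x in (CL, V1, Q, V2))
    starts = np.asarray(starts, dtype=float)
    amounts = np.asarray(amounts, dtype=float)
    durations = np.asarray(durations, dtype=float)
    times = np.asarray(times, dtype=float)
    if starts.ndim == 1:
        starts, amounts, durations = (x[None, :, None] for x in (starts, amounts, durations))
    else:
        starts, amounts, durations = (x[:, :, None] for x in (starts, amounts, durations))
    if times.ndim == 1:
        times = times[None, None, :]
    else:
        times = times[:, None, :]
    par = tuple(x[:, None, None] for x in (CL, V1, Q, V2))
    return n, par, starts, amounts, durations, times


def conc_many(CL, V1, Q, V2, starts, amounts, durations, times) -> np.ndarray:
    """Central concentration (mg/L) for broadcast parameter/dose/time arrays.

    ``CL, V1, Q, V2`` are scalars or shape-(n,) arrays; ``starts/amounts/
    durations`` are shape (d,) or (n, d); ``times`` is shape (m,) or (n, m).
    Returns an (n, m) array.  Doses with ``amount == 0`` contribute nothing,
    so designs may be zero-padded to a common width.
    """
    n, (CL, V1, Q, V2), starts, amounts, durations, times = _prep(
        CL, V1, Q, V2, starts, amounts, durations, times
    )
    if starts.shape[1] == 0:
        return np.zeros((n, times.shape[-1]))
    alpha, beta, cA, cB = _hybrid_arrays(CL, V1, Q, V2)
    tau = times - starts
    rate = amounts / durations
    term = cA * _mode_conc(alpha, tau, durations)
    term = term + np.where(cB != 0, cB * _mode_conc(beta, tau, durations), 0.0)
    return np.sum(rate * term, axis=1)


def auc_many(CL, V1, Q, V2, starts, amounts, durations, t0, t1) -> np.ndarray:
    """Exact AUC (mg·h/L) over ``[t0, t1]`` for broadcast inputs; shape (n,)."""
    t0a = np.atleast_1d(np.asarray(t0, dtype=float))
    t1a = np.atleast_1d(np.asarray(t1, dtype=float))
    times = np.stack(np.broadcast_arrays(t0a, t1a), axis=-1)  # (k, 2)
    n, (CL, V1, Q, V2), starts, amounts, durations, tgrid = _prep(
        CL, V1, Q, V2, starts, amounts, durations, times.ravel()
    )
    if starts.shape[1] == 0:
        return np.zeros((n, t0a.shape[0])) if t0a.shape[0] > 1 else np.zeros(n)
    alpha, beta, cA, cB = _hybrid_arrays(CL, V1, Q, V2)
    tau = tgrid - starts
    rate = amounts / durations
    term = cA * _mode_cum(alpha, tau, durations)
    term = term + np.where(cB != 0, cB * _mode_cum(beta, tau, durations), 0.0)
    cum = np.sum(rate * term, axis=1).reshape(n, -1, 2)
    out = cum[..., 1] - cum[..., 0]
    return out[:, 0] if out.shape[1] == 1 else out


def concentration(p: PKParams, r: Regimen, times: Sequence[float] | np.ndarray) -> np.ndarray:
    """Total central concentration (mg/L) at the requested times.

    The result is the exact superposition of the per-dose infusion
    responses of the expanded regimen; it is zero before the first dose,
    continuous everywhere, and nonnegative.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("time grid must not be empty")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    starts, amounts, durations = r.expand()
    out = conc_many(p.CL, p.V1, p.Q, p.V2, starts, amounts, durations, t.ravel())[0]
    return out.reshape(t.shape)


def auc(p: PKParams, r: Regimen, window: tuple[float, float]) -> float:
    """Exact AUC (mg·h/L) of the regimen's concentration over ``window``.

    Analytic, hence additive over adjacent windows to rounding error.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not (0 <= t0 < t1):
        raise ValueError(f"require 0 <= t0 < t1, got window=({t0}, {t1})")
    starts, amounts, durations = r.expand()
    return float(auc_many(p.CL, p.V1, p.Q, p.V2, starts, amounts, durations, t0, t1)[0])


def terminal_half_life(p: PKParams) -> float:
    """Terminal half-life ``ln 2 / beta`` in hours.

    In the degenerate one-compartment limit (``Q = 0``) the beta mode
    carries no mass and the terminal phase is governed by ``k10``, so
    ``ln 2 / k10`` is returned instead.
    """
    mc = macro_constants(p)
    if mc.beta <= 0 or mc.coefB == 0:
        return _LN2 / mc.alpha
    return _LN2 / mc.beta
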