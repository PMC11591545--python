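"""Free-drug exposure, probability of target attainment (PTA) and
cumulative fraction of response (CFR).

The pharmacodynamic index is ``fAUC24/MIC``: the unbound (free) area under
the concentration-time curve over the *last 24 hours before redosing*,
divided by the pathogen MIC.  Using the pre-redosing window is the
conservative choice for suppressive therapy — it measures exposure in the
interval where concentrations are lowest.  Free concentrations are obtained
from total concentrations by the scalar factor ``1 - PB/100`` for a given
protein-binding scenario ``PB`` (percent bound).

Stasis, 1-log kill and 2-log kill correspond to ``fAUC24/MIC`` thresholds
of 27.1, 53.3 and 111.1 for S. aureus; attainment uses the strict
inequality ``fAUC24/MIC > threshold``.  PTA and CFR are "desirable" at
or above 90%.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PKParams, Regimen, auc_many
from .population import VirtualPopulation

__all__ = [
    "PKPDTargets",
    "TARGETS",
    "resolve_target",
    "BindingScenario",
    "MICDistribution",
    "default_mic_distribution",
    "EUCAST_MIC_GRID",
    "PTAResult",
    "CFRResult",
    "evaluation_windows",
    "fauc_tail",
    "pta",
    "pta_curve",
    "cfr",
    "desirability",
]

#: EUCAST doubling-dilution MIC grid for S. aureus / dalbavancin (mg/L).
EUCAST_MIC_GRID: tuple[float, ...] = (0.016, 0.03, 0.06, 0.125, 0.25, 0.5, 1.0, 2.0)

DESIRABILITY_BOUND = 90.0


@dataclass(frozen=True)
class PKPDTargets:
    """``fAUC24/MIC`` thresholds for S. aureus (unitless, strictly increasing)."""

    stasis: float = 27.1
    log1kill: float = 53.3
    log2kill: float = 111.1

    def __post_init__(self) -> None:
        if not (0 < self.stasis < self.log1kill < self.log2kill):
            raise ValueError("targets must be positive and strictly increasing")


TARGETS = PKPDTargets()


def resolve_target(target: str | float) -> float:
    """Map a target name ('stasis', 'log1kill', 'log2kill') or number to a threshold."""
    if isinstance(target, str):
        try:
            return float(getattr(TARGETS, target))
        except AttributeError:
            raise ValueError(
                f"unknown target {target!r}; expected one of stasis/log1kill/log2kill"
            ) from None
    return float(target)


@dataclass(frozen=True)
class BindingScenario:
    """A deterministic protein-binding scenario, percent bound in [0, 100].

    ``pb = 100`` is allowed and yields zero free exposure.
    """

    pb: float

    def __post_init__(self) -> None:
        if not (0 <= self.pb <= 100):
            raise ValueError(f"protein binding must be within [0, 100] %, got {self.pb}")

    @property
    def free_fraction(self) -> float:
        return 1.0 - self.pb / 100.0


@dataclass(frozen=True)
class MICDistribution:
    """Ordered (MIC, frequency) pairs on the EUCAST range [0.016, 2] mg/L."""

    mics: tuple[float, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.mics, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if m.shape != f.shape or m.size == 0:
            raise ValueError("mics and frequencies must be equal-length and nonempty")
        if not np.all(np.diff(m) > 0):
            raise ValueError("MICs must be strictly increasing")
        if m[0] < 0.016 - 1e-12 or m[-1] > 2 + 1e-12:
            raise ValueError("MICs must lie within [0.016, 2] mg/L")
        if np.any(f < 0):
            raise ValueError("frequencies must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1 (got {f.sum():.12f})")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MICDistribution":
        df = pd.read_csv(path, comment="#")
        required = {"mic_mg_per_L", "frequency"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"MIC distribution CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        return cls(tuple(df["mic_mg_per_L"].astype(float)), tuple(df["frequency"].astype(float)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mic_mg_per_L": self.mics, "frequency": self.frequencies})


def default_mic_distribution() -> MICDistribution:
    """The packaged synthetic EUCAST-style S. aureus snapshot (see data file)."""
    with resources.files("dalbapk.data").joinpath("mic_saureus_synthetic.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return MICDistribution(tuple(df["mic_mg_per_L"]), tuple(df["frequency"]))


@dataclass
class PTAResult:
    """PTA (%) over a MIC grid for one regimen x binding x threshold."""

    regimen_label: str
    pb: float
    threshold: float
    mics: np.ndarray
    pta: np.ndarray
    n_subjects: int
    seed: int | None = None

    def value_at(self, mic: float) -> float:
        idx = np.flatnonzero(np.isclose(self.mics, mic, rtol=1e-9, atol=0.0))
        if idx.size == 0:
            raise ValueError(f"MIC {mic} not on the PTA grid {list(self.mics)}")
        return float(self.pta[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regimen": self.regimen_label,
                "pb_percent": self.pb,
                "threshold": self.threshold,
                "mic_mg_per_L": self.mics,
                "pta_percent": self.pta,
                "n_subjects": self.n_subjects,
            }
        )


@dataclass
class CFRResult:
    """Cumulative fraction of response (%) for one regimen x binding x threshold."""

    regimen_label: str
    pb: float
    threshold: float
    cfr: float
    n_subjects: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# Exposure windows
# ---------------------------------------------------------------------------


def evaluation_windows(r: Regimen) -> list[tuple[float, float]]:
    """The 24-h pre-redosing windows of the final simulated cycle.

    A window ``[t - 24, t]`` is evaluated before every scheduled redosing
    ``t`` in the last cycle, including the start of the (hypothetical) next
    cycle.  For regimens with several doses per cycle this yields several
    windows; the regimen-level exposure is the worst (minimum) across them,
    which for the regimens studied here is the cycle-end window.
    """
    if r.cycle_length is None:
        raise ValueError(
            "regimen has no cycle_length, so the pre-redosing evaluation "
            "interval is undefined"
        )
    if not r.events:
        raise ValueError("regimen has no dose events")
    L = float(r.cycle_length)
    offset = (r.n_cycles - 1) * L
    redose = [e.start_time + offset for e in r.events[1:]] + [r.n_cycles * L]
    starts, _, _ = r.expand()
    windows = []
    for t in redose:
        prev = starts[starts < t - 1e-9]
        gap = t - (prev[-1] if prev.size else 0.0)
        if gap < 24.0:
            raise ValueError(
                f"dosing interval ending at t={t} h is shorter than 24 h ({gap:.1f} h); "
                "the 24-h pre-redosing AUC window is undefined"
            )
        windows.append((t - 24.0, t))
    return windows


def _free_exposures(params: dict[str, np.ndarray], r: Regimen, pb: float) -> np.ndarray:
    """Worst-window free AUC24 (mg·h/L) per individual; vectorized."""
    scen = BindingScenario(pb)
    windows = evaluation_windows(r)
    starts, amounts, durations = r.expand()
    t0 = np.array([w[0] for w in windows])
    t1 = np.array([w[1] for w in windows])
    total = auc_many(
        params["CL"], params["V1"], params["Q"], params["V2"],
        starts, amounts, durations, t0, t1,
    )
    worst = total if total.ndim == 1 else np.min(total, axis=1)
    return scen.free_fraction * worst


def fauc_tail(p: PKParams, r: Regimen, pb: float) -> float:
    """Free AUC over the last 24 h before redosing (mg·h/L) for one subject.

    With several redosing boundaries per cycle, the minimum across the
    final-cycle windows is returned.
    """
    params = {k: np.array([v]) for k, v in p.as_dict().items()}
    return float(_free_exposures(params, r, pb)[0])


def pta(
    pop: VirtualPopulation,
    r: Regimen,
    mic: float,
    pb: float,
    threshold: float | str = "stasis",
) -> float:
    """Probability of target attainment, percent.

    Fraction of individuals with ``fAUC24 / MIC > threshold`` (strict),
    times 100.  Exposures are error-free model predictions.
    """
    if mic <= 0:
        raise ValueError(f"MIC must be positive, got {mic}")
    if pop.n < 1:
        raise ValueError("population is empty")
    thr = resolve_target(threshold)
    expo = _free_exposures(pop.params, r, pb)
    return float(100.0 * np.mean(expo / mic > thr))


def pta_curve(
    pop: VirtualPopulation,
    r: Regimen,
    mic_grid=EUCAST_MIC_GRID,
    pb: float = 93.0,
    threshold: float | str = "stasis",
) -> PTAResult:
    """PTA over a MIC grid; exposures are computed once and thresholds vectorized."""
    mics = np.asarray(mic_grid, dtype=float)
    if mics.size == 0:
        raise ValueError("MIC grid must not be empty")
    if not np.all(np.diff(mics) > 0):
        raise ValueError("MIC grid must be strictly increasing")
    thr = resolve_target(threshold)
    expo = _free_exposures(pop.params, r, pb)
    vals = 100.0 * np.mean(expo[:, None] > thr * mics[None, :], axis=0)
    return PTAResult(
        regimen_label=r.label,
        pb=pb,
        threshold=thr,
        mics=mics,
        pta=vals,
        n_subjects=pop.n,
        seed=pop.seed,
    )


def cfr(pta_result: PTAResult, dist: MICDistribution) -> CFRResult:
    """CFR = sum over the MIC distribution of ``PTA(MIC) * frequency``.

    Every MIC of the distribution must be present on the PTA grid —
    no interpolation is performed.
    """
    missing = [
        m for m in dist.mics
        if not np.any(np.isclose(pta_result.mics, m, rtol=1e-9, atol=0.0))
    ]
    if missing:
        raise ValueError(
            "MIC distribution values missing from the PTA grid: "
            + ", ".join(f"{m:g}" for m in missing)
        )
    value = sum(
        pta_result.value_at(m) * f for m, f in zip(dist.mics, dist.frequencies)
    )
    return CFRResult(
        regimen_label=pta_result.regimen_label,
        pb=pta_result.pb,
        threshold=pta_result.threshold,
        cfr=float(value),
        n_subjects=pta_result.n_subjects,
        seed=pta_result.seed,
    )


def desirability(x: PTAResult | CFRResult | float, mic: float | None = None) -> bool:
    """True iff the attainment value is at or above the 90% desirability bound."""
    if isinstance(x, PTAResult):
        if mic is None:
            raise ValueError("a MIC must be given to query a PTA curve")
        value = x.value_at(mic)
    elif isinstance(x, CFRResult):
        value = x.cfr
    else:
        value = float(x)
    return value >= DESIRABILITY_BOUND
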