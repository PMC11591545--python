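"""Regimen presets and YAML (de)serialization.

Regimens are described in clinical terms — calendar day of each dose, dose
amount in mg, infusion duration in hours, and a cycle length in weeks —
and converted to the hour-based :class:`~dalbapk.model.Regimen` used by the
PK engine.  Day ``n`` maps to start time ``(n - 1) * 24`` h, so day 1 is
t = 0 and day 8 is t = 168 h.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .model import DoseEvent, Regimen

__all__ = ["PRESET_LABELS", "build_regimen", "load_regimen", "load_presets", "regimen_to_dict"]

_HOURS_PER_DAY = 24.0
_HOURS_PER_WEEK = 168.0


def build_regimen(
    doses: list[dict],
    cycle_weeks: float | None = None,
    n_cycles: int = 6,
    label: str = "",
) -> Regimen:
    """Build a :class:`Regimen` from clinical dose descriptions.

    Each dose is ``{"day": int, "amount_mg": float, "duration_h": float}``
    (``duration_h`` optional, default 0.5 h).
    """
    events = tuple(
        DoseEvent(
            start_time=(float(d["day"]) - 1.0) * _HOURS_PER_DAY,
            amount=float(d["amount_mg"]),
            infusion_duration=float(d.get("duration_h", 0.5)),
        )
        for d in doses
    )
    cycle_h = None if cycle_weeks is None else float(cycle_weeks) * _HOURS_PER_WEEK
    return Regimen(events=events, cycle_length=cycle_h, n_cycles=n_cycles, label=label)


def _preset_specs() -> dict:
    with resources.files("dalbapk.data").joinpath("regimens.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_presets(n_cycles: int | None = None) -> dict[str, Regimen]:
    """All shipped regimen presets, keyed by label."""
    out = {}
    for label, spec in _preset_specs().items():
        out[label] = build_regimen(
            spec["doses"],
            cycle_weeks=spec.get("cycle_weeks"),
            n_cycles=n_cycles if n_cycles is not None else spec.get("n_cycles", 6),
            label=label,
        )
    return out


PRESET_LABELS: tuple[str, ...] = tuple(_preset_specs().keys())


def load_regimen(name_or_path: str, n_cycles: int | None = None) -> Regimen:
    """Load a regimen by preset label or from a YAML file of the same shape."""
    presets = _preset_specs()
    if name_or_path in presets:
        spec = presets[name_or_path]
        label = name_or_path
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ValueError(
                f"unknown regimen {name_or_path!r}; available presets: "
                + ", ".join(sorted(presets))
            )
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        label = spec.get("label", path.stem)
    return build_regimen(
        spec["doses"],
        cycle_weeks=spec.get("cycle_weeks"),
        n_cycles=n_cycles if n_cycles is not None else spec.get("n_cycles", 6),
        label=label,
    )


def regimen_to_dict(r: Regimen) -> dict:
    """Clinical-terms dictionary representation (inverse of build_regimen)."""
    return {
        "label": r.label,
        "doses": [
            {
                "day": e.start_time / _HOURS_PER_DAY + 1.0,
                "amount_mg": e.amount,
                "duration_h": e.infusion_duration,
            }
            for e in r.events
        ],
        "cycle_weeks": None if r.cycle_length is None else r.cycle_length / _HOURS_PER_WEEK,
        "n_cycles": r.n_cycles,
    }
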