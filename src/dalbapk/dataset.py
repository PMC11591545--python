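"""Sparse longitudinal PK datasets in a NONMEM-flavoured CSV layout.

Columns: ``ID,TIME,EVID,AMT,DUR,DV,BQL,ANALYTE,WT,BSA,AGE,CRCL,ALB,PB``.
``EVID`` is 1 for dose rows (``AMT`` mg over ``DUR`` h, ``DV`` empty) and
0 for observation rows (``DV`` mg/L, ``BQL`` 0/1 flag, ``ANALYTE`` either
``total`` or ``unbound``).  Covariates are carried on every row of a
subject: weight (kg), body surface area (m²), age (y), creatinine
clearance (mL/min), albumin (mg/dL) and measured protein binding (%).

Below-quantification-limit (BQL) observations are handled by the simple
QL/2 replacement rule: any observation with ``DV`` strictly below its
analyte's quantification limit (or explicitly flagged) is replaced by half
the limit.  Values exactly at the limit are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "COVARIATE_COLUMNS", "PKDataset", "impute_bql", "QL_TOTAL", "QL_UNBOUND"]

COVARIATE_COLUMNS = ("WT", "BSA", "AGE", "CRCL", "ALB", "PB")
COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "BQL", "ANALYTE") + COVARIATE_COLUMNS

#: Assay quantification limits, mg/L.
QL_TOTAL = 12.5
QL_UNBOUND = 1.0


@dataclass
class PKDataset:
    """A validated table of dosing and observation records."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        errors = validate_records(self.records)
        if errors:
            raise ValueError("invalid PK dataset:\n  " + "\n  ".join(errors))
        self.records = self.records.reset_index(drop=True)

    # -- accessors ----------------------------------------------------------

    @property
    def subjects(self) -> list:
        return sorted(self.records["ID"].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def doses(self, subject=None) -> pd.DataFrame:
        df = self.records[self.records["EVID"] == 1]
        return df if subject is None else df[df["ID"] == subject]

    def observations(self, analyte: str | None = None, subject=None) -> pd.DataFrame:
        df = self.records[self.records["EVID"] == 0]
        if analyte is not None:
            df = df[df["ANALYTE"] == analyte]
        if subject is not None:
            df = df[df["ID"] == subject]
        return df

    def covariates(self) -> pd.DataFrame:
        """One row per subject, indexed by ID."""
        first = self.records.groupby("ID", sort=True).first()
        return first[list(COVARIATE_COLUMNS)]

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "PKDataset":
        path = Path(path)
        try:
            df = pd.read_csv(path, comment="#")
        except Exception as exc:  # malformed CSV
            raise ValueError(f"{path}: cannot parse CSV: {exc}") from exc
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
        errors = validate_records(df)
        if errors:
            raise ValueError(f"{path}: invalid dataset:\n  " + "\n  ".join(errors))
        return cls(df[list(COLUMNS)].copy())

    def to_csv(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for k, v in (meta or {}).items():
                fh.write(f"# {k}={v}\n")
            self.records[list(COLUMNS)].to_csv(fh, index=False)


def validate_records(df: pd.DataFrame) -> list[str]:
    """Exhaustive validation; returns every violation with its CSV line.

    Line numbers assume a single header line (data starts at line 2).
    """
    errors: list[str] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        return [f"missing required columns: {', '.join(missing)}"]

    def line(i) -> int:
        return int(i) + 2

    for i, row in df.iterrows():
        evid = row["EVID"]
        if evid not in (0, 1):
            errors.append(f"line {line(i)}: EVID must be 0 or 1, got {evid!r}")
            continue
        t = row["TIME"]
        if not np.isfinite(t) or t < 0:
            errors.append(f"line {line(i)}: TIME must be nonnegative, got {t!r}")
        if evid == 1:
            if not (np.isfinite(row["AMT"]) and row["AMT"] > 0):
                errors.append(f"line {line(i)}: dose row needs AMT > 0, got {row['AMT']!r}")
            if not (np.isfinite(row["DUR"]) and row["DUR"] > 0):
                errors.append(f"line {line(i)}: dose row needs DUR > 0, got {row['DUR']!r}")
            if pd.notna(row["DV"]):
                errors.append(f"line {line(i)}: DV must be empty on dose rows")
        else:
            if pd.isna(row["DV"]):
                errors.append(f"line {line(i)}: observation row needs a DV value")
            if row["ANALYTE"] not in ("total", "unbound"):
                errors.append(
                    f"line {line(i)}: ANALYTE must be 'total' or 'unbound', "
                    f"got {row['ANALYTE']!r}"
                )
            if row["BQL"] not in (0, 1):
                errors.append(f"line {line(i)}: BQL must be 0 or 1, got {row['BQL']!r}")
    for sid, grp in df.groupby("ID"):
        if not (grp["EVID"] == 1).any():
            errors.append(f"subject {sid}: has no dose record")
        if not (grp["EVID"] == 0).any():
            errors.append(f"subject {sid}: has no observation record")
        if not grp["TIME"].is_monotonic_increasing:
            errors.append(f"subject {sid}: records are not sorted by TIME")
    return errors


def impute_bql(
    d: PKDataset,
    ql_total: float = QL_TOTAL,
    ql_unbound: float = QL_UNBOUND,
) -> tuple[PKDataset, dict]:
    """Replace below-QL observations by QL/2 (simple imputation).

    An observation is imputed when its DV is strictly below the analyte's
    quantification limit or its BQL flag is set; values exactly at the
    limit are kept.  Dose rows and record counts are untouched.  Returns
    the imputed dataset and a report dict with per-analyte counts and
    fractions replaced.
    """
    if ql_total <= 0 or ql_unbound <= 0:
        raise ValueError("quantification limits must be positive")
    df = d.records.copy()
    report: dict = {"ql_total": ql_total, "ql_unbound": ql_unbound}
    for analyte, ql in (("total", ql_total), ("unbound", ql_unbound)):
        obs = (df["EVID"] == 0) & (df["ANALYTE"] == analyte)
        below = obs & ((df["DV"] < ql) | (df["BQL"] == 1))
        df.loc[below, "DV"] = ql / 2.0
        df.loc[below, "BQL"] = 1
        n_obs = int(obs.sum())
        n_bql = int(below.sum())
        report[f"n_{analyte}"] = n_obs
        report[f"n_bql_{analyte}"] = n_bql
        report[f"frac_bql_{analyte}"] = (n_bql / n_obs) if n_obs else 0.0
    return PKDataset(df), report
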