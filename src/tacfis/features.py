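"""Concentration-to-dose ratio (CDR) phenotypes.

The CDR is the tacrolimus trough blood concentration (ng/mL) divided by the
weight-adjusted daily dose (mg/kg); a high CDR means slow elimination.
Because inter-center assay differences skew the raw scale, CDRs are
normalised by natural-log transformation before any pooling.  The weekly
phenotype is the per-patient median of daily log-CDR values within each
post-operative week (days 1-7, 8-14, 15-21, 22-28); the classification
anchors are the per-center first and third quartiles of all month-1 log-CDR
observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError

WEEKS = (1, 2, 3, 4)


def week_of_day(day: int) -> int:
    """Post-operative week of a day in 1..28 (week w = days 7(w-1)+1 .. 7w)."""
    return (day - 1) // 7 + 1


def compute_cdr(trough: float | None, daily_dose: float | None, weight: float) -> float:
    """CDR = trough / (daily_dose / weight), in (ng/mL)/(mg/kg).

    Returns NaN when the trough is missing or the dose is zero/missing
    (the ratio is undefined on drug-free days).  A non-positive weight is a
    validation error, not a missing value.
    """
    if weight is None or not np.isfinite(weight) or weight <= 0:
        raise ValidationError(f"weight must be > 0, got {weight}")
    if trough is None or daily_dose is None:
        return float("nan")
    if not np.isfinite(trough) or not np.isfinite(daily_dose) or daily_dose == 0:
        return float("nan")
    return trough / (daily_dose / weight)


def log_transform(cdr: float) -> float:
    """Natural log of a CDR; non-positive or missing values give NaN."""
    if cdr is None or not np.isfinite(cdr):
        return float("nan")
    if cdr <= 0:
        warnings.warn(f"non-positive CDR {cdr} has no log; treated as missing", stacklevel=2)
        return float("nan")
    return float(np.log(cdr))


def add_cdr(pk: pd.DataFrame) -> pd.DataFrame:
    """Append ``cdr`` and ``log_cdr`` columns to a patient-day frame.

    Vectorised version of :func:`compute_cdr`/:func:`log_transform`; rows
    with missing trough or zero/missing dose get NaN in both columns.
    """
    if (pk["weight"] <= 0).any():
        raise ValidationError("weight must be > 0 for all rows")
    out = pk.copy()
    dose_per_kg = out["daily_dose"] / out["weight"]
    cdr = out["trough"] / dose_per_kg
    cdr = cdr.where(dose_per_kg > 0)
    out["cdr"] = cdr
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_cdr"] = np.where(cdr > 0, np.log(cdr), np.nan)
    return out


@dataclass
class WeeklyCDRProfile:
    """Per-patient weekly medians of log CDR over the first month."""

    patient_id: str
    weekly_median_logcdr: tuple[float, float, float, float]
    n_days_observed: tuple[int, int, int, int]

    def n_weeks_observed(self) -> int:
        return int(sum(np.isfinite(v) for v in self.weekly_median_logcdr))


def weekly_medians(cdr_records: pd.DataFrame) -> WeeklyCDRProfile:
    """Weekly medians of ``log_cdr`` for a single patient's day frame.

    A week without any finite observation is reported as NaN with zero
    observed days; missing days simply shrink the median's support.
    """
    if (~cdr_records["day"].between(1, 28)).any():
        raise ValidationError("days outside [1, 28]")
    pid = str(cdr_records["patient_id"].iloc[0]) if len(cdr_records) else ""
    medians, counts = [], []
    weeks = (cdr_records["day"] - 1) // 7 + 1
    for w in WEEKS:
        vals = cdr_records.loc[weeks == w, "log_cdr"].dropna()
        counts.append(int(len(vals)))
        medians.append(float(vals.median()) if len(vals) else float("nan"))
    return WeeklyCDRProfile(pid, tuple(medians), tuple(counts))


def weekly_median_frame(cdr: pd.DataFrame) -> pd.DataFrame:
    """All patients' weekly log-CDR medians, one row per patient.

    Columns ``week1`` .. ``week4`` hold the medians, ``center_id`` the
    patient's center (assumed constant within patient).
    """
    df = cdr.copy()
    df["week"] = (df["day"] - 1) // 7 + 1
    med = (
        df.pivot_table(index="patient_id", columns="week", values="log_cdr", aggfunc="median")
        .reindex(columns=list(WEEKS))
    )
    med.columns = [f"week{w}" for w in WEEKS]
    centers = df.groupby("patient_id")["center_id"].first()
    out = med.join(centers).reset_index()
    return out


@dataclass(frozen=True)
class CenterQuartiles:
    """Month-1 log-CDR quartile anchors of one center."""

    center_id: str
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValidationError(f"center {self.center_id}: Q1 > Q3")


def center_quartiles(
    values, center_id: str = "", method: str = "linear"
) -> CenterQuartiles:
    """First and third quartiles of a center's pooled month-1 log-CDR values.

    ``method`` is any numpy quantile convention; the default linear
    interpolation between order statistics matches R's type 7.  Fewer than
    four observations cannot anchor quartiles and are fatal for the center.
    """
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(vals) < 4:
        raise ValidationError(
            f"center {center_id!r}: {len(vals)} observations, need >= 4 for quartiles"
        )
    q1, q3 = np.quantile(vals, [0.25, 0.75], method=method)
    return CenterQuartiles(center_id=center_id, q1=float(q1), q3=float(q3))


def quartiles_by_center(cdr: pd.DataFrame, method: str = "linear") -> dict[str, CenterQuartiles]:
    """Month-1 quartile anchors per center from pooled patient-day log CDRs."""
    return {
        str(cid): center_quartiles(grp["log_cdr"], str(cid), method=method)
        for cid, grp in cdr.groupby("center_id")
    }
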