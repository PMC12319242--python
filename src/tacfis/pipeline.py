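"""End-to-end conveniences chaining the pipeline stages.

These helpers wire pk -> CDR features -> classification -> concordance the
way the CLI and the reproduction script do, so library users can run the
whole chain in a few calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as _classify
from .features import add_cdr, quartiles_by_center, weekly_median_frame
from .io import pk_frame
from .types import GenotypePair, PKDayRecord


def features_from_pk(pk: list[PKDayRecord] | pd.DataFrame, quartile_method: str = "linear"):
    """PK records -> (cdr frame, weekly medians frame, per-center quartiles)."""
    frame = pk if isinstance(pk, pd.DataFrame) else pk_frame(pk)
    cdr = add_cdr(frame)
    weekly = weekly_median_frame(cdr)
    quartiles = quartiles_by_center(cdr, method=quartile_method)
    return cdr, weekly, quartiles


def labels_by_scheme(labels: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Long label frame -> {scheme: {patient_id: label}}."""
    return {
        scheme: dict(zip(grp["patient_id"], grp["label"]))
        for scheme, grp in labels.groupby("scheme")
    }


def classify_all(
    pk: list[PKDayRecord] | pd.DataFrame,
    pairs: list[GenotypePair],
    majority: int = 3,
    quartile_method: str = "linear",
    direction: dict | None = None,
) -> pd.DataFrame:
    """Run features and all four classification schemes on a cohort."""
    _, weekly, quartiles = features_from_pk(pk, quartile_method)
    return _classify.classify_cohort(
        weekly, quartiles, pairs, direction=direction, majority=majority
    )


def stable_dose_by_group(
    pk: list[PKDayRecord] | pd.DataFrame,
    labels: dict[str, str],
    weeks: tuple[int, ...] = (3, 4),
) -> pd.DataFrame:
    """Mean stable-phase weight-adjusted daily dose (mg/kg) per label group.

    The stable phase defaults to weeks 3-4, after the feedback-dosing ramp;
    the per-patient dose is the mean daily dose/weight over those days, and
    groups are summarised by mean and SD across patients.
    """
    frame = pk if isinstance(pk, pd.DataFrame) else pk_frame(pk)
    df = frame.copy()
    df["week"] = (df["day"] - 1) // 7 + 1
    df = df[df["week"].isin(weeks)]
    df["dose_per_kg"] = df["daily_dose"] / df["weight"]
    per_patient = df.groupby("patient_id")["dose_per_kg"].mean()
    rows = []
    for group in sorted(set(labels.values())):
        vals = np.array([per_patient[pid] for pid, lab in labels.items() if lab == group and pid in per_patient.index])
        if len(vals) == 0:
            continue
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "mean_dose_per_kg": float(vals.mean()),
                "sd_dose_per_kg": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
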