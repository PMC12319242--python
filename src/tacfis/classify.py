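"""The four tacrolimus-clearance classification systems.

* **clinical-FIS** — retrospective, from the observed CDR trajectory: a
  patient whose weekly median log CDR exceeds the center's month-1 third
  quartile in more than half of the four weeks is a slow eliminator (SE);
  more than half below the first quartile is fast (FE); everyone else is
  intermediate (IE).
* **CPIC-EIP** — from a single CYP3A5 rs776746 genotype (recipient or
  donor): AA -> EM, AG -> IM, GG -> PM.  The pooled grouping used in the
  association analyses (AA/AG expressers vs GG non-expressers) is exposed
  separately.
* **paired-EIP** — from donor and recipient rs776746 jointly: both
  expressers (AA/AG) -> EM, exactly one GG -> IM, both GG -> PM.
* **genetic-EIP** — paired-EIP refined by two minor-effect loci: paired-EM
  patients whose recipient SULT1E1 rs3775770 genotype falls on the slow
  side move to IM, and paired-PM patients whose donor SLC7A8 rs7141505
  genotype falls on the fast side move to IM.  The slow/fast sides are
  data-driven (:func:`infer_minor_direction`) with a config override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import CenterQuartiles, WeeklyCDRProfile
from .types import GenotypePair, ValidationError

CYP3A5 = "rs776746"
MINOR_EM_LOCUS = ("recipient", "rs3775770")  # SULT1E1, refines paired-EM
MINOR_PM_LOCUS = ("donor", "rs7141505")  # SLC7A8, refines paired-PM

#: the two genotype groups each minor locus is split into
MINOR_GROUPS = {
    "rs3775770": (("AA", "AG"), ("GG",)),
    "rs7141505": (("GG", "GT"), ("TT",)),
}


class Unclassifiable(Exception):
    """The input does not admit a label (e.g. all weeks missing)."""


def classify_fis(
    profile: WeeklyCDRProfile, quartiles: CenterQuartiles, majority: int = 3
) -> str:
    """Clinical FE/IE/SE label from a weekly log-CDR profile.

    Strict inequalities against the center anchors; missing weeks count
    toward neither tally.  The SE rule is evaluated first; with the default
    majority of 3 out of 4 weeks the two rules can never both fire.
    """
    vals = [v for v in profile.weekly_median_logcdr if np.isfinite(v)]
    if not vals:
        raise Unclassifiable(f"patient {profile.patient_id}: all four weeks missing")
    n_above = sum(v > quartiles.q3 for v in vals)
    if n_above >= majority:
        return "SE"
    n_below = sum(v < quartiles.q1 for v in vals)
    if n_below >= majority:
        return "FE"
    return "IE"


def classify_cpic(call: str | None) -> str:
    """EM/IM/PM from a single rs776746 genotype (AA -> EM, AG -> IM, GG -> PM)."""
    if call is None:
        raise Unclassifiable("missing rs776746 call")
    mapping = {"AA": "EM", "AG": "IM", "GG": "PM"}
    if call not in mapping:
        raise ValidationError(f"unexpected rs776746 genotype {call!r}")
    return mapping[call]


def classify_cpic_pooled(call: str | None) -> str:
    """Expresser grouping used in the association analyses: AA/AG -> EM, GG -> PM."""
    if call is None:
        raise Unclassifiable("missing rs776746 call")
    if call in ("AA", "AG"):
        return "EM"
    if call == "GG":
        return "PM"
    raise ValidationError(f"unexpected rs776746 genotype {call!r}")


def classify_paired(donor: str | None, recipient: str | None) -> str:
    """Paired EM/IM/PM from donor and recipient rs776746 genotypes."""
    if donor is None or recipient is None:
        raise Unclassifiable("missing rs776746 call in donor or recipient")
    for call in (donor, recipient):
        if call not in ("AA", "AG", "GG"):
            raise ValidationError(f"unexpected rs776746 genotype {call!r}")
    n_gg = (donor == "GG") + (recipient == "GG")
    return ("EM", "IM", "PM")[n_gg]


def classify_genetic(
    paired_label: str,
    recipient_sult1e1: str | None,
    donor_slc7a8: str | None,
    direction: dict[str, dict[str, list[str]]],
) -> tuple[str, bool]:
    """Refine a paired-EIP label with the two minor-effect loci.

    Returns ``(label, refined)``.  Only EM and PM are eligible for
    refinement, and refinement always moves toward IM.  A missing minor
    call, or a locus absent from the direction map because its direction
    could not be inferred, leaves the paired label in place with
    ``refined=False``.
    """
    for _, rsid in (MINOR_EM_LOCUS, MINOR_PM_LOCUS):
        if rsid in direction:
            sides = direction[rsid]
            if "slow" not in sides or "fast" not in sides:
                raise ValidationError(f"direction map for {rsid} needs slow and fast sides")
    if paired_label == "IM":
        return "IM", False
    if paired_label == "EM":
        sides = direction.get(MINOR_EM_LOCUS[1])
        if sides is None or recipient_sult1e1 is None:
            return "EM", False
        if recipient_sult1e1 in sides["slow"]:
            return "IM", True
        return "EM", False
    if paired_label == "PM":
        sides = direction.get(MINOR_PM_LOCUS[1])
        if sides is None or donor_slc7a8 is None:
            return "PM", False
        if donor_slc7a8 in sides["fast"]:
            return "IM", True
        return "PM", False
    raise ValidationError(f"unexpected paired label {paired_label!r}")


@dataclass
class DirectionInference:
    """Outcome of the data-driven slow/fast assignment for one minor locus."""

    rsid: str
    slow: tuple[str, ...] | None
    fast: tuple[str, ...] | None
    group_means: dict[str, float]
    n_per_group: dict[str, int]


def infer_minor_direction(
    weekly: pd.DataFrame,
    pairs: list[GenotypePair],
    paired_labels: dict[str, str],
    min_group: int = 5,
) -> dict[str, dict[str, list[str]]]:
    """Learn which genotype group of each minor locus is the slow side.

    Within the refined stratum (paired-EM for recipient rs3775770,
    paired-PM for donor rs7141505) the mean of the week-2..4 log-CDR
    medians is compared between the locus's two genotype groups; the lower
    mean is the fast side.  Groups below ``min_group`` patients, or exact
    ties, leave the locus out of the returned map (the refinement then
    leaves that stratum untouched).
    """
    weekly = weekly.set_index("patient_id")
    late = weekly[["week2", "week3", "week4"]].mean(axis=1)
    calls = {p.patient_id: p for p in pairs}
    direction: dict[str, dict[str, list[str]]] = {}
    for stratum, (role, rsid) in (("EM", MINOR_EM_LOCUS), ("PM", MINOR_PM_LOCUS)):
        group_a, group_b = MINOR_GROUPS[rsid]
        means: dict[str, list[float]] = {"a": [], "b": []}
        for pid, label in paired_labels.items():
            if label != stratum or pid not in calls or pid not in late.index:
                continue
            call = calls[pid].call(role, rsid)
            v = late.loc[pid]
            if call is None or not np.isfinite(v):
                continue
            if call in group_a:
                means["a"].append(float(v))
            elif call in group_b:
                means["b"].append(float(v))
        if len(means["a"]) < min_group or len(means["b"]) < min_group:
            continue
        mean_a, mean_b = float(np.mean(means["a"])), float(np.mean(means["b"]))
        if mean_a == mean_b:
            warnings.warn(f"{rsid}: genotype groups tied; left unrefined", stacklevel=2)
            continue
        slow, fast = (group_a, group_b) if mean_a > mean_b else (group_b, group_a)
        direction[rsid] = {"slow": list(slow), "fast": list(fast)}
    return direction


def classify_cohort(
    weekly: pd.DataFrame,
    quartiles: dict,
    pairs: list[GenotypePair],
    direction: dict[str, dict[str, list[str]]] | None = None,
    majority: int = 3,
    schemes: tuple[str, ...] = ("fis", "cpic", "paired", "genetic"),
) -> pd.DataFrame:
    """Label every patient under the requested schemes.

    Returns a long frame (patient_id, scheme, label); unclassifiable
    patients are simply absent from that scheme's rows.  When ``direction``
    is None the genetic-EIP refinement directions are inferred from the
    cohort itself.
    """
    rows: list[tuple[str, str, str]] = []
    paired_labels: dict[str, str] = {}
    by_id = {p.patient_id: p for p in pairs}

    if "fis" in schemes:
        for row in weekly.itertuples(index=False):
            prof = WeeklyCDRProfile(
                row.patient_id,
                (row.week1, row.week2, row.week3, row.week4),
                (0, 0, 0, 0),
            )
            try:
                label = classify_fis(prof, quartiles[str(row.center_id)], majority)
            except Unclassifiable:
                continue
            rows.append((row.patient_id, "clinical-FIS", label))

    for pid, pair in by_id.items():
        d, r = pair.call("donor", CYP3A5), pair.call("recipient", CYP3A5)
        if "cpic" in schemes:
            try:
                rows.append((pid, "CPIC-recipient", classify_cpic(r)))
            except Unclassifiable:
                pass
            try:
                rows.append((pid, "CPIC-donor", classify_cpic(d)))
            except Unclassifiable:
                pass
        try:
            paired_labels[pid] = classify_paired(d, r)
        except Unclassifiable:
            continue
        if "paired" in schemes:
            rows.append((pid, "paired-EIP", paired_labels[pid]))

    if "genetic" in schemes:
        if direction is None:
            direction = infer_minor_direction(weekly, pairs, paired_labels)
        for pid, paired_label in paired_labels.items():
            pair = by_id[pid]
            label, _ = classify_genetic(
                paired_label,
                pair.call(*MINOR_EM_LOCUS),
                pair.call(*MINOR_PM_LOCUS),
                direction,
            )
            rows.append((pid, "genetic-EIP", label))

    return pd.DataFrame(rows, columns=["patient_id", "scheme", "label"])
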