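"""Agreement between classification schemes and per-group outcome tests.

The clinical-FIS and EIP label sets correspond class-to-class: fast
eliminators to extensive metabolizers (FE-EM), intermediate to intermediate
(IE-IM), and slow eliminators to poor metabolizers (SE-PM).  Agreement
between a clinical and a genetic scheme is the proportion of patients on
the diagonal of the 3x3 cross-tabulation under that mapping.

Outcome comparisons across the three clinical groups use a Pearson
chi-square for binary outcomes and the Kruskal-Wallis test with Dunn's
post-hoc pairwise comparisons for continuous ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import EIP_LABELS, FIS_LABELS, ValidationError

#: class correspondence used for the agreement diagonal
FIS_TO_EIP = {"FE": "EM", "IE": "IM", "SE": "PM"}


def sig3(x: float) -> float:
    """Round to 3 significant figures (the reporting convention for rates)."""
    return float(f"{x:.3g}")


def proportion_summary(numerator: int, denominator: int) -> float:
    """Percentage 100*num/den rounded to 3 significant figures."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator outside [0, denominator]")
    return sig3(100.0 * numerator / denominator)


@dataclass
class AgreementMatrix:
    """3x3 cross-tabulation of clinical-FIS rows against EIP columns."""

    scheme_pair: tuple[str, str]
    counts: pd.DataFrame  # index FE/IE/SE, columns EM/IM/PM
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def overall_pct(self) -> float:
        return sig3(100.0 * np.trace(self.counts.to_numpy()) / self.total)

    def per_class_pct(self) -> dict[str, float]:
        """Diagonal count over column total, per EIP class (NaN if empty)."""
        out = {}
        mat = self.counts.to_numpy()
        for j, eip in enumerate(EIP_LABELS):
            col = mat[:, j].sum()
            out[eip] = sig3(100.0 * mat[j, j] / col) if col else float("nan")
        return out


def agreement(
    labels_fis: dict[str, str], labels_eip: dict[str, str], scheme: str = "EIP"
) -> AgreementMatrix:
    """Cross-tabulate clinical-FIS labels against an EIP scheme's labels.

    Only patients classified under both schemes enter the table; the
    number excluded is carried on the result.  An empty intersection is
    fatal.
    """
    common = sorted(set(labels_fis) & set(labels_eip))
    if not common:
        raise ValidationError("no patients classified under both schemes")
    counts = pd.DataFrame(0, index=list(FIS_LABELS), columns=list(EIP_LABELS))
    for pid in common:
        counts.loc[labels_fis[pid], labels_eip[pid]] += 1
    excluded = len(set(labels_fis) | set(labels_eip)) - len(common)
    return AgreementMatrix(("clinical-FIS", scheme), counts, n_excluded=excluded)


@dataclass
class GroupOutcomeSummary:
    """One group's rate (or median/IQR) for one outcome."""

    scheme: str
    group: str
    outcome: str
    numerator: int | None = None
    denominator: int | None = None
    percentage: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None


def summarize_binary_outcome(
    labels: dict[str, str], outcome: dict[str, bool | None], outcome_name: str, scheme: str = "clinical-FIS"
) -> list[GroupOutcomeSummary]:
    """Per-group (numerator, denominator, %) for a tri-state boolean outcome.

    Patients with a missing outcome drop out of that outcome's denominator
    only, so denominators legitimately differ across outcomes.
    """
    order = FIS_LABELS if set(labels.values()) <= set(FIS_LABELS) else EIP_LABELS
    out = []
    for group in order:
        pids = [pid for pid, lab in labels.items() if lab == group]
        known = [outcome[pid] for pid in pids if outcome.get(pid) is not None]
        if not known:
            continue
        num = sum(known)
        out.append(
            GroupOutcomeSummary(
                scheme, group, outcome_name,
                numerator=int(num), denominator=len(known),
                percentage=proportion_summary(int(num), len(known)),
            )
        )
    return out


def summarize_continuous_outcome(
    labels: dict[str, str], outcome: dict[str, float | None], outcome_name: str, scheme: str = "clinical-FIS"
) -> list[GroupOutcomeSummary]:
    order = FIS_LABELS if set(labels.values()) <= set(FIS_LABELS) else EIP_LABELS
    out = []
    for group in order:
        vals = np.array(
            [outcome[pid] for pid, lab in labels.items() if lab == group and outcome.get(pid) is not None],
            dtype=float,
        )
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append(
            GroupOutcomeSummary(scheme, group, outcome_name, median=float(med), q1=float(q1), q3=float(q3))
        )
    return out


def group_rate_test(table: np.ndarray | list) -> tuple[float, float]:
    """Pearson chi-square comparing a binary outcome across groups.

    ``table`` is (events, non-events) per group, shape (2, k) or (k, 2).
    Groups with a zero denominator are dropped with a warning and the
    degrees of freedom adjusted; expected counts below 5 warn.
    Returns ``(chi2, p)``.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValidationError("need a 2-d contingency table")
    if tab.shape[0] == 2 and tab.shape[1] != 2:
        tab = tab.T  # groups as rows
    totals = tab.sum(axis=1)
    if (totals == 0).any():
        warnings.warn("group with zero denominator dropped from chi-square", stacklevel=2)
        tab = tab[totals > 0]
    if tab.shape[0] < 2:
        raise ValidationError("need >= 2 non-empty groups")
    if (tab.sum(axis=0) == 0).any():
        return 0.0, 1.0  # outcome constant across all groups
    chi2, p, _, expected = stats.chi2_contingency(tab, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count < 5; chi-square approximation is rough", stacklevel=2)
    return float(chi2), float(p)


def group_continuous_test(
    groups: list[np.ndarray | list], p_adjust: str = "bonferroni"
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis test across groups with Dunn's pairwise post-hoc.

    Groups with fewer than two values are dropped with a warning.  Dunn's
    z statistics use the tie-corrected rank variance; pairwise p values
    are Bonferroni-adjusted by default (``p_adjust=None`` for raw).
    Returns ``(H, p, pairwise)`` where ``pairwise`` has one row per group
    pair.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    kept_idx = [i for i, g in enumerate(arrays) if len(g) >= 2]
    if len(kept_idx) < len(arrays):
        warnings.warn("groups with < 2 values dropped from Kruskal-Wallis", stacklevel=2)
    arrays = [arrays[i] for i in kept_idx]
    if len(arrays) < 2:
        raise ValidationError("need >= 2 groups with >= 2 values")
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in (0,)):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)

    # Dunn's test: z for each pair from mean ranks of the pooled ranking
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    sizes = [len(g) for g in arrays]
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    rows = []
    pairs = list(combinations(range(len(arrays)), 2))
    for i, j in pairs:
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        praw = 2 * stats.norm.sf(abs(z))
        padj = min(1.0, praw * len(pairs)) if p_adjust == "bonferroni" else praw
        rows.append({"group_i": kept_idx[i], "group_j": kept_idx[j], "z": z, "p_raw": praw, "p_adj": padj})
    return float(h), float(p), pd.DataFrame(rows)
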