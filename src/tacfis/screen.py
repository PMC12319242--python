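"""Two-tier SNP association screen on weekly log-CDR phenotypes.

Tier one (training cohort): for every locus, carriers of the minor allele
are contrasted with non-carriers by a two-sample t-test on each of the four
weekly log-CDR medians, and loci are filtered on four rules — significance
in consecutive weeks, minor allele frequency, linkage-disequilibrium
pruning at r² > 0.5, and genomic-region preference.  Tier two: surviving
loci are re-tested in an independent validation cohort; replication
substitutes for multiple-testing correction.

Every filtering decision is recorded in a :class:`FilterAudit` so the
screen's output can be reconstructed and checked.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import LociFilterConfig
from .types import GenotypePair, ValidationError

#: genomic-region preference ranks: coding/UTR/splicing beat intronic beat
#: intergenic/upstream; unannotated loci rank last.
REGION_RANK = {
    "exonic": 1,
    "exonic(n)": 1,
    "exonic(s)": 1,
    "utr": 1,
    "utr3": 1,
    "utr5": 1,
    "splicing": 1,
    "intronic": 2,
    "upstream": 3,
    "downstream": 3,
    "intergenic": 3,
}
UNKNOWN_REGION_RANK = 4


def region_rank(region: str | None) -> int:
    if region is None:
        return UNKNOWN_REGION_RANK
    return REGION_RANK.get(str(region).strip().lower(), UNKNOWN_REGION_RANK)


# ---------------------------------------------------------------------------
# genotype summaries


@dataclass
class GroupAssignment:
    """Two-group split of a cohort at one locus (dominant contrast)."""

    rsid: str
    group1_genotypes: tuple[str, ...]
    group2_genotypes: tuple[str, ...]
    membership: dict[str, int]  # patient_id -> 1 or 2; missing calls absent
    untestable: bool = False


def allele_counts(calls: list[str | None]) -> Counter:
    counts: Counter = Counter()
    for call in calls:
        if call is not None:
            counts.update(call)
    return counts


def compute_maf(calls: list[str | None]) -> float:
    """Minor allele frequency among non-missing calls, in [0, 0.5]."""
    counts = allele_counts(calls)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("all calls missing; MAF undefined")
    if len(counts) == 1:
        return 0.0
    if len(counts) > 2:
        raise ValidationError(f"locus not biallelic: alleles {sorted(counts)}")
    return min(counts.values()) / total


def minor_allele(calls: list[str | None]) -> str | None:
    """Minor allele of a biallelic locus; None if monomorphic or all missing.

    Frequency ties break lexicographically so the choice is deterministic.
    """
    counts = allele_counts(calls)
    if len(counts) != 2:
        return None
    (a1, n1), (a2, n2) = sorted(counts.items())
    return a1 if n1 <= n2 else a2


def dominant_groups(
    calls: dict[str, str | None],
    rsid: str = "",
    grouping: tuple[tuple[str, ...], tuple[str, ...]] | None = None,
) -> GroupAssignment:
    """Split patients into minor-allele carriers vs non-carriers.

    ``grouping`` overrides the default dominant contrast with an explicit
    pair of genotype tuples (e.g. ``(("GG",), ("CC", "CG"))`` for a
    recessive-style split).  Monomorphic loci come back flagged untestable
    with everyone in group 1.
    """
    values = list(calls.values())
    if grouping is None:
        minor = minor_allele(values)
        if minor is None:
            return GroupAssignment(
                rsid, (), (), {p: 1 for p, c in calls.items() if c is not None}, untestable=True
            )
        genos = sorted({c for c in values if c is not None})
        g1 = tuple(g for g in genos if minor in g)
        g2 = tuple(g for g in genos if minor not in g)
    else:
        g1, g2 = tuple(grouping[0]), tuple(grouping[1])
    membership = {}
    for pid, call in calls.items():
        if call is None:
            continue
        if call in g1:
            membership[pid] = 1
        elif call in g2:
            membership[pid] = 2
    untestable = not (any(v == 1 for v in membership.values()) and any(v == 2 for v in membership.values()))
    return GroupAssignment(rsid, g1, g2, membership, untestable=untestable)


def dosage_vector(calls: list[str | None]) -> np.ndarray:
    """Minor-allele dosage (0/1/2) per call; NaN for missing."""
    minor = minor_allele(calls)
    out = np.full(len(calls), np.nan)
    for i, call in enumerate(calls):
        if call is None:
            continue
        out[i] = call.count(minor) if minor is not None else 0.0
    return out


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """One-df chi-square test of Hardy-Weinberg proportions.

    Arguments are genotype counts (major hom, het, minor hom).  Returns
    ``(chi2, p)``; a zero expected count (monomorphic sample) leaves the
    test undefined and returns ``(nan, nan)``.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValidationError("negative genotype counts")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValidationError("empty genotype table")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if np.any(expected == 0):
        return float("nan"), float("nan")
    observed = np.array([n_aa, n_ab, n_bb])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genotype_r2(calls_a: list[str | None], calls_b: list[str | None]) -> float:
    """Squared Pearson correlation of minor-allele dosages at two loci.

    The standard genotype-level LD estimate.  Requires >= 3 patients with
    calls at both loci; zero variance at either locus leaves r² undefined
    (NaN), which downstream pruning treats as not-in-LD.
    """
    da, db = dosage_vector(calls_a), dosage_vector(calls_b)
    ok = np.isfinite(da) & np.isfinite(db)
    if ok.sum() < 3:
        raise ValidationError("need >= 3 patients non-missing at both loci")
    da, db = da[ok], db[ok]
    if da.std() == 0 or db.std() == 0:
        return float("nan")
    r = np.corrcoef(da, db)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# weekly group tests


@dataclass
class LocusAssociationResult:
    """Group contrast of weekly log CDR at one locus."""

    rsid: str
    role: str
    week: int
    group1: tuple[str, ...]
    group2: tuple[str, ...]
    n1: int
    n2: int
    mean1: float
    mean2: float
    t: float
    p: float
    untestable: bool = False


def weekly_ttest(
    values: dict[str, float],
    groups: GroupAssignment,
    week: int = 0,
    role: str = "",
    welch: bool = True,
) -> LocusAssociationResult:
    """Two-sample t-test of weekly log CDR between the two genotype groups.

    Welch's unequal-variance test by default; the pooled-variance Student
    test is available for exact comparison studies.  Groups with fewer than
    two phenotyped patients make the week untestable.  Two identical
    constant groups give ``t=0, p=1`` rather than an undefined ratio.
    """
    x1 = np.array([v for pid, v in values.items() if groups.membership.get(pid) == 1 and np.isfinite(v)])
    x2 = np.array([v for pid, v in values.items() if groups.membership.get(pid) == 2 and np.isfinite(v)])
    base = dict(
        rsid=groups.rsid, role=role, week=week,
        group1=groups.group1_genotypes, group2=groups.group2_genotypes,
        n1=len(x1), n2=len(x2),
        mean1=float(x1.mean()) if len(x1) else float("nan"),
        mean2=float(x2.mean()) if len(x2) else float("nan"),
    )
    if groups.untestable or len(x1) < 2 or len(x2) < 2:
        return LocusAssociationResult(**base, t=float("nan"), p=float("nan"), untestable=True)
    if x1.var(ddof=1) == 0 and x2.var(ddof=1) == 0:
        if x1.mean() == x2.mean():
            return LocusAssociationResult(**base, t=0.0, p=1.0)
        return LocusAssociationResult(**base, t=float("inf"), p=0.0)
    t, p = stats.ttest_ind(x1, x2, equal_var=not welch)
    return LocusAssociationResult(**base, t=float(t), p=float(p))


def ttest_matrix(y: np.ndarray, indicators: np.ndarray, welch: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sample t-tests of one phenotype against many loci.

    ``y`` is (n,), ``indicators`` (n, L) with entries 1/2 for the two
    genotype groups and NaN for missing.  Returns ``(t, p)`` arrays of
    length L, NaN where a group has fewer than two phenotyped patients.
    Used for simulation studies where looping per locus would dominate.
    """
    y = np.asarray(y, dtype=float)
    ind = np.asarray(indicators, dtype=float)
    ok = np.isfinite(y)[:, None] & np.isfinite(ind)
    m1 = ok & (ind == 1)
    m2 = ok & (ind == 2)
    n1 = m1.sum(axis=0).astype(float)
    n2 = m2.sum(axis=0).astype(float)
    yv = np.where(np.isfinite(y), y, 0.0)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = (yv * m1).sum(axis=0) / n1
        s2 = (yv * m2).sum(axis=0) / n2
        v1 = ((yv - s1) ** 2 * m1).sum(axis=0) / (n1 - 1)
        v2 = ((yv - s2) ** 2 * m2).sum(axis=0) / (n2 - 1)
        if welch:
            se2 = v1 / n1 + v2 / n2
            t = (s1 - s2) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            t = (s1 - s2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
    p = 2 * stats.t.sf(np.abs(t), df)
    bad = (n1 < 2) | (n2 < 2)
    t[bad] = np.nan
    p[bad] = np.nan
    return t, p


# ---------------------------------------------------------------------------
# filtering and replication


@dataclass
class FilterAudit:
    """Why one locus was retained or dropped by the training filter."""

    rsid: str
    role: str
    passed_p_rule: bool
    passed_maf: bool
    passed_ld: bool
    region_rank: int
    retained: bool
    ld_proxy: str | None = None  # locus this one was pruned in favour of
    maf: float = float("nan")
    min_p: float = float("nan")

    @property
    def key(self) -> str:
        return f"{'D' if self.role == 'donor' else 'R'}.{self.rsid}"


def _consecutive_sig(pvals: list[float], alpha: float, k: int) -> bool:
    run = 0
    for p in pvals:
        if np.isfinite(p) and p < alpha:
            run += 1
            if run >= k:
                return True
        else:
            run = 0
    return False


def filter_loci(
    results: list[LocusAssociationResult],
    mafs: dict[str, float],
    r2: pd.DataFrame,
    regions: dict[str, str] | None = None,
    config: LociFilterConfig | None = None,
) -> list[FilterAudit]:
    """Apply the four training-phase retention rules, with a full audit.

    Rules: (1) p < ``p_threshold`` in at least ``consecutive_weeks_min``
    consecutive weeks; (2) MAF > ``maf_min``; (3) within each LD cluster —
    a connected component of the r² > ``ld_r2_max`` graph over loci passing
    rules 1-2 — exactly one locus is kept, preferring better region rank,
    then smaller minimum weekly p, then lexicographic key; (4) region rank
    is the tie-breaking preference of rule 3.  Keys in ``mafs``/``r2``/
    ``regions`` are role-prefixed (``D.rsid``/``R.rsid``).
    """
    config = config or LociFilterConfig()
    regions = regions or {}
    by_locus: dict[tuple[str, str], list[LocusAssociationResult]] = {}
    for res in results:
        by_locus.setdefault((res.rsid, res.role), []).append(res)

    audits: dict[str, FilterAudit] = {}
    for (rsid, role), locus_results in by_locus.items():
        locus_results = sorted(locus_results, key=lambda r: r.week)
        key = f"{'D' if role == 'donor' else 'R'}.{rsid}"
        pvals = [r.p for r in locus_results]
        finite = [p for p in pvals if np.isfinite(p)]
        maf = mafs.get(key, float("nan"))
        audits[key] = FilterAudit(
            rsid=rsid,
            role=role,
            passed_p_rule=_consecutive_sig(pvals, config.p_threshold, config.consecutive_weeks_min),
            passed_maf=bool(np.isfinite(maf) and maf > config.maf_min),
            passed_ld=True,
            region_rank=region_rank(regions.get(key)),
            retained=False,
            maf=maf,
            min_p=min(finite) if finite else float("nan"),
        )

    # LD pruning over the survivors of rules 1-2
    candidates = sorted(k for k, a in audits.items() if a.passed_p_rule and a.passed_maf)
    adjacency = {k: set() for k in candidates}
    for i, ka in enumerate(candidates):
        for kb in candidates[i + 1 :]:
            if ka in r2.index and kb in r2.columns:
                val = r2.loc[ka, kb]
            elif kb in r2.index and ka in r2.columns:
                val = r2.loc[kb, ka]
            else:
                continue
            if np.isfinite(val) and val > config.ld_r2_max:
                adjacency[ka].add(kb)
                adjacency[kb].add(ka)

    seen: set[str] = set()
    for start in candidates:
        if start in seen:
            continue
        cluster, stack = [], [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            cluster.append(node)
            stack.extend(adjacency[node] - seen)
        winner = min(cluster, key=lambda k: (audits[k].region_rank, audits[k].min_p, k))
        for key in cluster:
            if key == winner:
                audits[key].retained = True
            else:
                audits[key].passed_ld = False
                audits[key].ld_proxy = winner
    return [audits[k] for k in sorted(audits)]


@dataclass
class ReplicationResult:
    """Validation-phase verdict for one training-retained locus."""

    rsid: str
    role: str
    training_p: tuple[float, float, float, float]
    validation_p: tuple[float, float, float, float]
    replicated: bool | None  # None = undetermined (untestable in validation)


def replicate(
    training_audits: list[FilterAudit],
    validation_results: list[LocusAssociationResult],
    config: LociFilterConfig | None = None,
    training_results: list[LocusAssociationResult] | None = None,
) -> list[ReplicationResult]:
    """Tier-two replication of training-retained loci.

    A locus replicates if its validation p is below the threshold in at
    least ``replication_weeks_min`` weeks; a locus untestable in the
    validation cohort is carried with ``replicated=None``.
    """
    config = config or LociFilterConfig()
    val_by_locus: dict[tuple[str, str], dict[int, LocusAssociationResult]] = {}
    for res in validation_results:
        val_by_locus.setdefault((res.rsid, res.role), {})[res.week] = res
    train_by_locus: dict[tuple[str, str], dict[int, LocusAssociationResult]] = {}
    for res in training_results or []:
        train_by_locus.setdefault((res.rsid, res.role), {})[res.week] = res

    out = []
    for audit in training_audits:
        if not audit.retained:
            continue
        key = (audit.rsid, audit.role)
        val = val_by_locus.get(key, {})
        val_p = tuple(val[w].p if w in val else float("nan") for w in (1, 2, 3, 4))
        train = train_by_locus.get(key, {})
        train_p = tuple(train[w].p if w in train else float("nan") for w in (1, 2, 3, 4))
        finite = [p for p in val_p if np.isfinite(p)]
        if not finite:
            verdict = None
        else:
            n_sig = sum(p < config.p_threshold for p in finite)
            verdict = n_sig >= config.replication_weeks_min
        out.append(ReplicationResult(audit.rsid, audit.role, train_p, val_p, verdict))
    return out


def popfreq_diff(freqs: dict[str, float]) -> float:
    """Cross-population allele-frequency spread: max frequency minus min."""
    if not freqs:
        raise ValidationError("empty population-frequency map")
    vals = list(freqs.values())
    return max(vals) - min(vals)


# ---------------------------------------------------------------------------
# cohort-level driver


def locus_calls(
    pairs: list[GenotypePair], rsid: str, role: str
) -> dict[str, str | None]:
    return {p.patient_id: p.call(role, rsid) for p in pairs}


def screen_cohort(
    weekly: pd.DataFrame,
    pairs: list[GenotypePair],
    loci: list[tuple[str, str]],
    groupings: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
    welch: bool = True,
    patients: set[str] | None = None,
) -> tuple[list[LocusAssociationResult], dict[str, float], pd.DataFrame]:
    """Run the weekly t-tests for a list of (rsid, role) loci.

    Returns the per-week association results, role-prefixed MAFs, and the
    pairwise genotype r² matrix used by LD pruning.  ``patients`` restricts
    the run to a stratum (e.g. the paired-EM subgroup) without changing
    anything else.
    """
    groupings = groupings or {}
    weekly = weekly.set_index("patient_id")
    if patients is not None:
        weekly = weekly.loc[weekly.index.isin(patients)]
        pairs = [p for p in pairs if p.patient_id in patients]

    results: list[LocusAssociationResult] = []
    mafs: dict[str, float] = {}
    keyed_calls: dict[str, dict[str, str | None]] = {}
    for rsid, role in loci:
        key = f"{'D' if role == 'donor' else 'R'}.{rsid}"
        calls = locus_calls(pairs, rsid, role)
        keyed_calls[key] = calls
        values = list(calls.values())
        try:
            mafs[key] = compute_maf(values)
        except ValidationError:
            mafs[key] = float("nan")
        groups = dominant_groups(calls, rsid=rsid, grouping=groupings.get(key))
        for w in (1, 2, 3, 4):
            col = f"week{w}"
            vals = weekly[col].to_dict() if col in weekly else {}
            results.append(weekly_ttest(vals, groups, week=w, role=role, welch=welch))

    keys = sorted(keyed_calls)
    r2 = pd.DataFrame(np.nan, index=keys, columns=keys)
    for i, ka in enumerate(keys):
        r2.loc[ka, ka] = 1.0
        for kb in keys[i + 1 :]:
            ids = [pid for pid in keyed_calls[ka] if pid in keyed_calls[kb]]
            ca = [keyed_calls[ka][pid] for pid in ids]
            cb = [keyed_calls[kb][pid] for pid in ids]
            try:
                val = genotype_r2(ca, cb)
            except ValidationError:
                val = float("nan")
            r2.loc[ka, kb] = r2.loc[kb, ka] = val
    return results, mafs, r2


def association_frame(results: list[LocusAssociationResult]) -> pd.DataFrame:
    """Long frame of weekly association results (one row per locus-week)."""
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in results],
            "role": [r.role for r in results],
            "week": [r.week for r in results],
            "GT1": ["/".join(r.group1) for r in results],
            "GT2": ["/".join(r.group2) for r in results],
            "n1": [r.n1 for r in results],
            "n2": [r.n2 for r in results],
            "mean1": [r.mean1 for r in results],
            "mean2": [r.mean2 for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
        }
    )
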