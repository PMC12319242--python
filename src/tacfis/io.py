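"""Tabular readers and writers.

TSV is the primary interchange format; CSV is accepted everywhere via the
``dialect`` argument.  Genotype tables follow the ``D.<rsid>`` /
``R.<rsid>`` column convention for donor-role and recipient-role calls;
PLINK ped/map pairs and plain VCF are supported as convenience importers
mapped onto the same :class:`~tacfis.types.GenotypePair` records.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING_TOKENS,
    GenotypePair,
    OutcomeRecord,
    PKDayRecord,
    ValidationError,
    canonical_call,
)

PK_COLUMNS = ("patient_id", "center_id", "day", "trough", "daily_dose", "weight")

_SEP = {"tsv": "\t", "csv": ","}


def _delimiter(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        try:
            return _SEP[dialect]
        except KeyError:
            raise ValidationError(f"unknown dialect {dialect!r}") from None
    return _SEP["csv" if str(path).endswith(".csv") else "tsv"]


# ---------------------------------------------------------------------------
# pharmacokinetic table


def read_pk_table(
    path: str | Path,
    dialect: str | None = None,
    column_map: dict[str, str] | None = None,
) -> list[PKDayRecord]:
    """Read a longitudinal TDM table into validated :class:`PKDayRecord` rows.

    The header must name the six required columns (case-insensitive);
    ``column_map`` maps non-standard header names onto the required ones.
    Rows with a missing trough or dose are retained with missing markers —
    monitoring gaps are normal.  A malformed numeric field or an invariant
    violation raises :class:`ValidationError` naming the line.
    """
    df = pd.read_csv(path, sep=_delimiter(path, dialect), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [c.lower() for c in df.columns]
    missing_cols = set(PK_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {sorted(missing_cols)}")

    records: list[PKDayRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                PKDayRecord(
                    patient_id=str(getattr(row, "patient_id")),
                    center_id=str(getattr(row, "center_id")),
                    day=int(getattr(row, "day")),
                    trough=_opt_float(getattr(row, "trough")),
                    daily_dose=_opt_float(getattr(row, "daily_dose")),
                    weight=float(getattr(row, "weight")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return records


def _opt_float(token) -> float | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    if isinstance(token, str) and token.strip() in MISSING_TOKENS:
        return None
    return float(token)


def write_pk_table(records: list[PKDayRecord], path: str | Path, dialect: str | None = None) -> None:
    pk_frame(records).to_csv(path, sep=_delimiter(path, dialect), index=False)


def pk_frame(records: list[PKDayRecord]) -> pd.DataFrame:
    """Records -> frame with one row per patient-day (missing as NaN)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "center_id": [r.center_id for r in records],
            "day": [r.day for r in records],
            "trough": [np.nan if r.trough is None else r.trough for r in records],
            "daily_dose": [np.nan if r.daily_dose is None else r.daily_dose for r in records],
            "weight": [r.weight for r in records],
        }
    )


# ---------------------------------------------------------------------------
# genotype tables

_ROLE_PREFIX = {"D": "donor", "R": "recipient"}


def read_genotype_table(path: str | Path, dialect: str | None = None) -> list[GenotypePair]:
    """Read a wide genotype table (columns ``D.<rsid>`` / ``R.<rsid>``).

    Calls are canonicalised (alleles sorted); recognised missing tokens map
    to ``None``.  Duplicate patient ids are fatal; an unparseable allele
    token raises with its row.
    """
    df = pd.read_csv(path, sep=_delimiter(path, dialect), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    id_col = next((c for c in df.columns if c.lower() == "patient_id"), None)
    if id_col is None:
        raise ValidationError(f"{path}: missing patient_id column")
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate patient_id {dup!r}")

    role_cols: list[tuple[str, str, str]] = []  # (column, role, rsid)
    for col in df.columns:
        if col == id_col:
            continue
        prefix, _, rsid = col.partition(".")
        if prefix.upper() in _ROLE_PREFIX and rsid:
            role_cols.append((col, _ROLE_PREFIX[prefix.upper()], rsid))

    pairs: list[GenotypePair] = []
    for i, row in df.iterrows():
        pair = GenotypePair(patient_id=str(row[id_col]))
        for col, role, rsid in role_cols:
            try:
                call = canonical_call(None if pd.isna(row[col]) else str(row[col]))
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i + 2}, column {col}: {exc}") from exc
            table = pair.donor_genotypes if role == "donor" else pair.recipient_genotypes
            table[rsid] = call
        pairs.append(pair)
    return pairs


def write_genotype_table(
    pairs: list[GenotypePair], path: str | Path, dialect: str | None = None
) -> None:
    genotype_frame(pairs).to_csv(path, sep=_delimiter(path, dialect), index=False, na_rep="NA")


def genotype_frame(pairs: list[GenotypePair]) -> pd.DataFrame:
    """Pairs -> wide frame, one column per role-prefixed rsID."""
    rsids_d = sorted({r for p in pairs for r in p.donor_genotypes})
    rsids_r = sorted({r for p in pairs for r in p.recipient_genotypes})
    data: dict[str, list] = {"patient_id": [p.patient_id for p in pairs]}
    for rsid in rsids_d:
        data[f"D.{rsid}"] = [p.donor_genotypes.get(rsid) for p in pairs]
    for rsid in rsids_r:
        data[f"R.{rsid}"] = [p.recipient_genotypes.get(rsid) for p in pairs]
    return pd.DataFrame(data)


def read_plink_genotypes(ped_path: str | Path, map_path: str | Path, role: str) -> list[GenotypePair]:
    """Read a PLINK text ped/map pair; all loci are assigned to ``role``.

    The ped individual id (column 2) is used as the patient id.  ``0`` is
    the PLINK missing-allele code.
    """
    if role not in ("donor", "recipient"):
        raise ValidationError(f"role must be donor or recipient, got {role!r}")
    rsids = [line.split()[1] for line in Path(map_path).read_text().splitlines() if line.strip()]
    pairs: list[GenotypePair] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * len(rsids):
            raise ValidationError(
                f"{ped_path}: line {lineno}: expected {6 + 2 * len(rsids)} fields, got {len(fields)}"
            )
        pid = fields[1]
        pair = GenotypePair(patient_id=pid)
        table = pair.donor_genotypes if role == "donor" else pair.recipient_genotypes
        for j, rsid in enumerate(rsids):
            a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
            table[rsid] = None if "0" in (a1, a2) else canonical_call(a1 + a2)
        pairs.append(pair)
    return pairs


def read_vcf_genotypes(path: str | Path, role: str) -> list[GenotypePair]:
    """Read genotypes from a VCF; sample names become patient ids.

    Requires the optional ``cyvcf2`` dependency.  Multi-allelic records are
    read using REF plus the called ALT alleles.
    """
    if role not in ("donor", "recipient"):
        raise ValidationError(f"role must be donor or recipient, got {role!r}")
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    pairs = {s: GenotypePair(patient_id=s) for s in vcf.samples}
    for variant in vcf:
        rsid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        alleles = [variant.REF] + list(variant.ALT)
        for sample, gt in zip(vcf.samples, variant.genotypes):
            a, b = gt[0], gt[1]
            call = None if a < 0 or b < 0 else canonical_call(alleles[a] + alleles[b])
            table = pairs[sample].donor_genotypes if role == "donor" else pairs[sample].recipient_genotypes
            table[rsid] = call
    return list(pairs.values())


def merge_roles(donor: list[GenotypePair], recipient: list[GenotypePair]) -> list[GenotypePair]:
    """Combine donor-role and recipient-role imports on patient id."""
    by_id = {p.patient_id: GenotypePair(patient_id=p.patient_id, donor_genotypes=dict(p.donor_genotypes)) for p in donor}
    for p in recipient:
        target = by_id.setdefault(p.patient_id, GenotypePair(patient_id=p.patient_id))
        target.recipient_genotypes.update(p.recipient_genotypes)
    return [by_id[k] for k in sorted(by_id)]


# ---------------------------------------------------------------------------
# population allele-frequency table

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")


def read_popfreq_table(path: str | Path, dialect: str | None = None) -> dict[str, dict[str, float]]:
    """Read per-locus alternative allele frequencies across reference populations.

    Expects one row per locus (``rsid`` column) and one column per
    population label.  Frequencies outside [0, 1] raise with the row.
    """
    df = pd.read_csv(path, sep=_delimiter(path, dialect))
    df.columns = [c.strip() for c in df.columns]
    id_col = next((c for c in df.columns if c.lower() in ("rsid", "snp", "locus")), None)
    if id_col is None:
        raise ValidationError(f"{path}: missing rsid column")
    pops = [c for c in df.columns if c.upper() in POPULATIONS]
    if not pops:
        raise ValidationError(f"{path}: no population columns among {POPULATIONS}")
    out: dict[str, dict[str, float]] = {}
    for i, row in df.iterrows():
        freqs = {}
        for pop in pops:
            f = float(row[pop])
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{path}: row {i + 2}: {pop} frequency {f} outside [0, 1]")
            freqs[pop.upper()] = f
        out[str(row[id_col])] = freqs
    return out


# ---------------------------------------------------------------------------
# outcomes


def outcomes_frame(records: list[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "alt_week1": [r.alt_week1 for r in records],
            "creatinine_week1": [r.creatinine_week1 for r in records],
            "leukocyte_elevated": [r.leukocyte_elevated for r in records],
            "infection": [r.infection for r in records],
            "rejection": [r.rejection for r in records],
        }
    )


def write_outcomes_table(records: list[OutcomeRecord], path: str | Path, dialect: str | None = None) -> None:
    outcomes_frame(records).to_csv(path, sep=_delimiter(path, dialect), index=False, na_rep="NA")


def read_outcomes_table(path: str | Path, dialect: str | None = None) -> list[OutcomeRecord]:
    df = pd.read_csv(path, sep=_delimiter(path, dialect))

    def tri(v):
        if pd.isna(v):
            return None
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return str(v).strip().lower() in ("true", "1", "yes")

    return [
        OutcomeRecord(
            patient_id=str(row.patient_id),
            alt_week1=None if pd.isna(row.alt_week1) else float(row.alt_week1),
            creatinine_week1=None if pd.isna(row.creatinine_week1) else float(row.creatinine_week1),
            leukocyte_elevated=tri(row.leukocyte_elevated),
            infection=tri(row.infection),
            rejection=tri(row.rejection),
        )
        for row in df.itertuples(index=False)
    ]
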