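"""Core domain records shared across the pipeline.

The pipeline moves three kinds of data around: daily therapeutic-drug-
monitoring observations (:class:`PKDayRecord`), per-patient donor/recipient
genotype calls (:class:`GenotypePair`), and early post-operative clinical
outcomes (:class:`OutcomeRecord`).  Records are plain dataclasses; tabular
work downstream happens on pandas frames built from them via the helpers in
:mod:`tacfis.io`.

Genotype calls are unordered allele pairs stored canonically (alleles
sorted, so ``"GA"`` and ``"AG"`` are the same call ``"AG"``).  Missing is
always an explicit ``None``, never an empty string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

VALID_ALLELES = frozenset("ACGT")

#: tokens commonly used for a missing genotype in tabular exports
MISSING_TOKENS = frozenset({"", ".", "./.", ".|.", "NA", "N/A", "NN", "--", "0", "00"})


class ValidationError(ValueError):
    """A record violated a domain invariant."""


def canonical_call(token: str | None) -> str | None:
    """Normalise a genotype token to a canonical two-allele call.

    Alleles are sorted so the call is order-insensitive (``"GA"`` ->
    ``"AG"``); separators ``/`` and ``|`` are accepted.  Recognised missing
    tokens map to ``None``.

    Raises
    ------
    ValidationError
        If the token is not a missing marker and is not a pair of alleles
        from {A, C, G, T}.
    """
    if token is None:
        return None
    tok = token.strip().upper()
    if tok in MISSING_TOKENS:
        return None
    tok = tok.replace("|", "/")
    alleles = tok.split("/") if "/" in tok else list(tok)
    if len(alleles) != 2 or any(a not in VALID_ALLELES for a in alleles):
        raise ValidationError(f"unrecognised genotype token {token!r}")
    return "".join(sorted(alleles))


def is_missing(value: float | None) -> bool:
    """True for ``None`` or NaN."""
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass(frozen=True)
class PKDayRecord:
    """One patient-day of therapeutic drug monitoring.

    ``trough`` is the pre-dose blood concentration in ng/mL, ``daily_dose``
    the total daily tacrolimus dose in mg, ``weight`` body weight in kg.
    ``day`` is the post-operative day, restricted to the first month (1-28).
    ``trough``/``daily_dose`` may be missing (``None``) on days without
    monitoring; weight must always be known and positive.
    """

    patient_id: str
    center_id: str
    day: int
    trough: float | None
    daily_dose: float | None
    weight: float

    def __post_init__(self) -> None:
        if not 1 <= self.day <= 28:
            raise ValidationError(
                f"patient {self.patient_id}: day {self.day} outside [1, 28]"
            )
        if not is_missing(self.trough) and self.trough < 0:
            raise ValidationError(f"patient {self.patient_id}: negative trough")
        if not is_missing(self.daily_dose) and self.daily_dose < 0:
            raise ValidationError(f"patient {self.patient_id}: negative dose")
        if is_missing(self.weight) or self.weight <= 0:
            raise ValidationError(f"patient {self.patient_id}: weight must be > 0")


@dataclass
class GenotypePair:
    """Donor-role and recipient-role genotype calls for one patient.

    In liver transplantation the graft (donor role) and the recipient
    intestine carry different genomes, so every locus exists in two copies
    keyed by role.  Calls are canonical (see :func:`canonical_call`);
    missing calls are explicit ``None`` entries.
    """

    patient_id: str
    donor_genotypes: dict[str, str | None] = field(default_factory=dict)
    recipient_genotypes: dict[str, str | None] = field(default_factory=dict)

    def call(self, role: str, rsid: str) -> str | None:
        table = self.donor_genotypes if role == "donor" else self.recipient_genotypes
        return table.get(rsid)


@dataclass(frozen=True)
class OutcomeRecord:
    """Early post-operative clinical outcomes for one patient.

    Booleans are tri-state (``True``/``False``/``None``) so that the
    denominator of each outcome rate can differ, as happens with
    incomplete follow-up.
    """

    patient_id: str
    alt_week1: float | None = None
    creatinine_week1: float | None = None
    leukocyte_elevated: bool | None = None
    infection: bool | None = None
    rejection: bool | None = None


# classification label domains
FIS_LABELS = ("FE", "IE", "SE")
EIP_LABELS = ("EM", "IM", "PM")

SCHEMES = {
    "clinical-FIS": FIS_LABELS,
    "CPIC-recipient": EIP_LABELS,
    "CPIC-donor": EIP_LABELS,
    "paired-EIP": EIP_LABELS,
    "genetic-EIP": EIP_LABELS,
}


@dataclass(frozen=True)
class ClassLabel:
    """One patient's label under one classification scheme."""

    patient_id: str
    scheme: str
    label: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if self.label not in SCHEMES[self.scheme]:
            raise ValidationError(
                f"label {self.label!r} invalid for scheme {self.scheme!r}"
            )
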