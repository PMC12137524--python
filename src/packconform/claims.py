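"""Prescription records, inclusion/exclusion filtering, pack multiplicity.

The unit of observation is one dispensing event: a patient received some
number of packs of one product.  The study population is restricted to
general-practitioner prescriptions to adults (18+) in the analysis year,
enteral solid preparations only, and — for the three substances recommended
exclusively for urinary tract infections in women — female patients only.

Pack multiplicity distinguishes single packs (the main analysis set) from
partial packs (a non-whole number of packs, e.g. 0.5 or 1.5) and multiple
packs (a whole number >= 2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .formulary import GuidelineRecommendation, PackProduct, recommended_total

__all__ = [
    "FILTER_RULES",
    "ClaimsError",
    "ClaimsSchemaError",
    "ClaimsRecordError",
    "Prescription",
    "FilterReport",
    "classify_multiplicity",
    "apply_inclusion_filters",
    "within_twice_rule",
    "read_claims",
    "write_claims",
]

#: Rule attribution order: a removed record is charged to the first rule it fails.
FILTER_RULES = ("prescriber", "age", "year", "galenic", "sex_female_only")

_CLAIMS_COLUMNS = (
    "rx_id", "patient_id", "sex", "age", "canton", "year",
    "prescriber", "galenic", "product_id", "packs",
)


class ClaimsError(ValueError):
    pass


class ClaimsSchemaError(ClaimsError):
    """The claims file header or structure is unusable."""


@dataclass(frozen=True)
class ClaimsRecordError:
    """A single malformed claims row, kept with its source line number."""

    line_no: int
    message: str


@dataclass(frozen=True)
class Prescription:
    """One dispensing event."""

    rx_id: str
    patient_id: str
    sex: str                # "female" | "male"
    age_years: int
    region: int             # canton 1..26
    year: int
    prescriber: str         # "GP" | "other"
    galenic: str            # "enteral_solid" | "other"
    product: PackProduct
    packs: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ClaimsError(f"{self.rx_id}: invalid sex {self.sex!r}")
        if self.age_years < 0:
            raise ClaimsError(f"{self.rx_id}: negative age")
        if not 1 <= self.region <= 26:
            raise ClaimsError(f"{self.rx_id}: canton must be in 1..26")
        if self.prescriber not in ("GP", "other"):
            raise ClaimsError(f"{self.rx_id}: invalid prescriber {self.prescriber!r}")
        if self.galenic not in ("enteral_solid", "other"):
            raise ClaimsError(f"{self.rx_id}: invalid galenic {self.galenic!r}")
        if not self.packs > 0:
            raise ClaimsError(f"{self.rx_id}: packs must be > 0")

    @property
    def total_mg(self) -> Fraction:
        """Total prescribed dosage: packs x pack total, exact.

        Pack counts are decimal-valued (0.5, 1, 1.5, 2, ...); converting via
        their decimal string representation keeps the product exact.
        """
        return Fraction(str(self.packs)) * self.product.pack_total_mg

    @property
    def multiplicity(self) -> str:
        return classify_multiplicity(self.packs)


def classify_multiplicity(packs: float, tol: float = 1e-6) -> str:
    """Partition a positive pack count into single / partial / multiple.

    Integrality is judged after rounding to ``tol`` so that pack counts read
    from text (e.g. "2.0000001") classify by their intended value.
    """
    if not packs > 0:
        raise ClaimsError(f"packs must be > 0, got {packs}")
    nearest = round(packs)
    if nearest >= 1 and abs(packs - nearest) <= tol:
        return "single" if nearest == 1 else "multiple"
    return "partial"


@dataclass
class FilterReport:
    """Accounting of one filtering pass: every input row is either retained,
    removed under exactly one rule, or counted as unparseable."""

    input_count: int = 0
    unparseable: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in FILTER_RULES}
    )
    retained: int = 0

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def check_conservation(self) -> None:
        if self.input_count != self.retained + self.total_removed + self.unparseable:
            raise ClaimsError(
                f"filter accounting violated: {self.input_count} != "
                f"{self.retained} + {self.total_removed} + {self.unparseable}"
            )

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "unparseable": self.unparseable,
            "removed": dict(self.removed),
            "retained": self.retained,
        }


def _failing_rule(p: Prescription, analysis_year: int) -> str | None:
    if p.prescriber != "GP":
        return "prescriber"
    if p.age_years < 18:
        return "age"
    if p.year != analysis_year:
        return "year"
    if p.galenic != "enteral_solid":
        return "galenic"
    if p.sex == "male" and p.product.substance.female_only:
        return "sex_female_only"
    return None


def apply_inclusion_filters(
    records: Iterable[Prescription | ClaimsRecordError],
    analysis_year: int,
) -> tuple[list[Prescription], FilterReport]:
    """Apply the study's inclusion criteria, attributing each removal to the
    first failing rule in :data:`FILTER_RULES` order.

    Malformed rows (``ClaimsRecordError``) are counted as unparseable, never
    silently dropped.  Idempotent: filtering retained output removes nothing.
    """
    report = FilterReport()
    retained: list[Prescription] = []
    for rec in records:
        report.input_count += 1
        if isinstance(rec, ClaimsRecordError):
            report.unparseable += 1
            continue
        rule = _failing_rule(rec, analysis_year)
        if rule is None:
            retained.append(rec)
            report.retained += 1
        else:
            report.removed[rule] += 1
    report.check_conservation()
    return retained, report


def within_twice_rule(
    p: Prescription,
    recs_for_substance: Sequence[GuidelineRecommendation],
) -> bool:
    """True iff the prescription total does not exceed twice the largest
    recommended total for its substance (boundary inclusive).

    Used to keep partial/multiple-pack prescriptions for acute treatment in
    sub-analyses while excluding likely chronic treatment.
    """
    if not recs_for_substance:
        raise ClaimsError("within_twice_rule needs at least one recommendation")
    for rec in recs_for_substance:
        if rec.substance.atc != p.product.substance.atc:
            raise ClaimsError(
                f"recommendation for {rec.substance.atc} does not match "
                f"prescription substance {p.product.substance.atc}"
            )
    max_upper = max(recommended_total(r).upper_mg for r in recs_for_substance)
    return p.total_mg <= 2 * max_upper


# ---------------------------------------------------------------------------
# Delimiter-separated claims I/O
# ---------------------------------------------------------------------------

def read_claims(
    path: str | Path,
    products: Mapping[str, PackProduct],
    delimiter: str = ",",
) -> list[Prescription | ClaimsRecordError]:
    """Read a claims file, validating every row.

    Required columns: rx_id, patient_id, sex, age, canton, year, prescriber,
    galenic, product_id, packs.  A missing column raises
    :class:`ClaimsSchemaError`; a malformed row becomes a
    :class:`ClaimsRecordError` carrying its line number.
    """
    out: list[Prescription | ClaimsRecordError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ClaimsSchemaError(f"{path}: empty file, no header row")
        missing = [c for c in _CLAIMS_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ClaimsSchemaError(f"{path}: missing required columns {missing}")
        for row in reader:
            line_no = reader.line_num
            try:
                product = products.get(row["product_id"])
                if product is None:
                    raise ClaimsError(f"unknown product_id {row['product_id']!r}")
                out.append(Prescription(
                    rx_id=row["rx_id"],
                    patient_id=row["patient_id"],
                    sex=row["sex"],
                    age_years=int(row["age"]),
                    region=int(row["canton"]),
                    year=int(row["year"]),
                    prescriber=row["prescriber"],
                    galenic=row["galenic"],
                    product=product,
                    packs=float(row["packs"]),
                ))
            except (ClaimsError, ValueError, TypeError, KeyError) as exc:
                out.append(ClaimsRecordError(line_no=line_no, message=str(exc)))
    return out


def write_claims(
    prescriptions: Iterable[Prescription],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write prescriptions in the format :func:`read_claims` consumes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_CLAIMS_COLUMNS)
        for p in prescriptions:
            packs = int(p.packs) if float(p.packs).is_integer() else p.packs
            writer.writerow([
                p.rx_id, p.patient_id, p.sex, p.age_years, p.region, p.year,
                p.prescriber, p.galenic, p.product.product_id, packs,
            ])
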