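"""Guideline and pack-size catalogues with exact dosage arithmetic.

The analysis rests on two small catalogues:

* the Swiss national first- and second-line treatment recommendations for the
  five most common outpatient indications for antibiotics (uncomplicated
  urinary tract infection in women, acute bacterial rhinosinusitis,
  community-acquired pneumonia, acute otitis media, streptococcal
  pharyngitis), each a regimen of unit dose (mg) x doses/day x duration
  (days); and
* the marketed pack sizes of the eleven substances those recommendations
  cover, each a product of unit dose (mg) x units per pack.

All dosages are stored as integer milligrams so that conformity comparisons
are exact; grams are a presentation unit only.  For combination substances
(amoxicillin/clavulanic acid, sulfamethoxazole/trimethoprim) the component
doses are summed into one value; the split is kept as metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ATC_LEVEL5_RE",
    "INDICATIONS",
    "LINES",
    "CatalogueError",
    "SubstanceCode",
    "PackProduct",
    "GuidelineRecommendation",
    "RecommendedTotal",
    "pack_total_dosage",
    "regimen_total",
    "recommended_total",
    "builtin_catalogues",
    "builtin_substances",
    "catalogue_discrepancies",
    "products_by_substance",
    "recommendations_for",
    "load_catalogues",
    "save_catalogues",
]

#: Systemic antibacterials at ATC level 5, e.g. ``J01XE01`` (nitrofurantoin).
ATC_LEVEL5_RE = re.compile(r"^J01[A-Z]{2}\d{2}$")

INDICATIONS = ("UTI", "ABRS", "CAP", "OM", "SP")
LINES = ("first", "second")


class CatalogueError(ValueError):
    """A catalogue entry violates its invariants or the fixture is inconsistent."""


@dataclass(frozen=True)
class SubstanceCode:
    """An antibiotic substance identified by its ATC level-5 code.

    ``female_only`` marks substances recommended exclusively for urinary
    tract infections in women (fosfomycin, nitrofurantoin, norfloxacin);
    prescriptions for men are excluded for these substances.
    """

    atc: str
    name: str
    female_only: bool = False

    def __post_init__(self) -> None:
        if not ATC_LEVEL5_RE.match(self.atc):
            raise CatalogueError(
                f"{self.atc!r} is not a level-5 J01 ATC code"
            )


@dataclass(frozen=True)
class PackProduct:
    """A marketed product: one substance, one unit dose, a fixed unit count.

    ``component_doses_mg`` records the per-component split of combination
    substances (e.g. 625 = 500 amoxicillin + 125 clavulanic acid); it is
    metadata only and never used in arithmetic.
    """

    product_id: str
    substance: SubstanceCode
    unit_dose_mg: int
    units_per_pack: int
    component_doses_mg: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.unit_dose_mg <= 0:
            raise CatalogueError(f"{self.product_id}: unit_dose_mg must be > 0")
        if self.units_per_pack < 1 or int(self.units_per_pack) != self.units_per_pack:
            raise CatalogueError(
                f"{self.product_id}: units_per_pack must be an integer >= 1"
            )
        if self.component_doses_mg and sum(self.component_doses_mg) != self.unit_dose_mg:
            raise CatalogueError(
                f"{self.product_id}: component doses {self.component_doses_mg} "
                f"do not sum to unit dose {self.unit_dose_mg}"
            )

    @property
    def pack_total_mg(self) -> int:
        return self.unit_dose_mg * self.units_per_pack


@dataclass(frozen=True)
class RecommendedTotal:
    """Closed interval [lower_mg, upper_mg] of guideline-conform total dosages."""

    lower_mg: int
    upper_mg: int

    def __post_init__(self) -> None:
        if not (0 < self.lower_mg <= self.upper_mg):
            raise CatalogueError(
                f"invalid recommended-total interval [{self.lower_mg}, {self.upper_mg}]"
            )

    def contains(self, total_mg) -> bool:
        """Inclusive on both sides: the entire range counts as conform."""
        return self.lower_mg <= total_mg <= self.upper_mg

    @property
    def is_point(self) -> bool:
        return self.lower_mg == self.upper_mg


@dataclass(frozen=True)
class GuidelineRecommendation:
    """One substance/indication regimen from the national guidelines.

    Point recommendations have equal min and max in both the frequency and
    the duration field.  ``total_override_mg`` carries the published
    recommended total where it differs from the regimen arithmetic (one such
    case exists in the built-in catalogue); classification uses the
    override, :func:`regimen_total` keeps the arithmetic.
    """

    indication: str
    substance: SubstanceCode
    line: str
    unit_dose_mg: int
    doses_per_day_min: int
    doses_per_day_max: int
    duration_days_min: int
    duration_days_max: int
    total_override_mg: int | None = None

    def __post_init__(self) -> None:
        if self.indication not in INDICATIONS:
            raise CatalogueError(f"unknown indication {self.indication!r}")
        if self.line not in LINES:
            raise CatalogueError(f"unknown line {self.line!r}")
        for name in ("unit_dose_mg", "doses_per_day_min", "doses_per_day_max",
                     "duration_days_min", "duration_days_max"):
            if getattr(self, name) <= 0:
                raise CatalogueError(f"{name} must be strictly positive")
        if self.doses_per_day_min > self.doses_per_day_max:
            raise CatalogueError("doses_per_day_min > doses_per_day_max")
        if self.duration_days_min > self.duration_days_max:
            raise CatalogueError("duration_days_min > duration_days_max")
        if self.total_override_mg is not None and self.total_override_mg <= 0:
            raise CatalogueError("total_override_mg must be strictly positive")

    @property
    def key(self) -> tuple[str, str]:
        return (self.substance.atc, self.indication)


def pack_total_dosage(product: PackProduct) -> int:
    """Total dosage in one pack: unit dose times the number of units, in mg."""
    return product.pack_total_mg


def regimen_total(rec: GuidelineRecommendation) -> RecommendedTotal:
    """Recommended total from the regimen arithmetic alone.

    lower = unit_dose x doses/day(min) x duration(min); upper likewise with
    the maxima, so a "2 or 3 times daily for 5 to 7 days" regimen spans the
    full envelope of the published range.
    """
    lower = rec.unit_dose_mg * rec.doses_per_day_min * rec.duration_days_min
    upper = rec.unit_dose_mg * rec.doses_per_day_max * rec.duration_days_max
    return RecommendedTotal(lower, upper)


def recommended_total(rec: GuidelineRecommendation) -> RecommendedTotal:
    """The interval used for conformity classification.

    Equal to :func:`regimen_total` except where the catalogue carries a
    published total that overrides the arithmetic.
    """
    if rec.total_override_mg is not None:
        return RecommendedTotal(rec.total_override_mg, rec.total_override_mg)
    return regimen_total(rec)


# ---------------------------------------------------------------------------
# Built-in catalogues
# ---------------------------------------------------------------------------

_SUBSTANCE_ROWS: tuple[tuple[str, str, bool], ...] = (
    ("J01CA04", "amoxicillin", False),
    ("J01CR02", "amoxicillin/clavulanic acid", False),
    ("J01FA10", "azithromycin", False),
    ("J01DC02", "cefuroxime", False),
    ("J01FA09", "clarithromycin", False),
    ("J01AA02", "doxycycline", False),
    ("J01XX01", "fosfomycin", True),
    ("J01XE01", "nitrofurantoin", True),
    ("J01MA06", "norfloxacin", True),
    ("J01CE02", "penicillin V", False),
    ("J01EE01", "sulfamethoxazole/trimethoprim", False),
)

# (indication, atc, line, unit_dose_mg, dpd_min, dpd_max, dur_min, dur_max, override_mg)
_RECOMMENDATION_ROWS: tuple[tuple, ...] = (
    ("UTI", "J01XE01", "first", 100, 2, 2, 5, 5, None),
    ("UTI", "J01EE01", "first", 960, 2, 2, 3, 3, None),
    ("UTI", "J01XX01", "second", 3000, 1, 1, 1, 1, None),
    ("UTI", "J01MA06", "second", 400, 2, 2, 3, 3, None),
    ("UTI", "J01DC02", "second", 500, 2, 2, 3, 3, None),
    # Published recommended total (4.5 g) differs from the regimen arithmetic
    # (5.625 g); the published value is authoritative for classification.
    ("UTI", "J01CR02", "second", 625, 3, 3, 3, 3, 4500),
    ("ABRS", "J01CA04", "first", 1000, 2, 3, 5, 7, None),
    ("ABRS", "J01CR02", "first", 1000, 2, 2, 5, 7, None),
    ("ABRS", "J01DC02", "second", 500, 2, 2, 5, 7, None),
    ("ABRS", "J01AA02", "second", 100, 2, 2, 5, 7, None),
    ("ABRS", "J01FA09", "second", 500, 2, 2, 5, 5, None),
    ("CAP", "J01CA04", "first", 1000, 3, 3, 5, 5, None),
    ("CAP", "J01CR02", "first", 1000, 3, 3, 5, 5, None),
    ("CAP", "J01AA02", "second", 100, 2, 2, 5, 5, None),
    ("CAP", "J01FA10", "second", 500, 1, 1, 3, 3, None),
    ("CAP", "J01EE01", "second", 960, 2, 2, 5, 5, None),
    ("OM", "J01CA04", "first", 1000, 3, 3, 5, 5, None),
    ("OM", "J01CR02", "second", 1000, 3, 3, 5, 5, None),
    ("OM", "J01DC02", "second", 500, 2, 2, 5, 5, None),
    ("SP", "J01CE02", "first", 625, 2, 2, 6, 6, None),
    ("SP", "J01CA04", "first", 1000, 2, 2, 6, 6, None),
    ("SP", "J01DC02", "second", 500, 2, 2, 6, 6, None),
    ("SP", "J01FA09", "second", 500, 2, 2, 6, 6, None),
)

# (product_id, atc, unit_dose_mg, units_per_pack, pack_total_mg, components)
# pack_total_mg is stored redundantly as a fixture-integrity check against the
# published per-substance pack totals.
_PRODUCT_ROWS: tuple[tuple, ...] = (
    ("AMX1000x3", "J01CA04", 1000, 3, 3000, ()),
    ("AMX1000x6", "J01CA04", 1000, 6, 6000, ()),
    ("AMX1000x10", "J01CA04", 1000, 10, 10000, ()),
    ("AMX1000x14", "J01CA04", 1000, 14, 14000, ()),
    ("AMX1000x15", "J01CA04", 1000, 15, 15000, ()),
    ("AMX1000x20", "J01CA04", 1000, 20, 20000, ()),
    ("AMC625x10", "J01CR02", 625, 10, 6250, (500, 125)),
    ("AMC1000x12", "J01CR02", 1000, 12, 12000, (875, 125)),
    ("AMC625x20", "J01CR02", 625, 20, 12500, (500, 125)),
    ("AMC1000x20", "J01CR02", 1000, 20, 20000, (875, 125)),
    ("AZM300x1", "J01FA10", 300, 1, 300, ()),
    ("AZM300x3", "J01FA10", 300, 3, 900, ()),
    ("AZM500x2", "J01FA10", 500, 2, 1000, ()),
    ("AZM500x3", "J01FA10", 500, 3, 1500, ()),
    ("CXM500x7", "J01DC02", 500, 7, 3500, ()),
    ("CXM500x14", "J01DC02", 500, 14, 7000, ()),
    ("CLR500x7", "J01FA09", 500, 7, 3500, ()),
    ("CLR500x10", "J01FA09", 500, 10, 5000, ()),
    ("CLR500x14", "J01FA09", 500, 14, 7000, ()),
    ("CLR500x20", "J01FA09", 500, 20, 10000, ()),
    ("CLR500x30", "J01FA09", 500, 30, 15000, ()),
    ("DOX100x8", "J01AA02", 100, 8, 800, ()),
    ("DOX100x10", "J01AA02", 100, 10, 1000, ()),
    ("DOX112x10", "J01AA02", 112, 10, 1120, ()),
    ("DOX100x14", "J01AA02", 100, 14, 1400, ()),
    ("DOX100x16", "J01AA02", 100, 16, 1600, ()),
    ("DOX100x20", "J01AA02", 100, 20, 2000, ()),
    ("DOX112x20", "J01AA02", 112, 20, 2240, ()),
    ("DOX100x25", "J01AA02", 100, 25, 2500, ()),
    ("DOX100x32", "J01AA02", 100, 32, 3200, ()),
    ("FOF3000x1", "J01XX01", 3000, 1, 3000, ()),
    ("NIT100x20", "J01XE01", 100, 20, 2000, ()),
    ("NIT100x30", "J01XE01", 100, 30, 3000, ()),
    ("NIT100x50", "J01XE01", 100, 50, 5000, ()),
    ("NOR400x6", "J01MA06", 400, 6, 2400, ()),
    ("NOR400x14", "J01MA06", 400, 14, 5600, ()),
    ("NOR400x42", "J01MA06", 400, 42, 16800, ()),
    ("SXT960x10", "J01EE01", 960, 10, 9600, (800, 160)),
    ("SXT960x20", "J01EE01", 960, 20, 19200, (800, 160)),
    ("SXT960x50", "J01EE01", 960, 50, 48000, (800, 160)),
    ("PEN625x12", "J01CE02", 625, 12, 7500, ()),
    ("PEN625x18", "J01CE02", 625, 18, 11250, ()),
    ("PEN625x24", "J01CE02", 625, 24, 15000, ()),
    ("PEN625x36", "J01CE02", 625, 36, 22500, ()),
)


def builtin_substances() -> dict[str, SubstanceCode]:
    """The eleven analysed substances keyed by ATC code."""
    return {
        atc: SubstanceCode(atc=atc, name=name, female_only=fem)
        for atc, name, fem in _SUBSTANCE_ROWS
    }


def builtin_catalogues() -> tuple[list[GuidelineRecommendation], list[PackProduct]]:
    """The built-in guideline (23 regimens) and pack-size (41 products) fixtures.

    Raises :class:`CatalogueError` if any stored pack total disagrees with
    unit_dose x units, or if a female-only substance appears outside the
    UTI-only list.
    """
    substances = builtin_substances()
    recs = [
        GuidelineRecommendation(
            indication=ind, substance=substances[atc], line=line,
            unit_dose_mg=dose, doses_per_day_min=dmin, doses_per_day_max=dmax,
            duration_days_min=tmin, duration_days_max=tmax,
            total_override_mg=override,
        )
        for ind, atc, line, dose, dmin, dmax, tmin, tmax, override in _RECOMMENDATION_ROWS
    ]
    products = []
    for pid, atc, dose, units, total, comps in _PRODUCT_ROWS:
        prod = PackProduct(
            product_id=pid, substance=substances[atc],
            unit_dose_mg=dose, units_per_pack=units,
            component_doses_mg=tuple(comps),
        )
        if prod.pack_total_mg != total:
            raise CatalogueError(
                f"fixture integrity: {pid} stores total {total} mg but "
                f"{dose} x {units} = {prod.pack_total_mg} mg"
            )
        products.append(prod)
    # female-only substances must be recommended only for UTI
    for rec in recs:
        if rec.substance.female_only and rec.indication != "UTI":
            raise CatalogueError(
                f"{rec.substance.atc} is female-only but recommended for {rec.indication}"
            )
    return recs, products


def catalogue_discrepancies(
    recs: Iterable[GuidelineRecommendation],
) -> list[dict]:
    """Recommendations whose published total overrides the regimen arithmetic.

    Returned as a validation report, one dict per conflicting entry.
    """
    out = []
    for rec in recs:
        if rec.total_override_mg is None:
            continue
        arith = regimen_total(rec)
        if (arith.lower_mg, arith.upper_mg) != (rec.total_override_mg, rec.total_override_mg):
            out.append({
                "substance": rec.substance.atc,
                "substance_name": rec.substance.name,
                "indication": rec.indication,
                "line": rec.line,
                "regimen_total_mg": [arith.lower_mg, arith.upper_mg],
                "published_total_mg": rec.total_override_mg,
            })
    return out


def products_by_substance(
    products: Iterable[PackProduct],
) -> dict[str, list[PackProduct]]:
    out: dict[str, list[PackProduct]] = {}
    for p in products:
        out.setdefault(p.substance.atc, []).append(p)
    return out


def recommendations_for(
    recs: Iterable[GuidelineRecommendation], atc: str
) -> list[GuidelineRecommendation]:
    return [r for r in recs if r.substance.atc == atc]


# ---------------------------------------------------------------------------
# Catalogue config-file round-trip
# ---------------------------------------------------------------------------

def save_catalogues(
    recs: Sequence[GuidelineRecommendation],
    products: Sequence[PackProduct],
    path: str | Path,
) -> None:
    """Write both catalogues to one YAML file (lossless round-trip)."""
    substances: dict[str, SubstanceCode] = {}
    for rec in recs:
        substances[rec.substance.atc] = rec.substance
    for prod in products:
        substances[prod.substance.atc] = prod.substance
    doc = {
        "substances": [
            {"atc": s.atc, "name": s.name, "female_only": s.female_only}
            for s in sorted(substances.values(), key=lambda s: s.atc)
        ],
        "recommendations": [
            {
                "indication": r.indication,
                "substance": r.substance.atc,
                "line": r.line,
                "unit_dose_mg": r.unit_dose_mg,
                "doses_per_day": [r.doses_per_day_min, r.doses_per_day_max],
                "duration_days": [r.duration_days_min, r.duration_days_max],
                "total_override_mg": r.total_override_mg,
            }
            for r in recs
        ],
        "products": [
            {
                "product_id": p.product_id,
                "substance": p.substance.atc,
                "unit_dose_mg": p.unit_dose_mg,
                "units_per_pack": p.units_per_pack,
                "pack_total_mg": p.pack_total_mg,
                "component_doses_mg": list(p.component_doses_mg),
            }
            for p in products
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_catalogues(
    path: str | Path,
) -> tuple[list[GuidelineRecommendation], list[PackProduct]]:
    """Read catalogues written by :func:`save_catalogues` (with integrity check)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        substances = {
            row["atc"]: SubstanceCode(
                atc=row["atc"], name=row["name"],
                female_only=bool(row.get("female_only", False)),
            )
            for row in doc["substances"]
        }
        recs = []
        for row in doc["recommendations"]:
            dpd = row["doses_per_day"]
            dur = row["duration_days"]
            dpd = [dpd, dpd] if isinstance(dpd, int) else list(dpd)
            dur = [dur, dur] if isinstance(dur, int) else list(dur)
            recs.append(GuidelineRecommendation(
                indication=row["indication"],
                substance=substances[row["substance"]],
                line=row["line"],
                unit_dose_mg=int(row["unit_dose_mg"]),
                doses_per_day_min=int(dpd[0]), doses_per_day_max=int(dpd[1]),
                duration_days_min=int(dur[0]), duration_days_max=int(dur[1]),
                total_override_mg=row.get("total_override_mg"),
            ))
        products = []
        for row in doc["products"]:
            prod = PackProduct(
                product_id=row["product_id"],
                substance=substances[row["substance"]],
                unit_dose_mg=int(row["unit_dose_mg"]),
                units_per_pack=int(row["units_per_pack"]),
                component_doses_mg=tuple(row.get("component_doses_mg") or ()),
            )
            stored = row.get("pack_total_mg")
            if stored is not None and int(stored) != prod.pack_total_mg:
                raise CatalogueError(
                    f"{prod.product_id}: stored pack total {stored} mg disagrees "
                    f"with unit_dose x units = {prod.pack_total_mg} mg"
                )
            products.append(prod)
    except KeyError as exc:
        raise CatalogueError(f"catalogue file {path}: missing field {exc}") from exc
    return recs, products
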