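"""Conformity classification of prescribed totals against guideline totals.

A prescribed total dosage is *potentially conform* for an indication when it
lies inside the recommended-total interval (inclusive on both sides — where
a guideline recommends a treatment range, the entire range is conform).
Below the interval it is a potential underprescription, above it a potential
overprescription; the surplus is expressed in units (tablets) of the
prescribed product.

Because claims data carry no diagnosis, a cross-guideline variant classifies
a total as non-conform only when it matches none of the substance's
recommendations, and then measures the surplus against the *closest*
recommended total (interval endpoints included) — a conservative estimate of
overprescription.  Equidistant ties resolve toward the larger reference,
which classifies the prescription as under rather than over.

All arithmetic is exact: totals are integers or exact fractions of mg, and
``surplus_units * unit_dose_mg + reference_mg == total_mg`` holds identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .claims import Prescription
from .formulary import (
    GuidelineRecommendation,
    PackProduct,
    RecommendedTotal,
    products_by_substance,
    recommended_total,
)

__all__ = [
    "ConformityCall",
    "CombinationSummary",
    "NetUnits",
    "classify_against",
    "cross_guideline_call",
    "net_units",
    "combination_summary",
    "conform_pack_totals",
    "zero_conform_combinations",
    "write_summary_table",
    "write_calls_long",
]


def _as_mg(x) -> Fraction:
    """Exact mg value from int, Fraction, or decimal-valued float."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class ConformityCall:
    """Classification of one total dosage against a reference.

    ``surplus_units`` is the signed unit (tablet) surplus relative to the
    reference: zero for conform, positive for over, negative for under.
    """

    status: str                  # "conform" | "under" | "over"
    reference_mg: Fraction
    surplus_units: Fraction
    basis: str                   # "per_indication" | "cross_guideline"
    unit_dose_mg: int

    def __post_init__(self) -> None:
        if self.status not in ("conform", "under", "over"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "conform" and self.surplus_units != 0:
            raise ValueError("conform call must have zero surplus")
        if self.status == "over" and not self.surplus_units > 0:
            raise ValueError("over call must have positive surplus")
        if self.status == "under" and not self.surplus_units < 0:
            raise ValueError("under call must have negative surplus")

    @property
    def total_mg(self) -> Fraction:
        return self.reference_mg + self.surplus_units * self.unit_dose_mg


def classify_against(
    total_mg,
    rec_total: RecommendedTotal,
    unit_dose_mg: int,
    basis: str = "per_indication",
) -> ConformityCall:
    """Classify one total against one recommended-total interval.

    Conform totals take themselves as reference (surplus 0); under totals
    are referenced to the lower bound, over totals to the upper bound.
    """
    total = _as_mg(total_mg)
    if not total > 0:
        raise ValueError(f"total_mg must be > 0, got {total_mg}")
    if rec_total.contains(total):
        return ConformityCall("conform", total, Fraction(0), basis, unit_dose_mg)
    if total < rec_total.lower_mg:
        ref = Fraction(rec_total.lower_mg)
    else:
        ref = Fraction(rec_total.upper_mg)
    surplus = (total - ref) / unit_dose_mg
    status = "over" if surplus > 0 else "under"
    return ConformityCall(status, ref, surplus, basis, unit_dose_mg)


def cross_guideline_call(
    total_mg,
    recs: Sequence[GuidelineRecommendation],
    unit_dose_mg: int,
) -> ConformityCall:
    """Classify a total against all of one substance's recommendations.

    Conform when the total lies inside at least one recommended interval.
    Otherwise the reference is the interval endpoint (lower and upper limits
    of every recommendation considered) closest to the total; at equal
    distance the larger endpoint wins, yielding an under call.
    """
    if not recs:
        raise ValueError("cross_guideline_call needs at least one recommendation")
    atcs = {r.substance.atc for r in recs}
    if len(atcs) != 1:
        raise ValueError(f"recommendations span several substances: {sorted(atcs)}")
    total = _as_mg(total_mg)
    if not total > 0:
        raise ValueError(f"total_mg must be > 0, got {total_mg}")
    intervals = [recommended_total(r) for r in recs]
    if any(iv.contains(total) for iv in intervals):
        return ConformityCall(
            "conform", total, Fraction(0), "cross_guideline", unit_dose_mg
        )
    endpoints = {iv.lower_mg for iv in intervals} | {iv.upper_mg for iv in intervals}
    # min distance; ties toward the larger endpoint (the conservative choice:
    # the call becomes "under" rather than "over")
    ref = max(
        (e for e in endpoints),
        key=lambda e: (-abs(total - e), e),
    )
    surplus = (total - Fraction(ref)) / unit_dose_mg
    status = "over" if surplus > 0 else "under"
    return ConformityCall(status, Fraction(ref), surplus, "cross_guideline", unit_dose_mg)


@dataclass(frozen=True)
class NetUnits:
    """Totals of over- and underprescribed units and their net balance."""

    over_units: Fraction
    under_units: Fraction

    @property
    def net(self) -> Fraction:
        return self.over_units - self.under_units


def net_units(
    calls: Iterable[ConformityCall],
    weights: Iterable[float] | None = None,
) -> NetUnits:
    """Sum positive and negative unit surpluses over a set of calls.

    ``weights`` (e.g. stratum extrapolation weights, one per call) scale each
    call's surplus; omitted weights count each call once.
    """
    over = Fraction(0)
    under = Fraction(0)
    if weights is None:
        pairs = ((c, 1) for c in calls)
    else:
        pairs = zip(calls, weights, strict=True)
    for call, w in pairs:
        w = _as_mg(w)
        if call.surplus_units > 0:
            over += call.surplus_units * w
        elif call.surplus_units < 0:
            under += -call.surplus_units * w
    return NetUnits(over_units=over, under_units=under)


@dataclass
class CombinationSummary:
    """Weighted conformity counts for one substance/indication combination.

    Percentages are relative to the substance's full classified prescription
    pool, so a substance recommended for several indications reports each
    indication's cell from the same denominator.
    """

    substance_atc: str
    substance_name: str
    indication: str
    line: str
    rec_lower_mg: int
    rec_upper_mg: int
    n_total: float
    n_conform: float
    n_under: float
    n_over: float

    def _pct(self, x: float) -> float | None:
        return None if self.n_total == 0 else 100.0 * x / self.n_total

    @property
    def pct_conform(self) -> float | None:
        return self._pct(self.n_conform)

    @property
    def pct_under(self) -> float | None:
        return self._pct(self.n_under)

    @property
    def pct_over(self) -> float | None:
        return self._pct(self.n_over)


def combination_summary(
    prescriptions: Sequence[Prescription],
    rec: GuidelineRecommendation,
    weight_of: Callable[[Prescription], float] | None = None,
    classify_total: bool = False,
) -> CombinationSummary:
    """Classify a substance's prescriptions against one recommendation.

    By default each prescription's *pack* total is classified (the single-pack
    main analysis); with ``classify_total`` the full prescribed total
    (packs x pack total) is used, for the partial/multiple-pack sub-analysis.
    ``weight_of`` supplies the stratum extrapolation weight (default 1).
    """
    interval = recommended_total(rec)
    n_total = n_conform = n_under = n_over = 0.0
    for p in prescriptions:
        if p.product.substance.atc != rec.substance.atc:
            raise ValueError(
                f"prescription {p.rx_id} is {p.product.substance.atc}, "
                f"recommendation is for {rec.substance.atc}"
            )
        total = p.total_mg if classify_total else p.product.pack_total_mg
        call = classify_against(total, interval, p.product.unit_dose_mg)
        w = 1.0 if weight_of is None else weight_of(p)
        n_total += w
        if call.status == "conform":
            n_conform += w
        elif call.status == "under":
            n_under += w
        else:
            n_over += w
    return CombinationSummary(
        substance_atc=rec.substance.atc,
        substance_name=rec.substance.name,
        indication=rec.indication,
        line=rec.line,
        rec_lower_mg=interval.lower_mg,
        rec_upper_mg=interval.upper_mg,
        n_total=n_total,
        n_conform=n_conform,
        n_under=n_under,
        n_over=n_over,
    )


def conform_pack_totals(
    rec: GuidelineRecommendation,
    products: Iterable[PackProduct],
) -> set[int]:
    """Pack totals of the substance's products that lie inside the interval."""
    interval = recommended_total(rec)
    return {
        p.pack_total_mg
        for p in products
        if p.substance.atc == rec.substance.atc and interval.contains(p.pack_total_mg)
    }


def zero_conform_combinations(
    recs: Sequence[GuidelineRecommendation],
    products: Sequence[PackProduct],
) -> tuple[int, int]:
    """Count combinations with no conform pack at all vs. at least one.

    Returns ``(count_zero, count_some)``; the two sum to the number of
    recommendations.
    """
    count_zero = 0
    for rec in recs:
        if not conform_pack_totals(rec, products):
            count_zero += 1
    return count_zero, len(recs) - count_zero


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def _fmt_g(mg: int | Fraction) -> str:
    """Milligrams rendered as grams with up to 2 decimals."""
    g = float(mg) / 1000.0
    return f"{g:.2f}".rstrip("0").rstrip(".")


def write_summary_table(
    summaries: Sequence[CombinationSummary],
    products: Sequence[PackProduct],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write the combination-summary matrix (one row per substance/indication).

    Columns mirror the published layout: recommended total and pack totals in
    grams, weighted n and percentage for conform / under / over.
    """
    packs_by_sub = products_by_substance(products)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([
            "substance_atc", "substance", "indication", "line",
            "recommended_total_g", "pack_totals_g",
            "n_total", "n_conform", "pct_conform",
            "n_under", "pct_under", "n_over", "pct_over",
        ])
        for s in summaries:
            if s.rec_lower_mg == s.rec_upper_mg:
                rec_g = _fmt_g(s.rec_lower_mg)
            else:
                rec_g = f"{_fmt_g(s.rec_lower_mg)} to {_fmt_g(s.rec_upper_mg)}"
            packs = sorted({
                p.pack_total_mg for p in packs_by_sub.get(s.substance_atc, [])
            })
            pack_g = "; ".join(_fmt_g(t) for t in packs)
            writer.writerow([
                s.substance_atc, s.substance_name, s.indication, s.line,
                rec_g, pack_g,
                f"{s.n_total:.2f}",
                f"{s.n_conform:.2f}",
                "" if s.pct_conform is None else f"{s.pct_conform:.2f}",
                f"{s.n_under:.2f}",
                "" if s.pct_under is None else f"{s.pct_under:.2f}",
                f"{s.n_over:.2f}",
                "" if s.pct_over is None else f"{s.pct_over:.2f}",
            ])


def write_calls_long(
    rows: Sequence[tuple[Prescription, GuidelineRecommendation | None, ConformityCall, float]],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Long-format per-prescription call export (density-plot source data).

    Each row: (prescription, recommendation or None for cross-guideline
    calls, call, weight).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([
            "rx_id", "substance_atc", "substance", "indication", "line",
            "basis", "total_g", "status", "reference_g", "surplus_units", "weight",
        ])
        for p, rec, call, w in rows:
            writer.writerow([
                p.rx_id,
                p.product.substance.atc,
                p.product.substance.name,
                "" if rec is None else rec.indication,
                "" if rec is None else rec.line,
                call.basis,
                f"{float(call.total_mg) / 1000.0:.4f}",
                call.status,
                f"{float(call.reference_mg) / 1000.0:.4f}",
                f"{float(call.surplus_units):.4f}",
                f"{w:.6f}",
            ])
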