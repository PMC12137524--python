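"""Stratified extrapolation of insurer claims to national population scale.

Claims from one insurer cover only a fraction of the population, and that
fraction varies with geography, sex and age.  Counts are therefore
post-stratified: the population is cut into canton (26) x sex (2) x
age class (16) x year cells — 832 strata per year — and every prescription
is weighted by census_count / insured_count of its cell.  Weighted counts
then estimate what the whole population would have generated.

The 16 age-class boundaries are configuration, not code: the default is a
band for 18-year-olds, a 19-25 band, then 5-year bands up to an open 91+
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import pandas as pd

from .claims import Prescription

__all__ = [
    "DEFAULT_AGE_EDGES",
    "AgeBins",
    "Stratum",
    "StratumWeight",
    "WeightTable",
    "StratumMismatchError",
    "WeightlessStratumError",
    "compute_weights",
    "weighted_aggregate",
    "AggregateResult",
    "read_count_table",
    "write_count_table",
]

#: Lower edges of the 16 default adult age classes; the last class is open.
DEFAULT_AGE_EDGES = (18, 19, 26, 31, 36, 41, 46, 51, 56, 61, 66, 71, 76, 81, 86, 91)

_COUNT_COLUMNS = ("canton", "sex", "age_class", "year", "count")


class StratumMismatchError(ValueError):
    """Census and insured tables do not cover the same stratum grid."""


class WeightlessStratumError(ValueError):
    """A prescription fell into a stratum with no defined weight."""


@dataclass(frozen=True)
class AgeBins:
    """Monotone lower edges defining the age classes (first edge = adult age)."""

    edges: tuple[int, ...] = DEFAULT_AGE_EDGES

    def __post_init__(self) -> None:
        if len(self.edges) < 1 or list(self.edges) != sorted(set(self.edges)):
            raise ValueError("age edges must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.edges)

    def class_of(self, age_years: int) -> int:
        """1-based age class; ages below the first edge raise."""
        if age_years < self.edges[0]:
            raise ValueError(f"age {age_years} below the first age-class edge")
        for i in range(len(self.edges) - 1, -1, -1):
            if age_years >= self.edges[i]:
                return i + 1
        raise AssertionError("unreachable")

    def age_range(self, age_class: int) -> tuple[int, int]:
        """Closed [low, high] age range of a class; the top class caps at 100."""
        low = self.edges[age_class - 1]
        high = self.edges[age_class] - 1 if age_class < self.n_classes else 100
        return low, high


class Stratum(NamedTuple):
    region: int
    sex: str
    age_class: int
    year: int


@dataclass(frozen=True)
class StratumWeight:
    """census/insured ratio for one cell; undefined when nobody is insured."""

    stratum: Stratum
    census_count: int
    insured_count: int

    def __post_init__(self) -> None:
        if self.census_count < 0 or self.insured_count < 0:
            raise ValueError("stratum counts must be non-negative")

    @property
    def weight(self) -> float | None:
        if self.insured_count == 0:
            return None
        return self.census_count / self.insured_count


@dataclass
class WeightTable:
    """All stratum weights for an analysis, plus the age-class definition."""

    weights: dict[Stratum, StratumWeight]
    age_bins: AgeBins = field(default_factory=AgeBins)

    @property
    def undefined_strata(self) -> list[Stratum]:
        """Strata with insured_count == 0 — reported, never silently dropped."""
        return sorted(s for s, w in self.weights.items() if w.weight is None)

    def stratum_of(self, p: Prescription) -> Stratum:
        return Stratum(
            region=p.region,
            sex=p.sex,
            age_class=self.age_bins.class_of(p.age_years),
            year=p.year,
        )

    def weight_of(
        self,
        p: Prescription,
        policy: Literal["error", "exclude"] = "error",
    ) -> float | None:
        """Weight of a prescription's stratum.

        Unknown or weightless strata raise under the default policy; under
        ``policy="exclude"`` they return None for the caller to report.
        """
        stratum = self.stratum_of(p)
        sw = self.weights.get(stratum)
        w = None if sw is None else sw.weight
        if w is None and policy == "error":
            raise WeightlessStratumError(
                f"prescription {p.rx_id}: no defined weight for stratum {stratum}"
            )
        return w


def _table_to_counts(df: pd.DataFrame, label: str) -> dict[Stratum, int]:
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise StratumMismatchError(f"{label} table missing columns {missing}")
    counts: dict[Stratum, int] = {}
    for row in df.itertuples(index=False):
        stratum = Stratum(
            int(row.canton), str(row.sex), int(row.age_class), int(row.year)
        )
        if stratum in counts:
            raise StratumMismatchError(f"{label} table lists stratum {stratum} twice")
        counts[stratum] = int(row.count)
    return counts


def compute_weights(
    census: pd.DataFrame,
    insured: pd.DataFrame,
    age_bins: AgeBins | None = None,
) -> WeightTable:
    """Build the stratum weight table from census and insured counts.

    Both tables must be keyed by exactly the same strata (canton, sex,
    age_class, year); any asymmetric cell raises
    :class:`StratumMismatchError` listing the offenders.
    """
    census_counts = _table_to_counts(census, "census")
    insured_counts = _table_to_counts(insured, "insured")
    only_census = sorted(set(census_counts) - set(insured_counts))
    only_insured = sorted(set(insured_counts) - set(census_counts))
    if only_census or only_insured:
        raise StratumMismatchError(
            f"stratum grids differ: {len(only_census)} strata only in census "
            f"(first: {only_census[:3]}), {len(only_insured)} only in insured "
            f"(first: {only_insured[:3]})"
        )
    weights = {
        s: StratumWeight(stratum=s, census_count=census_counts[s],
                         insured_count=insured_counts[s])
        for s in census_counts
    }
    return WeightTable(weights=weights, age_bins=age_bins or AgeBins())


class AggregateResult(NamedTuple):
    value: float
    n_used: int
    n_excluded: int


def weighted_aggregate(
    prescriptions: Iterable[Prescription],
    table: WeightTable,
    statistic: Literal["count", "mean_age", "proportion_female", "patient_count"],
    policy: Literal["error", "exclude"] = "error",
) -> AggregateResult:
    """Weighted summary over a prescription stream.

    * ``count`` — sum of stratum weights (extrapolated prescription count);
    * ``mean_age`` — weight-weighted mean age;
    * ``proportion_female`` — weighted share of prescriptions to women;
    * ``patient_count`` — each distinct patient counted once at their weight.
    """
    wsum = 0.0
    wage = 0.0
    wfem = 0.0
    n_used = 0
    n_excluded = 0
    patients: dict[str, float] = {}
    for p in prescriptions:
        w = table.weight_of(p, policy=policy)
        if w is None:
            n_excluded += 1
            continue
        n_used += 1
        wsum += w
        wage += w * p.age_years
        if p.sex == "female":
            wfem += w
        patients.setdefault(p.patient_id, w)
    if statistic == "count":
        value = wsum
    elif statistic == "mean_age":
        value = wage / wsum if wsum else float("nan")
    elif statistic == "proportion_female":
        value = wfem / wsum if wsum else float("nan")
    elif statistic == "patient_count":
        value = sum(patients.values())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return AggregateResult(value=value, n_used=n_used, n_excluded=n_excluded)


def read_count_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise StratumMismatchError(f"{path}: missing columns {missing}")
    return df


def write_count_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False, columns=list(_COUNT_COLUMNS))
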