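"""End-to-end pipeline: read inputs, filter, weight, classify, report.

Three analysis modes mirror the study design:

* ``primary_single_pack`` — only single-pack prescriptions; each pack's
  total is classified against the recommendation;
* ``subanalysis_with_partials`` — single packs plus partial/multiple-pack
  prescriptions whose prescribed total does not exceed twice the largest
  recommended total for the substance (a guard against chronic treatment);
  the full prescribed total is classified;
* ``explorative_cross_guideline`` — single-pack stream, but classification
  is against the closest of all of the substance's recommendations.

Every run emits the filter report, a prescription-pattern table, the
combination-summary matrix, cross-guideline non-conformity statistics with
over/underprescribed unit totals, a per-prescription call export, and a
machine-readable run log.  Outputs are deterministic: rerunning an identical
configuration reproduces every file byte for byte.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .claims import (
    FilterReport,
    Prescription,
    apply_inclusion_filters,
    read_claims,
    within_twice_rule,
)
from .conformity import (
    CombinationSummary,
    combination_summary,
    cross_guideline_call,
    net_units,
    write_calls_long,
    write_summary_table,
    zero_conform_combinations,
)
from .extrapolation import (
    AgeBins,
    WeightTable,
    compute_weights,
    read_count_table,
)
from .formulary import (
    builtin_catalogues,
    load_catalogues,
    recommendations_for,
)

__all__ = ["MODES", "PipelineError", "RunConfig", "RunResult", "run_pipeline"]

MODES = (
    "primary_single_pack",
    "subanalysis_with_partials",
    "explorative_cross_guideline",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    claims_path: str | Path
    census_path: str | Path
    insured_path: str | Path
    out_dir: str | Path
    catalogue_path: str | Path | None = None
    analysis_year: int = 2022
    mode: str = "primary_single_pack"
    weightless_policy: str = "error"
    delimiter: str = ","
    age_bin_edges: tuple[int, ...] | None = None
    seed: int | None = None  # echoed into the run log only

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise PipelineError(f"[config] unknown mode {self.mode!r}; choose from {MODES}")
        if self.weightless_policy not in ("error", "exclude"):
            raise PipelineError("[config] weightless_policy must be 'error' or 'exclude'")
        for name in ("claims_path", "census_path", "insured_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise PipelineError(f"[config] {name} does not exist: {p}")
        if self.catalogue_path is not None and not Path(self.catalogue_path).exists():
            raise PipelineError(f"[config] catalogue_path does not exist: {self.catalogue_path}")

    def echo(self) -> dict:
        return {
            "claims_path": str(self.claims_path),
            "census_path": str(self.census_path),
            "insured_path": str(self.insured_path),
            "catalogue_path": None if self.catalogue_path is None else str(self.catalogue_path),
            "out_dir": str(self.out_dir),
            "analysis_year": self.analysis_year,
            "mode": self.mode,
            "weightless_policy": self.weightless_policy,
            "delimiter": self.delimiter,
            "age_bin_edges": None if self.age_bin_edges is None else list(self.age_bin_edges),
            "seed": self.seed,
        }


@dataclass
class RunResult:
    filter_report: FilterReport
    summaries: list[CombinationSummary]
    zero_conform: tuple[int, int]
    cross_stats: dict
    patterns: pd.DataFrame
    paths: dict[str, Path]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage attribution."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _patterns_table(
    prescriptions: Sequence[Prescription],
    weight_of,
) -> pd.DataFrame:
    """Weighted prescription counts and multiplicity shares by substance and
    product (the prescription-pattern figure as a table)."""
    rows = []
    for p in prescriptions:
        w = weight_of(p)
        if w is None:
            continue
        rows.append((
            p.product.substance.atc, p.product.substance.name,
            p.product.product_id, p.multiplicity, w,
        ))
    df = pd.DataFrame(
        rows, columns=["atc", "substance", "product_id", "multiplicity", "w"]
    )
    out = []
    total = df["w"].sum() if len(df) else 0.0
    for level, keys in (("substance", ["atc", "substance"]),
                        ("product", ["atc", "substance", "product_id"])):
        if not len(df):
            continue
        grouped = df.groupby(keys, as_index=False)
        for key_vals, g in grouped:
            key_vals = (key_vals,) if not isinstance(key_vals, tuple) else key_vals
            rec = dict(zip(keys, key_vals))
            wsum = g["w"].sum()
            by_mult = g.groupby("multiplicity")["w"].sum()
            out.append({
                "level": level,
                "atc": rec["atc"],
                "substance": rec["substance"],
                "product_id": rec.get("product_id", ""),
                "weighted_n": round(wsum, 2),
                "pct_of_total": round(100.0 * wsum / total, 2) if total else None,
                "pct_single": round(100.0 * by_mult.get("single", 0.0) / wsum, 2),
                "pct_partial": round(100.0 * by_mult.get("partial", 0.0) / wsum, 2),
                "pct_multiple": round(100.0 * by_mult.get("multiple", 0.0) / wsum, 2),
            })
    cols = ["level", "atc", "substance", "product_id", "weighted_n",
            "pct_of_total", "pct_single", "pct_partial", "pct_multiple"]
    out_df = pd.DataFrame(out, columns=cols)
    return out_df.sort_values(
        ["level", "atc", "product_id"], ignore_index=True
    )


def _cross_guideline_stats(
    single: Sequence[Prescription],
    extended: Sequence[Prescription],
    recs,
    weight_of,
) -> dict:
    """Cross-guideline non-conformity and unit-surplus statistics.

    The weighted mean non-conformity across substances is the
    prescription-weighted mean: total non-conform weighted prescriptions over
    total weighted prescriptions.  Reported for the single-pack stream (pack
    totals) and for the stream including partial/multiple packs (prescribed
    totals).
    """
    def _nonconform_share(stream, use_rx_total):
        wtot = wnon = 0.0
        for p in stream:
            sub_recs = recommendations_for(recs, p.product.substance.atc)
            if not sub_recs:
                continue
            w = weight_of(p)
            if w is None:
                continue
            total = p.total_mg if use_rx_total else p.product.pack_total_mg
            call = cross_guideline_call(total, sub_recs, p.product.unit_dose_mg)
            wtot += w
            if call.status != "conform":
                wnon += w
        return (100.0 * wnon / wtot if wtot else None), wtot

    pct_single, wtot_single = _nonconform_share(single, use_rx_total=False)
    pct_ext, wtot_ext = _nonconform_share(extended, use_rx_total=True)

    per_substance = {}
    calls_weights: dict[str, list] = {}
    for p in single:
        sub_recs = recommendations_for(recs, p.product.substance.atc)
        if not sub_recs:
            continue
        w = weight_of(p)
        if w is None:
            continue
        call = cross_guideline_call(
            p.product.pack_total_mg, sub_recs, p.product.unit_dose_mg
        )
        calls_weights.setdefault(p.product.substance.atc, []).append((call, w))
    all_over = all_under = 0.0
    for atc in sorted(calls_weights):
        calls, weights = zip(*calls_weights[atc])
        nu = net_units(calls, weights)
        per_substance[atc] = {
            "over_units": round(float(nu.over_units), 2),
            "under_units": round(float(nu.under_units), 2),
            "net_units": round(float(nu.net), 2),
        }
        all_over += float(nu.over_units)
        all_under += float(nu.under_units)
    return {
        "pct_nonconform_single_pack": None if pct_single is None else round(pct_single, 2),
        "weighted_n_single_pack": round(wtot_single, 2),
        "pct_nonconform_incl_partial_multiple": None if pct_ext is None else round(pct_ext, 2),
        "weighted_n_incl_partial_multiple": round(wtot_ext, 2),
        "units_by_substance": per_substance,
        "total_over_units": round(all_over, 2),
        "total_under_units": round(all_under, 2),
        "total_net_units": round(all_over - all_under, 2),
    }


def run_pipeline(config: RunConfig) -> RunResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "_INCOMPLETE"
    marker.write_text("run in progress; outputs incomplete\n")

    with _stage("catalogue"):
        if config.catalogue_path is None:
            recs, products = builtin_catalogues()
        else:
            recs, products = load_catalogues(config.catalogue_path)
        by_id = {p.product_id: p for p in products}

    with _stage("claims"):
        records = read_claims(config.claims_path, by_id, delimiter=config.delimiter)
        retained, filter_report = apply_inclusion_filters(records, config.analysis_year)

    with _stage("weights"):
        census = read_count_table(config.census_path, delimiter=config.delimiter)
        insured = read_count_table(config.insured_path, delimiter=config.delimiter)
        bins = AgeBins(config.age_bin_edges) if config.age_bin_edges else AgeBins()
        table = compute_weights(census, insured, age_bins=bins)

        def weight_of(p: Prescription) -> float | None:
            return table.weight_of(p, policy=config.weightless_policy)

    with _stage("streams"):
        single = [p for p in retained if p.multiplicity == "single"]
        extras = []
        for p in retained:
            if p.multiplicity == "single":
                continue
            sub_recs = recommendations_for(recs, p.product.substance.atc)
            if sub_recs and within_twice_rule(p, sub_recs):
                extras.append(p)
        extended = single + extras
        if config.mode == "subanalysis_with_partials":
            mode_stream, classify_total = extended, True
        else:
            mode_stream, classify_total = single, False

    with _stage("classification"):
        by_substance: dict[str, list[Prescription]] = {}
        for p in mode_stream:
            by_substance.setdefault(p.product.substance.atc, []).append(p)
        summaries = [
            combination_summary(
                by_substance.get(rec.substance.atc, []),
                rec,
                weight_of=weight_of,
                classify_total=classify_total,
            )
            for rec in recs
        ]
        zero_conform = zero_conform_combinations(recs, products)
        cross_stats = _cross_guideline_stats(single, extended, recs, weight_of)
        call_rows = []
        basis_cross = config.mode == "explorative_cross_guideline"
        for p in mode_stream:
            sub_recs = recommendations_for(recs, p.product.substance.atc)
            w = weight_of(p)
            if w is None or not sub_recs:
                continue
            total = p.total_mg if classify_total else p.product.pack_total_mg
            if basis_cross:
                call = cross_guideline_call(total, sub_recs, p.product.unit_dose_mg)
                call_rows.append((p, None, call, w))
            else:
                from .conformity import classify_against
                from .formulary import recommended_total
                for rec in sub_recs:
                    call = classify_against(
                        total, recommended_total(rec), p.product.unit_dose_mg
                    )
                    call_rows.append((p, rec, call, w))

    with _stage("patterns"):
        patterns = _patterns_table(retained, weight_of)

    with _stage("report"):
        paths = {
            "filter_report": out_dir / "filter_report.json",
            "patterns": out_dir / "prescription_patterns.csv",
            "summary": out_dir / "conformity_summary.csv",
            "cross_guideline": out_dir / "cross_guideline.json",
            "calls_long": out_dir / "calls_long.csv",
            "run_log": out_dir / "run_log.json",
        }
        with open(paths["filter_report"], "w") as fh:
            json.dump(filter_report.as_dict(), fh, indent=2, sort_keys=True)
        patterns.to_csv(paths["patterns"], index=False, sep=config.delimiter)
        write_summary_table(summaries, products, paths["summary"],
                            delimiter=config.delimiter)
        with open(paths["cross_guideline"], "w") as fh:
            json.dump(cross_stats, fh, indent=2, sort_keys=True)
        write_calls_long(call_rows, paths["calls_long"], delimiter=config.delimiter)
        run_log = {
            "package_version": __version__,
            "pandas_version": pd.__version__,
            "config": config.echo(),
            "n_recommendations": len(recs),
            "n_products": len(products),
            "zero_conform_combinations": zero_conform[0],
            "some_conform_combinations": zero_conform[1],
            "undefined_weight_strata": [list(s) for s in table.undefined_strata],
            "filter_report": filter_report.as_dict(),
        }
        with open(paths["run_log"], "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)

    marker.unlink(missing_ok=True)
    return RunResult(
        filter_report=filter_report,
        summaries=summaries,
        zero_conform=zero_conform,
        cross_stats=cross_stats,
        patterns=patterns,
        paths=paths,
    )
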