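"""Conformity classification: per-indication calls, closest-reference
cross-guideline calls, surplus arithmetic, combination summaries."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from packconform.claims import Prescription
from packconform.conformity import (
    classify_against,
    combination_summary,
    conform_pack_totals,
    cross_guideline_call,
    net_units,
    zero_conform_combinations,
)
from packconform.formulary import (
    GuidelineRecommendation,
    RecommendedTotal,
    SubstanceCode,
    recommendations_for,
    recommended_total,
)


def _rec(substance, indication, unit, dpd, days, line="first", override=None):
    return GuidelineRecommendation(
        indication=indication, substance=substance, line=line,
        unit_dose_mg=unit, doses_per_day_min=dpd, doses_per_day_max=dpd,
        duration_days_min=days, duration_days_max=days,
        total_override_mg=override,
    )


SUB = SubstanceCode("J01CA04", "amoxicillin")


# --- classify_against ------------------------------------------------------

def test_nitrofurantoin_pack_over_uti_recommendation(products_by_id, recommendations):
    """The 2 g pack against the 1 g recommendation: 10 surplus 100 mg tablets."""
    rec = next(r for r in recommendations if r.key == ("J01XE01", "UTI"))
    call = classify_against(2000, recommended_total(rec), unit_dose_mg=100)
    assert call.status == "over"
    assert call.reference_mg == 1000
    assert call.surplus_units == 10


def test_amoxicillin_10g_conform_in_sinusitis_range(recommendations):
    rec = next(r for r in recommendations if r.key == ("J01CA04", "ABRS"))
    call = classify_against(10_000, recommended_total(rec), unit_dose_mg=1000)
    assert call.status == "conform"
    assert call.surplus_units == 0


def test_boundary_of_point_interval_is_conform():
    call = classify_against(5000, RecommendedTotal(5000, 5000), unit_dose_mg=500)
    assert call.status == "conform"
    assert call.surplus_units == 0


@given(
    total=st.integers(1, 50_000),
    lower=st.integers(1, 30_000),
    width=st.integers(0, 20_000),
    unit=st.integers(1, 1000),
)
def test_trichotomy_and_surplus_conservation(total, lower, width, unit):
    """Exactly one status; surplus x unit dose + reference == total, exactly."""
    iv = RecommendedTotal(lower, lower + width)
    call = classify_against(total, iv, unit)
    assert (call.status == "conform") == (lower <= total <= lower + width)
    assert (call.status == "under") == (total < lower)
    assert (call.status == "over") == (total > lower + width)
    assert call.surplus_units * unit + call.reference_mg == total


@given(
    lower=st.integers(1, 30_000),
    width=st.integers(0, 20_000),
    t1=st.integers(1, 50_000),
    t2=st.integers(1, 50_000),
)
def test_classification_monotone_in_total(lower, width, t1, t2):
    """As the total grows the status moves under -> conform -> over."""
    order = {"under": 0, "conform": 1, "over": 2}
    iv = RecommendedTotal(lower, lower + width)
    lo, hi = sorted((t1, t2))
    c_lo = classify_against(lo, iv, 100)
    c_hi = classify_against(hi, iv, 100)
    assert order[c_lo.status] <= order[c_hi.status]


# --- cross-guideline -------------------------------------------------------

def test_fosfomycin_single_recommendation_conform(recommendations):
    recs = recommendations_for(recommendations, "J01XX01")
    call = cross_guideline_call(3000, recs, unit_dose_mg=3000)
    assert call.status == "conform"


def test_equidistant_tie_resolves_to_larger_reference():
    """Total 2 g between point recommendations at 1 g and 3 g: the larger
    reference wins, giving the conservative under call."""
    recs = [
        _rec(SUB, "UTI", 1000, 1, 1),
        _rec(SUB, "CAP", 1000, 1, 3, line="second"),
    ]
    call = cross_guideline_call(2000, recs, unit_dose_mg=1000)
    assert call.status == "under"
    assert call.reference_mg == 3000
    assert call.surplus_units == -1


def test_nitrofurantoin_5g_pack_cross_guideline(recommendations):
    recs = recommendations_for(recommendations, "J01XE01")
    call = cross_guideline_call(5000, recs, unit_dose_mg=100)
    assert call.status == "over"
    assert call.surplus_units == 40


def _brute_force_reference(total, recs):
    """Independent oracle: exhaustive scan over all interval endpoints."""
    endpoints = set()
    for r in recs:
        iv = recommended_total(r)
        endpoints.update((iv.lower_mg, iv.upper_mg))
    best = None
    for e in sorted(endpoints):
        d = abs(total - e)
        if best is None or d < best[0] or (d == best[0] and e > best[1]):
            best = (d, e)
    return best[1]


@given(
    total=st.integers(1, 40_000),
    regimens=st.lists(
        st.tuples(st.integers(1, 40) , st.integers(1, 4), st.integers(1, 10),
                  st.integers(0, 5)),
        min_size=1, max_size=6,
    ),
)
def test_closest_reference_matches_exhaustive_oracle(total, regimens):
    """For up to 6 recommendations the chosen reference equals the argmin
    found by enumerating every interval endpoint."""
    recs = []
    for i, (unit100, dpd, days, extra) in enumerate(regimens):
        recs.append(GuidelineRecommendation(
            indication="CAP", substance=SUB, line="first",
            unit_dose_mg=unit100 * 100, doses_per_day_min=dpd,
            doses_per_day_max=dpd, duration_days_min=days,
            duration_days_max=days + extra,
        ))
    call = cross_guideline_call(total, recs, unit_dose_mg=100)
    if call.status == "conform":
        assert any(recommended_total(r).contains(total) for r in recs)
    else:
        assert call.reference_mg == _brute_force_reference(total, recs)
        assert call.surplus_units * 100 + call.reference_mg == total


@given(
    total=st.integers(1, 40_000),
    regimens=st.lists(
        st.tuples(st.integers(1, 40), st.integers(1, 4), st.integers(1, 10)),
        min_size=1, max_size=6,
    ),
)
def test_cross_guideline_dominates_per_indication(total, regimens):
    """Conform for any single recommendation implies cross-guideline conform."""
    recs = [
        GuidelineRecommendation(
            indication="CAP", substance=SUB, line="first",
            unit_dose_mg=u * 100, doses_per_day_min=d, doses_per_day_max=d,
            duration_days_min=t, duration_days_max=t,
        )
        for u, d, t in regimens
    ]
    per_ind = [classify_against(total, recommended_total(r), 100) for r in recs]
    cross = cross_guideline_call(total, recs, unit_dose_mg=100)
    if any(c.status == "conform" for c in per_ind):
        assert cross.status == "conform"


def test_cross_guideline_rejects_empty_and_mixed():
    with pytest.raises(ValueError):
        cross_guideline_call(1000, [], 100)
    other = SubstanceCode("J01AA02", "doxycycline")
    with pytest.raises(ValueError):
        cross_guideline_call(
            1000, [_rec(SUB, "CAP", 1000, 1, 1), _rec(other, "CAP", 100, 2, 5)], 100
        )


# --- net units -------------------------------------------------------------

def test_net_units_empty():
    nu = net_units([])
    assert (nu.over_units, nu.under_units, nu.net) == (0, 0, 0)


def test_net_units_mixed_signs():
    calls = [
        classify_against(2000, RecommendedTotal(1000, 1000), 100),   # +10
        classify_against(600, RecommendedTotal(1000, 1000), 100),    # -4
    ]
    nu = net_units(calls)
    assert (nu.over_units, nu.under_units, nu.net) == (10, 4, 6)


def test_net_units_weighted_nitrofurantoin(recommendations):
    """1,000 weighted single 2 g packs against the 1 g recommendation yield
    10,000 overprescribed tablets (per-record summation oracle)."""
    rec = next(r for r in recommendations if r.key == ("J01XE01", "UTI"))
    iv = recommended_total(rec)
    calls = [classify_against(2000, iv, 100) for _ in range(100)]
    weights = [10.0] * 100
    nu = net_units(calls, weights)
    expected = sum(Fraction(10) * 10 for _ in range(100))
    assert nu.over_units == expected == 10_000
    assert nu.under_units == 0


# --- combination summaries and zero-conform counts -------------------------

def _stream(products_by_id, pid, n, packs=1.0):
    return [
        Prescription(
            rx_id=f"{pid}-{i}", patient_id=f"p{i}", sex="female", age_years=40,
            region=1, year=2022, prescriber="GP", galenic="enteral_solid",
            product=products_by_id[pid], packs=packs,
        )
        for i in range(n)
    ]


@pytest.mark.parametrize("pids,key,field,pct", [
    (["CXM500x7", "CXM500x14"], ("J01DC02", "UTI"), "pct_over", 100.0),
    (["SXT960x10", "SXT960x20", "SXT960x50"], ("J01EE01", "UTI"), "pct_over", 100.0),
    (["FOF3000x1"], ("J01XX01", "UTI"), "pct_conform", 100.0),
])
def test_forced_all_over_or_all_conform_cells(
    products_by_id, recommendations, pids, key, field, pct
):
    rec = next(r for r in recommendations if r.key == key)
    stream = [p for pid in pids for p in _stream(products_by_id, pid, 3)]
    summary = combination_summary(stream, rec)
    assert getattr(summary, field) == pct


def test_summary_all_inside_interval_is_all_conform(products_by_id, recommendations):
    rec = next(r for r in recommendations if r.key == ("J01CA04", "ABRS"))
    stream = _stream(products_by_id, "AMX1000x10", 4) + _stream(
        products_by_id, "AMX1000x20", 2
    )
    summary = combination_summary(stream, rec)
    assert summary.pct_conform == 100.0
    assert summary.n_under == summary.n_over == 0


def test_summary_rejects_foreign_substance(products_by_id, recommendations):
    rec = next(r for r in recommendations if r.key == ("J01XX01", "UTI"))
    with pytest.raises(ValueError):
        combination_summary(_stream(products_by_id, "NIT100x20", 1), rec)


def test_summary_weighted_counts(products_by_id, recommendations):
    rec = next(r for r in recommendations if r.key == ("J01XE01", "UTI"))
    stream = _stream(products_by_id, "NIT100x20", 4)
    summary = combination_summary(stream, rec, weight_of=lambda p: 2.5)
    assert summary.n_total == 10.0
    assert summary.n_over == 10.0
    assert summary.pct_over == 100.0


def test_zero_conform_split_10_of_23(catalogues):
    """With the full built-in catalogues, 10 of the 23 combinations have no
    conform pack size and 13 have at least one."""
    recs, products = catalogues
    assert zero_conform_combinations(recs, products) == (10, 13)


def test_zero_conform_vanishes_with_tailored_packs(catalogues, products_by_id):
    """A catalogue offering a pack exactly at each lower bound has no
    zero-conform combination."""
    from packconform.formulary import PackProduct

    recs, _ = catalogues
    tailored = []
    for i, rec in enumerate(recs):
        lower = recommended_total(rec).lower_mg
        tailored.append(PackProduct(
            product_id=f"T{i}", substance=rec.substance,
            unit_dose_mg=lower, units_per_pack=1,
        ))
    assert zero_conform_combinations(recs, tailored) == (0, 23)


def test_conform_pack_totals_cefuroxime(recommendations, products):
    rec = next(r for r in recommendations if r.key == ("J01DC02", "ABRS"))
    assert conform_pack_totals(rec, products) == {7000}
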