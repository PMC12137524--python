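"""Prescription filtering, multiplicity classification, claims I/O."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from packconform.claims import (
    ClaimsError,
    ClaimsRecordError,
    ClaimsSchemaError,
    Prescription,
    apply_inclusion_filters,
    classify_multiplicity,
    read_claims,
    within_twice_rule,
    write_claims,
)
from packconform.formulary import recommendations_for


def make_rx(products_by_id, *, product="AMX1000x10", sex="female", age=40,
            region=1, year=2022, prescriber="GP", galenic="enteral_solid",
            packs=1.0, rx_id="RX1", patient_id="P1"):
    return Prescription(
        rx_id=rx_id, patient_id=patient_id, sex=sex, age_years=age,
        region=region, year=year, prescriber=prescriber, galenic=galenic,
        product=products_by_id[product], packs=packs,
    )


# --- multiplicity ----------------------------------------------------------

@pytest.mark.parametrize("packs,expected", [
    (1, "single"), (1.0, "single"), (0.5, "partial"), (1.5, "partial"),
    (2, "multiple"), (3, "multiple"), (4, "multiple"),
    (2.0000001, "multiple"), (0.9999999, "single"),
])
def test_multiplicity_examples(packs, expected):
    assert classify_multiplicity(packs) == expected


def test_multiplicity_rejects_nonpositive():
    with pytest.raises(ClaimsError):
        classify_multiplicity(0)
    with pytest.raises(ClaimsError):
        classify_multiplicity(-1.5)


@given(st.integers(2, 10_000))
def test_every_whole_count_ge2_is_multiple(n):
    assert classify_multiplicity(n) == "multiple"


@given(st.fractions(min_value="1/100", max_value=20))
def test_multiplicity_partitions_positive_rationals(q):
    """Exactly one category for every positive rational pack count."""
    cat = classify_multiplicity(float(q))
    if q == 1:
        assert cat == "single"
    elif q.denominator == 1 and q >= 2:
        assert cat == "multiple"
    elif abs(float(q) - round(float(q))) > 1e-6:
        assert cat == "partial"


# --- inclusion filters -----------------------------------------------------

def test_filter_rules_and_attribution(products_by_id):
    records = [
        make_rx(products_by_id, rx_id="keep", age=18),
        make_rx(products_by_id, rx_id="male_nitro", sex="male", product="NIT100x20"),
        make_rx(products_by_id, rx_id="minor", age=17),
        make_rx(products_by_id, rx_id="wrong_year", year=2021),
        make_rx(products_by_id, rx_id="specialist", prescriber="other"),
        make_rx(products_by_id, rx_id="syrup", galenic="other"),
        # fails both prescriber and age: charged to prescriber (first rule)
        make_rx(products_by_id, rx_id="both", prescriber="other", age=17),
        ClaimsRecordError(line_no=99, message="bad row"),
    ]
    retained, report = apply_inclusion_filters(records, analysis_year=2022)
    assert [p.rx_id for p in retained] == ["keep"]
    assert report.removed == {
        "prescriber": 2, "age": 1, "year": 1, "galenic": 1, "sex_female_only": 1,
    }
    assert report.unparseable == 1
    assert report.input_count == 8
    assert report.retained + report.total_removed + report.unparseable == 8


def test_male_allowed_on_non_female_only_substance(products_by_id):
    rx = make_rx(products_by_id, sex="male", product="AMX1000x10")
    retained, _ = apply_inclusion_filters([rx], 2022)
    assert retained == [rx]


def test_filtering_is_idempotent(products_by_id):
    records = [
        make_rx(products_by_id, rx_id=f"r{i}", age=a, sex=s, product=prod)
        for i, (a, s, prod) in enumerate([
            (30, "female", "NIT100x20"), (17, "female", "AMX1000x10"),
            (50, "male", "FOF3000x1"), (80, "male", "CXM500x7"),
        ])
    ]
    once, _ = apply_inclusion_filters(records, 2022)
    twice, report = apply_inclusion_filters(once, 2022)
    assert twice == once
    assert report.total_removed == 0


# --- twice rule ------------------------------------------------------------

def test_twice_rule_doxycycline_three_large_packs(products_by_id, recommendations):
    """3 x 1.4 g = 4.2 g exceeds twice the largest doxycycline recommendation
    (1.4 g), so the prescription is treated as likely chronic."""
    rx = make_rx(products_by_id, product="DOX100x14", packs=3)
    recs = recommendations_for(recommendations, "J01AA02")
    assert rx.total_mg == 4200
    assert within_twice_rule(rx, recs) is False


def test_twice_rule_boundary_inclusive(products_by_id, recommendations):
    # doxycycline max recommended upper bound is 1.4 g; 2 x 1.4 g sits exactly
    # on the boundary and is kept
    rx = make_rx(products_by_id, product="DOX100x14", packs=2)
    recs = recommendations_for(recommendations, "J01AA02")
    assert within_twice_rule(rx, recs) is True


def test_twice_rule_single_pack_below_recommendation(products_by_id, recommendations):
    rx = make_rx(products_by_id, product="DOX100x10", packs=1)
    recs = recommendations_for(recommendations, "J01AA02")
    assert within_twice_rule(rx, recs) is True


def test_twice_rule_requires_recommendations(products_by_id):
    rx = make_rx(products_by_id)
    with pytest.raises(ClaimsError):
        within_twice_rule(rx, [])


def test_twice_rule_rejects_wrong_substance(products_by_id, recommendations):
    rx = make_rx(products_by_id, product="DOX100x10")
    with pytest.raises(ClaimsError):
        within_twice_rule(rx, recommendations_for(recommendations, "J01CA04"))


# --- prescription invariants ----------------------------------------------

def test_total_mg_is_exact(products_by_id):
    rx = make_rx(products_by_id, product="AMC625x10", packs=0.5)
    assert rx.total_mg == Fraction(6250, 2)


def test_prescription_validation(products_by_id):
    with pytest.raises(ClaimsError):
        make_rx(products_by_id, packs=0)
    with pytest.raises(ClaimsError):
        make_rx(products_by_id, region=27)
    with pytest.raises(ClaimsError):
        make_rx(products_by_id, sex="f")


# --- I/O -------------------------------------------------------------------

def test_claims_roundtrip(tmp_path, products_by_id):
    records = [
        make_rx(products_by_id, rx_id="a", packs=1),
        make_rx(products_by_id, rx_id="b", packs=0.5, product="NIT100x20"),
        make_rx(products_by_id, rx_id="c", packs=3, product="FOF3000x1"),
    ]
    path = tmp_path / "claims.csv"
    write_claims(records, path)
    back = read_claims(path, products_by_id)
    assert back == records


def test_reader_reports_line_numbers(tmp_path, products_by_id):
    path = tmp_path / "claims.csv"
    path.write_text(
        "rx_id,patient_id,sex,age,canton,year,prescriber,galenic,product_id,packs\n"
        "a,p1,female,30,1,2022,GP,enteral_solid,AMX1000x10,1\n"
        "b,p2,female,thirty,1,2022,GP,enteral_solid,AMX1000x10,1\n"
        "c,p3,female,30,1,2022,GP,enteral_solid,NO_SUCH_PRODUCT,1\n"
    )
    rows = read_claims(path, products_by_id)
    assert isinstance(rows[0], Prescription) and rows[0].rx_id == "a"
    errors = [r for r in rows if isinstance(r, ClaimsRecordError)]
    assert [e.line_no for e in errors] == [3, 4]
    assert "NO_SUCH_PRODUCT" in errors[1].message


def test_reader_rejects_missing_columns(tmp_path, products_by_id):
    path = tmp_path / "claims.csv"
    path.write_text("rx_id,sex\n1,female\n")
    with pytest.raises(ClaimsSchemaError, match="missing required columns"):
        read_claims(path, products_by_id)
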