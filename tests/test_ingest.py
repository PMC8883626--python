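"""Quality scoring, Harris-Benedict screening, exclusion cascades, food key."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twindiet.ingest import (
    QualityScore,
    aggregate_food_key,
    apply_efr_exclusions,
    apply_ffq_exclusions,
    harris_benedict_bmr,
    parse_clock_time,
    score_quality,
)

from conftest import make_entries, make_participants


# --- Harris-Benedict --------------------------------------------------------


def test_harris_benedict_published_coefficients():
    # direct evaluation of the 1919 equations
    assert harris_benedict_bmr("F", 60, 165, 30) == pytest.approx(1393.8155)
    assert harris_benedict_bmr("M", 70, 175, 25) == pytest.approx(1735.7875)


def test_bmr_strictly_decreases_with_age():
    for sex in "MF":
        vals = [harris_benedict_bmr(sex, 70, 170, age) for age in (20, 40, 60, 80)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def test_bmr_rejects_nonpositive_anthropometrics():
    with pytest.raises(ValueError):
        harris_benedict_bmr("F", 0, 165, 30)
    with pytest.raises(ValueError):
        harris_benedict_bmr("X", 60, 165, 30)


# --- clock-time parsing -----------------------------------------------------


@pytest.mark.parametrize(
    "text, minutes",
    [
        ("08:00", 480),
        ("23:59", 1439),
        ("0:05", 5),
        ("8.30", 510),
        ("7:15 am", 435),
        ("12:30 pm", 750),
        ("12:05 am", 5),
        ("morning", None),
        ("", None),
        (None, None),
        ("25:00", None),
    ],
)
def test_parse_clock_time(text, minutes):
    assert parse_clock_time(text) == minutes


# --- quality scoring --------------------------------------------------------


def _record(entries):
    return make_entries([("R1", "P1", 1, entries)])


def test_fully_complete_record_scores_six():
    rec = _record([{} for _ in range(3)])  # defaults are complete on all fields
    q = score_quality(rec)
    assert (q.portion, q.description, q.timing) == (2, 2, 2)
    assert q.total == 6 and q.acceptable


def test_all_missing_record_scores_zero():
    rec = _record([{"meal_time": "", "description": "", "portion_text": ""}] * 2)
    q = score_quality(rec)
    assert (q.portion, q.description, q.timing) == (0, 0, 0)
    assert q.total == 0 and not q.acceptable


def test_partial_portion_scores_five_and_is_acceptable():
    rec = _record([{}, {"portion_text": "some"}, {}])
    q = score_quality(rec)
    assert (q.portion, q.description, q.timing) == (1, 2, 2)
    assert q.total == 5 and q.acceptable


def test_boundary_score_four_not_acceptable():
    rec = _record([{"portion_text": "some", "meal_time": "morning"}, {}])
    q = score_quality(rec)
    assert q.total == 4 and not q.acceptable


def test_empty_record_rejected():
    with pytest.raises(ValueError):
        score_quality(_record([]).iloc[0:0])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2)),
        min_size=1,
        max_size=6,
    )
)
def test_quality_total_invariants(states):
    """total = portion + description + timing, in 0..6; acceptable iff >= 5."""
    texts = {
        "portion_text": {0: "", 1: "some", 2: "1 cup (200 ml)"},
        "description": {0: "", 1: "Tea", 2: "Tea, black, infusion, average"},
        "meal_time": {0: "", 1: "morning", 2: "08:15"},
    }
    rec = _record(
        [
            {
                "portion_text": texts["portion_text"][p],
                "description": texts["description"][d],
                "meal_time": texts["meal_time"][t],
            }
            for p, d, t in states
        ]
    )
    q = score_quality(rec)
    assert q.total == q.portion + q.description + q.timing
    assert 0 <= q.total <= 6
    assert q.acceptable == (q.total >= 5)
    for comp, idx in ((q.portion, 0), (q.description, 1), (q.timing, 2)):
        col = [s[idx] for s in states]
        if all(v == 0 for v in col):
            assert comp == 0
        elif all(v == 2 for v in col):
            assert comp == 2
        else:
            assert comp == 1


# --- exclusion cascade ------------------------------------------------------


def _cascade_fixture():
    """19 well-behaved records plus labelled rule-breakers, one batch."""
    specs = []
    parts = []
    bmr = harris_benedict_bmr("F", 60, 165, 30)  # 1393.8155
    for i in range(19):
        pid = f"P{i:02d}"
        parts.append((pid, 30.0, "F"))
        specs.append(
            (f"R{i:02d}", pid, 1, [{"energy_kcal": bmr / 0.8, "protein_g": 70,
                                    "carbohydrate_g": 200, "fat_g": 60}])
        )
    # ratio outlier: bmr/energy = 2.5, energy still above the 500 kcal floor
    parts.append(("P19", 30.0, "F"))
    specs.append(("R19", "P19", 1, [{"energy_kcal": bmr / 2.5, "protein_g": 70,
                                     "carbohydrate_g": 200, "fat_g": 60}]))
    return make_entries(specs), make_participants(parts), bmr


def test_energy_floor_exclusion():
    entries = make_entries([("R1", "P1", 1, [{"energy_kcal": 450.0}]),
                            ("R2", "P2", 1, [{"energy_kcal": 2000.0}]),
                            ("R3", "P3", 1, [{"energy_kcal": 2000.0}])])
    parts = make_participants([("P1", 30, "F"), ("P2", 30, "F"), ("P3", 30, "F")])
    report = apply_efr_exclusions(entries, parts)
    assert dict(report.excluded.values)["R1"] == "energy_floor"


def test_age_floor_exclusion():
    entries = make_entries([("R1", "P1", 1, [{"energy_kcal": 2000.0}]),
                            ("R2", "P2", 1, [{"energy_kcal": 2000.0}]),
                            ("R3", "P3", 1, [{"energy_kcal": 2000.0}])])
    parts = make_participants([("P1", 17.5, "F"), ("P2", 30, "F"), ("P3", 30, "F")])
    report = apply_efr_exclusions(entries, parts)
    assert dict(report.excluded.values)["R1"] == "age_floor"


def test_missing_demographics_removed():
    entries = make_entries([("R1", "P1", 1, [{"energy_kcal": 2000.0}]),
                            ("R2", "P2", 1, [{"energy_kcal": 2000.0}]),
                            ("R3", "P3", 1, [{"energy_kcal": 2000.0}])])
    parts = make_participants([("P1", 30, "F"), ("P2", 30, "F"), ("P3", 30, "F")])
    parts.loc[parts["participant_id"] == "P2", "height_cm"] = np.nan
    report = apply_efr_exclusions(entries, parts)
    assert dict(report.excluded.values)["R2"] == "missing_demographics"


def test_ratio_rule_excludes_exactly_the_outlier():
    entries, parts, bmr = _cascade_fixture()
    report = apply_efr_exclusions(entries, parts)
    assert dict(report.excluded.values) == {"R19": "bmr_ratio_outlier"}
    # independent oracle: mean +- 2 SD of the 20 hand-built ratios
    ratios = np.array([0.8] * 19 + [2.5])
    hi = ratios.mean() + 2 * ratios.std(ddof=1)
    assert 2.5 > hi and 0.8 < hi


def test_cascade_idempotent_with_frozen_thresholds():
    entries, parts, _ = _cascade_fixture()
    first = apply_efr_exclusions(entries, parts)
    kept_entries = entries[entries["record_id"].isin(first.kept)]
    second = apply_efr_exclusions(
        kept_entries, parts, frozen_thresholds=first.thresholds
    )
    assert second.kept == first.kept
    assert len(second.excluded) == 0


def test_unknown_participant_raises():
    entries = make_entries([("R1", "PX", 1, [{}])])
    with pytest.raises(KeyError):
        apply_efr_exclusions(entries, make_participants([("P1", 30, "F")]))


# --- FFQ exclusions ---------------------------------------------------------


def _ffq_fixture():
    parts = make_participants([(f"P{i}", 40, "F") for i in range(6)])
    bmr = harris_benedict_bmr("F", 60, 165, 40)
    ffqs = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(6)],
            "ffq_id": [f"Q{i}" for i in range(6)],
            "ffq_date": "2015-01-01",
            "batch": 1,
            "n_incomplete_items": [0, 9, 10, 2, 0, 1],
            "energy_kcal": [bmr / 0.8] * 5 + [bmr / 3.5],
        }
    )
    return ffqs, parts


def test_ffq_exclusion_rules():
    ffqs, parts = _ffq_fixture()
    kept_efr = {"P0", "P1", "P2", "P5"}  # P3, P4 have no surviving EFR
    report = apply_ffq_exclusions(ffqs, parts, kept_efr)
    reasons = dict(report.excluded.values)
    assert reasons["Q2"] == "incomplete_items"  # 10 incomplete -> out
    assert reasons["Q5"] == "bmr_ratio_outlier"
    assert reasons["Q3"] == "no_matched_efr"
    assert reasons["Q4"] == "no_matched_efr"
    assert "Q1" not in reasons  # 9 incomplete, matched EFR -> retained
    assert set(report.kept) == {"Q0", "Q1"}


# --- food-key aggregation ---------------------------------------------------


def _variants(rows):
    cols = [f"nut{i}" for i in range(40)]
    df = pd.DataFrame(rows, columns=["description", *cols])
    return df, cols


def test_most_complete_variant_selected_verbatim():
    full = ["tea fresh"] + list(range(40))
    partial = ["tea stale"] + list(range(30)) + [np.nan] * 10
    df, cols = _variants([full, partial])
    merged, flags = aggregate_food_key(df, {"tea fresh": "tea", "tea stale": "tea"}, cols)
    assert len(flags) == 0
    assert merged.loc[0, "nut0"] == 0 and merged.loc[0, "nut39"] == 39


def test_equal_completeness_within_tolerance_averaged():
    a = ["tea a", 100.0] + [1.0] * 39
    b = ["tea b", 104.0] + [1.0] * 39
    df, cols = _variants([a, b])
    merged, flags = aggregate_food_key(df, {"tea a": "tea", "tea b": "tea"}, cols)
    assert merged.loc[0, "nut0"] == pytest.approx(102.0)  # 3.9% < 5% -> mean
    assert len(flags) == 0


def test_disagreement_beyond_tolerance_flagged():
    a = ["tea a", 100.0] + [1.0] * 39
    b = ["tea b", 120.0] + [1.0] * 39
    df, cols = _variants([a, b])
    merged, flags = aggregate_food_key(df, {"tea a": "tea", "tea b": "tea"}, cols)
    assert np.isnan(merged.loc[0, "nut0"])  # 18% > 5% -> manual review
    assert list(flags["nutrient"]) == ["nut0"]


def test_unmapped_description_raises_with_offender():
    df, cols = _variants([["mystery item", 100.0] + [1.0] * 39])
    with pytest.raises(KeyError, match="mystery item"):
        aggregate_food_key(df, {}, cols)
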