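"""DQI indicators: completeness, timeliness, grading, weekly assessment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phcwatch as pw
from phcwatch.quality import assess_all, completeness, grade_dqi, timeliness

from conftest import simulate_events


def events_frame(rows):
    return pd.DataFrame(
        rows, columns=["municipality", "encounter_week", "registration_week", "count"]
    )


@pytest.fixture
def hand_built_snapshot():
    """Municipality 'a': weeks 0..7 each with 1 encounter registered
    immediately, except weeks 2,3 registered late (delay 5) and week 6
    empty.  Municipality 'b' appears only after week 20."""
    rows = []
    for w in range(8):
        if w == 6:
            continue
        delay = 5 if w in (2, 3) else 0
        rows.append(("a", w, w + delay, 10))
    rows.append(("b", 20, 20, 3))
    return events_frame(rows)


def test_completeness_counts_window_weeks_with_any_visible_encounter(hand_built_snapshot):
    view = pw.snapshot_view(hand_built_snapshot, as_of_week=7, n_weeks=23)
    # weeks 2,3 registered at weeks 7,8 -> week 2's volume visible at 7, week 3's not
    assert completeness(view, "a", 7) == 6 / 8
    late = pw.snapshot_view(hand_built_snapshot, as_of_week=9, n_weeks=23)
    assert completeness(late, "a", 7) == 7 / 8  # week 6 permanently empty


def test_completeness_full_and_absent_cases():
    rows = [("a", w, w, 1) for w in range(8)]
    view = pw.snapshot_view(events_frame(rows), as_of_week=7, n_weeks=8)
    assert completeness(view, "a", 7) == 1.0
    assert completeness(view, "ghost", 7) == 0.0  # municipality absent from snapshot


def test_completeness_window_before_series_start_is_unavailable():
    rows = [("a", w, w, 1) for w in range(8)]
    view = pw.snapshot_view(events_frame(rows), as_of_week=7, n_weeks=8)
    assert completeness(view, "a", 6) is None


def test_timeliness_is_volume_weighted_ratio():
    # window volume 10: 8 units at delay <= 2, 2 units at delay 5
    rows = [("a", 0, 0, 5), ("a", 1, 3, 3), ("a", 2, 7, 2)]
    view = pw.snapshot_view(events_frame(rows), as_of_week=7, n_weeks=8)
    assert timeliness(view, "a", 7) == pytest.approx(0.8)


def test_timeliness_all_instant_is_one_and_empty_is_undefined():
    rows = [("a", w, w, 2) for w in range(8)]
    view = pw.snapshot_view(events_frame(rows), as_of_week=7, n_weeks=8)
    assert timeliness(view, "a", 7) == 1.0
    assert math.isnan(timeliness(view, "ghost", 7))
    assert grade_dqi(0.0, timeliness(view, "ghost", 7)) is False


def test_grade_dqi_threshold_examples():
    assert grade_dqi(1.0, 0.8) is True
    assert grade_dqi(0.875, 1.0) is False
    assert grade_dqi(1.0, None) is False
    assert grade_dqi(1.0, float("nan")) is False


@settings(max_examples=500, derandomize=True)
@given(
    comp=st.integers(min_value=0, max_value=8).map(lambda k: k / 8),
    tim=st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
    cmin=st.floats(min_value=0, max_value=1),
    tmin=st.floats(min_value=0, max_value=1),
)
def test_grade_dqi_equals_bruteforce_conjunction(comp, tim, cmin, tmin):
    expected = (tim is not None) and comp >= cmin and tim >= tmin
    assert grade_dqi(comp, tim, cmin, tmin) is expected


def test_assess_all_matches_single_week_operations():
    """The vectorised weekly assessment must agree with the per-week
    snapshot-view operations (dual route)."""
    cfg = pw.make_config(6, profile="poor", n_weeks=16, seed=13)
    _, events, munis = simulate_events(cfg)
    table = assess_all(events, municipalities=munis, n_weeks=cfg.n_weeks)
    for week in (7, 11, 15):
        view = pw.snapshot_view(events, as_of_week=week, n_weeks=cfg.n_weeks)
        for muni in munis:
            row = table[(table["municipality"] == muni) & (table["week"] == week)].iloc[0]
            assert row["completeness"] == pytest.approx(completeness(view, muni, week))
            t = timeliness(view, muni, week)
            if t is None or math.isnan(t):
                assert math.isnan(row["timeliness"])
            else:
                assert row["timeliness"] == pytest.approx(t)
            assert row["suitable"] == grade_dqi(row["completeness"], t)


def test_completeness_takes_only_ninths_and_timeliness_in_unit_interval():
    cfg = pw.make_config(20, profile="poor", seed=14)
    _, events, munis = simulate_events(cfg)
    table = assess_all(events, municipalities=munis, n_weeks=cfg.n_weeks)
    levels = {k / 8 for k in range(9)}
    assert set(np.round(table["completeness"], 12)).issubset(levels)
    tim = table["timeliness"].dropna()
    assert ((tim >= 0) & (tim <= 1)).all()


def test_adding_registrations_never_decreases_completeness():
    """Monotonicity: later snapshots can only reveal more weeks."""
    cfg = pw.make_config(8, profile="poor", n_weeks=20, seed=15)
    _, events, munis = simulate_events(cfg)
    week = 12
    early = pw.snapshot_view(events, as_of_week=week, n_weeks=cfg.n_weeks)
    later = pw.snapshot_view(events, as_of_week=week + 4, n_weeks=cfg.n_weeks)
    for muni in munis:
        assert completeness(later, muni, week) >= completeness(early, muni, week)


def test_prompt_profile_yields_all_suitable_full_window_weeks():
    cfg = pw.make_config(20, profile="prompt", baseline_rate=200, seed=16)
    _, events, munis = simulate_events(cfg)
    table = assess_all(events, municipalities=munis, n_weeks=cfg.n_weeks)
    assert len(table) == 20 * (cfg.n_weeks - 7)
    assert table["suitable"].all()


def test_poor_profile_has_fewer_suitable_weeks_than_prompt_at_same_truth():
    seed = 17
    prompt = pw.make_config(200, profile="prompt", seed=seed)
    poor = pw.make_config(200, profile="poor", seed=seed)
    truth = pw.simulate_truth(prompt)  # identical truth: same seed and truth params
    table_prompt = assess_all(
        pw.simulate_registration(truth, prompt),
        municipalities=[t.municipality for t in truth],
        n_weeks=prompt.n_weeks,
    )
    table_poor = assess_all(
        pw.simulate_registration(truth, poor),
        municipalities=[t.municipality for t in truth],
        n_weeks=poor.n_weeks,
    )
    assert table_poor["suitable"].mean() < table_prompt["suitable"].mean()


def test_zero_encounter_municipality_is_always_unsuitable():
    rows = [("a", w, w, 1) for w in range(12)]
    table = assess_all(
        events_frame(rows), municipalities=["a", "empty"], n_weeks=12
    )
    empty = table[table["municipality"] == "empty"]
    assert (empty["completeness"] == 0).all()
    assert empty["timeliness"].isna().all()
    assert (~empty["suitable"]).all()


def test_quality_indicators_require_snapshot_view():
    rows = [("a", w, w, 1) for w in range(8)]
    back = pw.backfilled_view(events_frame(rows), n_weeks=8)
    with pytest.raises(pw.InputError):
        completeness(back, "a", 7)
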