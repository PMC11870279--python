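"""Warning matching, stratified concordance, municipality grouping."""

import numpy as np
import pandas as pd
import pytest

import phcwatch as pw
from phcwatch.concordance import (
    concordance_by_municipality_group,
    concordance_by_quality,
    group_municipalities_by_suitable_weeks,
    match_warnings,
    weekly_suitable_series,
)


def warnings_frame(pairs, source="backfilled"):
    return pd.DataFrame(
        [
            {"municipality": m, "week": w, "source": source, "statistic": 5.0}
            for m, w in pairs
        ],
        columns=["municipality", "week", "source", "statistic"],
    )


def test_identical_sets_fully_concordant():
    a = warnings_frame([("m1", 5), ("m2", 7)])
    matched = match_warnings(a, a)
    assert matched["concordant"].all()


def test_disjoint_sets_fully_nonconcordant():
    a = warnings_frame([("m1", 5)])
    b = warnings_frame([("m1", 6), ("m2", 5)])
    assert not match_warnings(a, b)["concordant"].any()


def test_hand_countable_partition():
    ref = warnings_frame([("m1", 5), ("m1", 9), ("m2", 7)])
    test = warnings_frame([("m1", 5), ("m2", 8)], source="realtime")
    matched = match_warnings(ref, test)
    assert int(matched["concordant"].sum()) == 1
    assert int((~matched["concordant"]).sum()) == 2


def test_week_tolerance_flag_widens_matching():
    ref = warnings_frame([("m2", 7)])
    test = warnings_frame([("m2", 8)], source="realtime")
    assert not match_warnings(ref, test)["concordant"].any()
    assert match_warnings(ref, test, tolerance_weeks=1)["concordant"].all()


def test_direction_duality_concordant_counts_agree(mixed_cohort):
    wb = mixed_cohort["warnings_backfilled"]
    wr = mixed_cohort["warnings_realtime"]
    n_b = int(match_warnings(wb, wr)["concordant"].sum())
    n_r = int(match_warnings(wr, wb)["concordant"].sum())
    assert n_b == n_r
    assert n_b <= min(len(wb), len(wr))


@pytest.mark.parametrize("dimension", ["completeness", "timeliness", "suitable"])
def test_stratified_counts_sum_to_totals_in_both_directions(mixed_cohort, dimension):
    table = concordance_by_quality(
        mixed_cohort["warnings_backfilled"],
        mixed_cohort["warnings_realtime"],
        mixed_cohort["assessments"],
        dimension,
    )
    for direction, total in (
        ("vs_backfilled", len(mixed_cohort["warnings_backfilled"])),
        ("vs_realtime", len(mixed_cohort["warnings_realtime"])),
    ):
        sub = table[table["direction"] == direction]
        assert int(sub["n_reference"].sum()) == total
        assert (sub["n_concordant"] <= sub["n_reference"]).all()


def test_suitable_stratum_outperforms_unsuitable_in_mixed_cohort(mixed_cohort):
    table = concordance_by_quality(
        mixed_cohort["warnings_backfilled"],
        mixed_cohort["warnings_realtime"],
        mixed_cohort["assessments"],
        "suitable",
        directions=("vs_backfilled",),
    )
    by = dict(zip(table["stratum"], table["proportion"]))
    assert by["suitable"] > by["unsuitable"]


def test_unknown_dimension_rejected(mixed_cohort):
    with pytest.raises(pw.InputError):
        concordance_by_quality(
            mixed_cohort["warnings_backfilled"],
            mixed_cohort["warnings_realtime"],
            mixed_cohort["assessments"],
            "sparkle",
        )


def test_warning_without_assessment_lands_in_unassessed_stratum():
    ref = warnings_frame([("mX", 3)])
    test = warnings_frame([("mX", 3)], source="realtime")
    assessments = pd.DataFrame(
        {
            "municipality": pd.Series(dtype=str),
            "week": pd.Series(dtype=np.int64),
            "completeness": pd.Series(dtype=float),
            "timeliness": pd.Series(dtype=float),
            "suitable": pd.Series(dtype=bool),
        }
    )
    table = concordance_by_quality(ref, test, assessments, "suitable", ("vs_backfilled",))
    assert list(table["stratum"]) == ["unassessed"]
    assert table["proportion"].iloc[0] == 1.0


def assessments_with_fraction(frac_suitable, n_weeks=23, municipality="m"):
    n_suitable = round(frac_suitable * n_weeks)
    return pd.DataFrame(
        {
            "municipality": municipality,
            "week": np.arange(n_weeks),
            "completeness": 1.0,
            "timeliness": 1.0,
            "suitable": [True] * n_suitable + [False] * (n_weeks - n_suitable),
        }
    )


@pytest.mark.parametrize(
    "n_suitable,n_weeks,expected",
    [
        (23, 23, ">=80%"),
        (0, 23, "<=20%"),
        (14, 23, "60-80%"),  # 0.609 -> (0.6, 0.8]
        (2, 10, "<=20%"),  # 0.2 on the closed upper edge of the first bin
        (6, 10, "40-60%"),  # 0.6 upper-closed
    ],
)
def test_municipality_grouping_bin_edges(n_suitable, n_weeks, expected):
    ass = assessments_with_fraction(n_suitable / n_weeks, n_weeks)
    groups = group_municipalities_by_suitable_weeks(ass)
    assert groups["group"].iloc[0] == expected


def test_group_stratification_partitions_reference_warnings(mixed_cohort):
    table = concordance_by_municipality_group(
        mixed_cohort["warnings_backfilled"],
        mixed_cohort["warnings_realtime"],
        mixed_cohort["assessments"],
        directions=("vs_backfilled",),
    )
    assert int(table["n_reference"].sum()) == len(mixed_cohort["warnings_backfilled"])


def test_weekly_suitable_series_degenerate_and_median():
    ass = assessments_with_fraction(1.0)
    weekly, summary = weekly_suitable_series(ass)
    assert (weekly["proportion"] == 1.0).all()
    assert summary == {"median": 1.0, "q1": 1.0, "q3": 1.0}

    mixed = pd.concat(
        [
            assessments_with_fraction(1.0, n_weeks=3, municipality="a"),
            assessments_with_fraction(0.0, n_weeks=3, municipality="b"),
        ]
    )
    mixed.loc[(mixed["municipality"] == "b") & (mixed["week"] > 0), "suitable"] = [True, True]
    weekly, summary = weekly_suitable_series(mixed)
    assert summary["median"] == pytest.approx(1.0)
    assert sorted(weekly["proportion"]) == [0.5, 1.0, 1.0]


def test_half_split_weekly_suitable_proportion_near_half(mixed_cohort):
    """Half the cohort uploads promptly (virtually always suitable), half
    poorly (virtually never): the weekly suitable proportion sits near 1/2."""
    weekly, summary = weekly_suitable_series(mixed_cohort["assessments"])
    assert abs(summary["median"] - 0.5) <= 0.1


def test_perfect_quality_limit_gives_full_concordance():
    cfg = pw.make_config(20, delay_pmf=(1.0,), dropout_prob=0.0, seed=30)
    truth = pw.simulate_truth(cfg)
    events = pw.simulate_registration(truth, cfg)
    munis = [t.municipality for t in truth]
    back = pw.backfilled_view(events, n_weeks=cfg.n_weeks)
    wb = pw.run_ews(back)
    wr = pw.run_ews_realtime(events, municipalities=munis, n_weeks=cfg.n_weeks)
    assert pw.concordance_summary(wb, wr, "vs_backfilled")["proportion"] == 1.0
    assert pw.concordance_summary(wr, wb, "vs_realtime")["proportion"] == 1.0
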