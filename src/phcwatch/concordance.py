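"""Warning concordance between real-time and backfilled detection.

A reference warning is *concordant* when the other view raised a warning
for the same municipality in the same week.  Proportions are reported in
both directions: ``vs_backfilled`` uses the backfilled warnings as the
denominator (the gold-standard reference), ``vs_realtime`` uses the
real-time warnings.  Stratification joins each warning to the real-time
DQI assessment of its municipality-week.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import InputError

__all__ = [
    "match_warnings",
    "concordance_summary",
    "concordance_by_quality",
    "group_municipalities_by_suitable_weeks",
    "concordance_by_municipality_group",
    "weekly_suitable_series",
    "SUITABLE_WEEK_BINS",
    "SUITABLE_WEEK_LABELS",
]

SUMMARY_COLUMNS = ["direction", "stratum", "n_reference", "n_concordant", "proportion"]

SUITABLE_WEEK_BINS = (0.2, 0.4, 0.6, 0.8)
SUITABLE_WEEK_LABELS = ("<=20%", "20-40%", "40-60%", "60-80%", ">=80%")


def _keys(warnings: pd.DataFrame) -> pd.DataFrame:
    return warnings[["municipality", "week"]].drop_duplicates()


def match_warnings(
    reference: pd.DataFrame, test: pd.DataFrame, tolerance_weeks: int = 0
) -> pd.DataFrame:
    """Partition reference warnings into concordant / nonconcordant.

    Returns a copy of ``reference`` with a boolean ``concordant`` column:
    true iff a test warning exists for the same municipality within
    ``tolerance_weeks`` weeks (default 0 — the same week).
    """
    out = reference.copy()
    if len(reference) == 0:
        out["concordant"] = pd.Series(dtype=bool)
        return out
    test_keys = set(map(tuple, _keys(test).to_numpy())) if len(test) else set()

    def hit(row) -> bool:
        m, w = row
        return any((m, w + d) in test_keys for d in range(-tolerance_weeks, tolerance_weeks + 1))

    if tolerance_weeks == 0:
        out["concordant"] = [
            (m, w) in test_keys for m, w in zip(out["municipality"], out["week"])
        ]
    else:
        out["concordant"] = [hit((m, w)) for m, w in zip(out["municipality"], out["week"])]
    return out


def concordance_summary(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    direction: str,
    tolerance_weeks: int = 0,
) -> dict:
    """Overall concordant count and proportion for one direction."""
    matched = match_warnings(reference, test, tolerance_weeks)
    n_ref = len(matched)
    n_con = int(matched["concordant"].sum()) if n_ref else 0
    return {
        "direction": direction,
        "stratum": "overall",
        "n_reference": n_ref,
        "n_concordant": n_con,
        "proportion": n_con / n_ref if n_ref else np.nan,
    }


def _completeness_label(v: float) -> str:
    return f"{int(round(v * 8))}/8"


_DECILE_EDGES = np.linspace(0.0, 1.0, 11)


def _timeliness_label(v: float) -> str:
    if np.isnan(v):
        return "undefined"
    # half-open upper-closed deciles, lowest bin closed at 0
    k = int(np.searchsorted(_DECILE_EDGES[1:-1], v, side="left"))
    lo, hi = _DECILE_EDGES[k], _DECILE_EDGES[k + 1]
    return f"{lo * 100:.0f}-{hi * 100:.0f}%"


def _stratum_labels(joined: pd.DataFrame, dimension: str) -> pd.Series:
    if dimension == "completeness":
        vals = joined["completeness"]
        return vals.map(lambda v: "unassessed" if pd.isna(v) else _completeness_label(v))
    if dimension == "timeliness":
        has = joined["_assessed"]
        return pd.Series(
            np.where(has, joined["timeliness"].map(_timeliness_label), "unassessed"),
            index=joined.index,
        )
    if dimension == "suitable":
        def lab(row):
            if not row["_assessed"]:
                return "unassessed"
            return "suitable" if bool(row["suitable"]) else "unsuitable"

        return joined.apply(lab, axis=1)
    raise InputError(
        f"unknown stratification dimension {dimension!r}; "
        "use 'completeness', 'timeliness' or 'suitable'"
    )


def _stratified(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    assessments: pd.DataFrame,
    dimension: str,
    direction: str,
    tolerance_weeks: int,
) -> pd.DataFrame:
    matched = match_warnings(reference, test, tolerance_weeks)
    if len(matched) == 0:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    ass = assessments[["municipality", "week", "completeness", "timeliness", "suitable"]].copy()
    ass["_assessed"] = True
    joined = matched.merge(ass, on=["municipality", "week"], how="left")
    joined["_assessed"] = joined["_assessed"].notna() & joined["_assessed"].astype(bool)
    joined["stratum"] = _stratum_labels(joined, dimension)
    grouped = (
        joined.groupby("stratum", as_index=False)
        .agg(n_reference=("concordant", "size"), n_concordant=("concordant", "sum"))
        .astype({"n_concordant": int})
    )
    grouped["proportion"] = grouped["n_concordant"] / grouped["n_reference"]
    grouped.insert(0, "direction", direction)
    return grouped[SUMMARY_COLUMNS]


def concordance_by_quality(
    warnings_backfilled: pd.DataFrame,
    warnings_realtime: pd.DataFrame,
    assessments: pd.DataFrame,
    dimension: str,
    directions: tuple[str, ...] = ("vs_backfilled", "vs_realtime"),
    tolerance_weeks: int = 0,
) -> pd.DataFrame:
    """Per-stratum concordance in one or both directions.

    Strata come from the real-time DQI at each warning's municipality-week:
    the nine completeness levels k/8, timeliness deciles, or the binary
    suitable flag.  Warnings with no matching assessment fall into an
    explicit "unassessed" stratum.
    """
    pairs = {
        "vs_backfilled": (warnings_backfilled, warnings_realtime),
        "vs_realtime": (warnings_realtime, warnings_backfilled),
    }
    frames = []
    for direction in directions:
        if direction not in pairs:
            raise InputError(f"unknown direction {direction!r}")
        ref, test = pairs[direction]
        frames.append(_stratified(ref, test, assessments, dimension, direction, tolerance_weeks))
    if not frames:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def group_municipalities_by_suitable_weeks(
    assessments: pd.DataFrame,
    bins: tuple[float, ...] = SUITABLE_WEEK_BINS,
    labels: tuple[str, ...] = SUITABLE_WEEK_LABELS,
) -> pd.DataFrame:
    """Group municipalities by their fraction of suitable assessed weeks.

    Bins are half-open, upper-closed: [0, .2], (.2, .4], (.4, .6],
    (.6, .8], (.8, 1].  Municipalities with no assessed weeks are labelled
    "unassessed".  Returns (municipality, suitable_fraction, group).
    """
    if len(bins) + 1 != len(labels):
        raise InputError("need exactly one label per bin")
    per_muni = assessments.groupby("municipality")["suitable"].agg(["mean", "size"])
    frac = per_muni["mean"]
    edges = [-np.inf, *bins, np.inf]
    idx = np.searchsorted(np.asarray(bins), frac.to_numpy(), side="left")
    del edges
    group = pd.Series([labels[i] for i in idx], index=frac.index, name="group")
    out = pd.DataFrame(
        {
            "municipality": frac.index,
            "suitable_fraction": frac.to_numpy(),
            "group": group.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def concordance_by_municipality_group(
    warnings_backfilled: pd.DataFrame,
    warnings_realtime: pd.DataFrame,
    assessments: pd.DataFrame,
    directions: tuple[str, ...] = ("vs_backfilled", "vs_realtime"),
    tolerance_weeks: int = 0,
) -> pd.DataFrame:
    """Concordance stratified by each municipality's suitable-week group."""
    groups = group_municipalities_by_suitable_weeks(assessments)
    gmap = dict(zip(groups["municipality"], groups["group"]))
    pairs = {
        "vs_backfilled": (warnings_backfilled, warnings_realtime),
        "vs_realtime": (warnings_realtime, warnings_backfilled),
    }
    frames = []
    for direction in directions:
        ref, test = pairs[direction]
        matched = match_warnings(ref, test, tolerance_weeks)
        if len(matched) == 0:
            continue
        matched["stratum"] = matched["municipality"].map(lambda m: gmap.get(m, "unassessed"))
        grouped = (
            matched.groupby("stratum", as_index=False)
            .agg(n_reference=("concordant", "size"), n_concordant=("concordant", "sum"))
            .astype({"n_concordant": int})
        )
        grouped["proportion"] = grouped["n_concordant"] / grouped["n_reference"]
        grouped.insert(0, "direction", direction)
        frames.append(grouped[SUMMARY_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def weekly_suitable_series(assessments: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-week proportion of municipalities graded suitable, with the
    median and interquartile range of that proportion over weeks."""
    if len(assessments) == 0:
        raise InputError("no assessments available")
    weekly = (
        assessments.groupby("week", as_index=False)
        .agg(n_assessed=("suitable", "size"), n_suitable=("suitable", "sum"))
        .astype({"n_suitable": int})
    )
    weekly["proportion"] = weekly["n_suitable"] / weekly["n_assessed"]
    p = weekly["proportion"].to_numpy()
    summary = {
        "median": float(np.median(p)),
        "q1": float(np.percentile(p, 25)),
        "q3": float(np.percentile(p, 75)),
    }
    return weekly, summary
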