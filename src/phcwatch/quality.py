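"""Data Quality Index (DQI): completeness, timeliness, suitability.

Both indicators are computed on an 8-week rolling window ending at and
including the evaluation week, on the real-time snapshot available that
week:

* **completeness** — the proportion of window weeks with any registered
  encounter visible in the snapshot (k/8 for k in 0..8);
* **timeliness** — the proportion of the visible encounter volume in the
  window registered within 2 weeks of the encounter; undefined when the
  window holds no visible volume.

A municipality-week is graded **suitable** when completeness reaches 100%
and timeliness at least 80% — the thresholds under which the early-warning
system's real-time output best agrees with the backfilled gold standard.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import InputError
from .views import DatasetView, EventCube

__all__ = [
    "completeness",
    "timeliness",
    "grade_dqi",
    "assess_all",
    "DEFAULT_WINDOW_LEN",
    "DEFAULT_LAG_CUT",
    "DEFAULT_COMPLETENESS_MIN",
    "DEFAULT_TIMELINESS_MIN",
]

DEFAULT_WINDOW_LEN = 8
DEFAULT_LAG_CUT = 2
DEFAULT_COMPLETENESS_MIN = 1.0
DEFAULT_TIMELINESS_MIN = 0.8


def _require_snapshot(view: DatasetView) -> None:
    if view.kind != "snapshot":
        raise InputError("quality indicators are defined on snapshot views")


def completeness(
    view: DatasetView,
    municipality: str,
    week: int,
    window_len: int = DEFAULT_WINDOW_LEN,
) -> float | None:
    """Proportion of window weeks with any visible encounter, or None when
    the window extends before the series start (assessment unavailable)."""
    _require_snapshot(view)
    if week < window_len - 1:
        return None
    window = range(week - window_len + 1, week + 1)
    sub = view.counts[
        (view.counts["municipality"] == municipality)
        & view.counts["week"].isin(window)
        & (view.counts["count"] > 0)
    ]
    return sub["week"].nunique() / window_len


def timeliness(
    view: DatasetView,
    municipality: str,
    week: int,
    window_len: int = DEFAULT_WINDOW_LEN,
    lag_cut: int = DEFAULT_LAG_CUT,
) -> float | None:
    """Proportion of visible window volume registered within ``lag_cut``
    weeks of the encounter.

    Returns NaN when no volume is visible in the window (undefined — the
    grade then falls to unsuitable), or None when the window extends
    before the series start.
    """
    _require_snapshot(view)
    if week < window_len - 1:
        return None
    if view.delays is None:
        raise InputError("snapshot view lacks delay detail")
    window = range(week - window_len + 1, week + 1)
    sub = view.delays[
        (view.delays["municipality"] == municipality) & view.delays["week"].isin(window)
    ]
    den = int(sub["count"].sum())
    if den == 0:
        return math.nan
    num = int(sub.loc[sub["delay"] <= lag_cut, "count"].sum())
    return num / den


def grade_dqi(
    completeness_value: float,
    timeliness_value: float | None,
    completeness_min: float = DEFAULT_COMPLETENESS_MIN,
    timeliness_min: float = DEFAULT_TIMELINESS_MIN,
) -> bool:
    """Suitable iff completeness and timeliness both reach their thresholds.

    An undefined timeliness (None or NaN) grades unsuitable: absence of
    evidence of quality is not evidence of quality.
    """
    if not 0 <= completeness_value <= 1:
        raise InputError(f"completeness must lie in [0, 1], got {completeness_value!r}")
    if timeliness_value is None or (
        isinstance(timeliness_value, float) and math.isnan(timeliness_value)
    ):
        return False
    return completeness_value >= completeness_min and timeliness_value >= timeliness_min


def assess_all(
    events: pd.DataFrame,
    *,
    municipalities: list[str] | None = None,
    n_weeks: int | None = None,
    window_len: int = DEFAULT_WINDOW_LEN,
    lag_cut: int = DEFAULT_LAG_CUT,
    completeness_min: float = DEFAULT_COMPLETENESS_MIN,
    timeliness_min: float = DEFAULT_TIMELINESS_MIN,
) -> pd.DataFrame:
    """Weekly DQI assessment per municipality on per-week snapshots.

    The week-``w`` assessment uses the snapshot as of week ``w`` — the
    data the early-warning system would have had that week.  Weeks whose
    window extends before the series start are skipped (not scaled).

    Returns a frame with columns ``municipality, week, completeness,
    timeliness, suitable`` (timeliness NaN when undefined).
    """
    cube = EventCube(events, municipalities=municipalities, n_weeks=n_weeks)
    rows: list[pd.DataFrame] = []
    munis = np.asarray(cube.municipalities)
    for w in range(window_len - 1, cube.n_weeks):
        win = slice(w - window_len + 1, w + 1)
        vis = cube.visible(w)[:, win]
        comp = (vis > 0).sum(axis=1) / window_len
        den = vis.sum(axis=1).astype(float)
        num = cube.timely_visible(w, lag_cut)[:, win].sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            tim = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        suitable = (comp >= completeness_min) & ~np.isnan(tim) & (tim >= timeliness_min)
        rows.append(
            pd.DataFrame(
                {
                    "municipality": munis,
                    "week": w,
                    "completeness": comp,
                    "timeliness": tim,
                    "suitable": suitable,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["municipality", "week", "completeness", "timeliness", "suitable"]
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["municipality", "week"]).reset_index(drop=True)
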