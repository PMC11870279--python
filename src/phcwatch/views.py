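"""Dataset views over registry events.

Two views of the same event stream matter for the evaluation design:

* the **backfilled** view — all events regardless of registration week,
  the retrospectively consolidated gold standard;
* a **snapshot** view as of week *S* — only events registered by *S*,
  what a weekly-updated early-warning system actually sees.

An :class:`EventCube` holds a dense municipality × encounter-week ×
registration-week array with cumulative sums over registration week, so
per-week snapshot queries (as needed by rolling quality assessment and
vintage detection) are O(1) array slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import InputError

__all__ = ["DatasetView", "backfilled_view", "snapshot_view", "count_matrix", "EventCube"]

EVENT_COLUMNS = ["municipality", "encounter_week", "registration_week", "count"]


def _check_events(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InputError(f"event frame missing columns: {missing}")
    if len(events):
        if (events["registration_week"] < events["encounter_week"]).any():
            raise InputError("registration_week must be >= encounter_week")
        if (events["count"] < 0).any():
            raise InputError("event counts must be nonnegative")


@dataclass
class DatasetView:
    """Weekly counts per municipality under one visibility regime.

    ``counts`` is long format (municipality, week, count); ``delays``
    (snapshot views only) additionally splits each week's visible volume
    by registration delay in whole weeks.
    """

    kind: str  # "backfilled" | "snapshot"
    counts: pd.DataFrame
    n_weeks: int
    as_of_week: int | None = None
    delays: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("backfilled", "snapshot"):
            raise InputError(f"unknown view kind {self.kind!r}")
        if self.kind == "snapshot" and self.as_of_week is None:
            raise InputError("snapshot views require as_of_week")

    @property
    def municipalities(self) -> list[str]:
        return sorted(self.counts["municipality"].unique())

    def total_encounters(self) -> int:
        return int(self.counts["count"].sum())


def backfilled_view(events: pd.DataFrame, n_weeks: int | None = None) -> DatasetView:
    """All events, regardless of registration week."""
    _check_events(events)
    counts = (
        events.groupby(["municipality", "encounter_week"], as_index=False)["count"]
        .sum()
        .rename(columns={"encounter_week": "week"})
    )
    if n_weeks is None:
        n_weeks = int(events["encounter_week"].max()) + 1 if len(events) else 0
    return DatasetView(kind="backfilled", counts=counts, n_weeks=n_weeks)


def snapshot_view(events: pd.DataFrame, as_of_week: int, n_weeks: int | None = None) -> DatasetView:
    """Events registered by ``as_of_week`` (inclusive), with delay detail."""
    _check_events(events)
    vis = events[events["registration_week"] <= as_of_week].copy()
    counts = (
        vis.groupby(["municipality", "encounter_week"], as_index=False)["count"]
        .sum()
        .rename(columns={"encounter_week": "week"})
    )
    vis["delay"] = vis["registration_week"] - vis["encounter_week"]
    delays = (
        vis.groupby(["municipality", "encounter_week", "delay"], as_index=False)["count"]
        .sum()
        .rename(columns={"encounter_week": "week"})
    )
    if n_weeks is None:
        n_weeks = int(events["encounter_week"].max()) + 1 if len(events) else 0
    return DatasetView(
        kind="snapshot", counts=counts, n_weeks=n_weeks, as_of_week=as_of_week, delays=delays
    )


def count_matrix(
    view: DatasetView, municipalities: list[str] | None = None, n_weeks: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Dense municipality × week count matrix, missing weeks filled as 0."""
    if municipalities is None:
        municipalities = view.municipalities
    if n_weeks is None:
        n_weeks = view.n_weeks
    idx = {m: i for i, m in enumerate(municipalities)}
    mat = np.zeros((len(municipalities), n_weeks), dtype=np.int64)
    sub = view.counts[view.counts["municipality"].isin(idx) & (view.counts["week"] < n_weeks)]
    if len(sub):
        mi = sub["municipality"].map(idx).to_numpy()
        np.add.at(mat, (mi, sub["week"].to_numpy()), sub["count"].to_numpy())
    return mat, list(municipalities)


class EventCube:
    """Dense cumulative event array for fast per-week snapshot queries."""

    def __init__(
        self,
        events: pd.DataFrame,
        municipalities: list[str] | None = None,
        n_weeks: int | None = None,
    ) -> None:
        _check_events(events)
        if municipalities is None:
            municipalities = sorted(events["municipality"].unique())
        if n_weeks is None:
            n_weeks = int(events["encounter_week"].max()) + 1 if len(events) else 0
        self.municipalities = list(municipalities)
        self.n_weeks = n_weeks
        idx = {m: i for i, m in enumerate(self.municipalities)}
        m_count = len(self.municipalities)

        raw = np.zeros((m_count, n_weeks, n_weeks), dtype=np.int64)
        total = np.zeros((m_count, n_weeks), dtype=np.int64)
        sub = events[events["municipality"].isin(idx)]
        if len(sub):
            m = sub["municipality"].map(idx).to_numpy()
            e = sub["encounter_week"].to_numpy()
            r = sub["registration_week"].to_numpy()
            c = sub["count"].to_numpy()
            if (e >= n_weeks).any():
                raise InputError("encounter_week beyond the study span")
            np.add.at(total, (m, e), c)
            vis = r < n_weeks
            np.add.at(raw, (m[vis], e[vis], r[vis]), c[vis])
        self._raw = raw
        # cumulative over registration week: [..., r] = volume registered by week r
        self._cum = np.cumsum(raw, axis=2)
        self.total = total  # backfilled counts (includes post-span amendments)
        self._timely_cache: dict[int, np.ndarray] = {}

    def visible(self, as_of_week: int) -> np.ndarray:
        """Counts per (municipality, encounter week) registered by ``as_of_week``."""
        if not 0 <= as_of_week < self.n_weeks:
            raise InputError(f"as_of_week {as_of_week} outside study span")
        return self._cum[:, :, as_of_week]

    def timely_visible(self, as_of_week: int, lag_cut: int) -> np.ndarray:
        """As :meth:`visible` but restricted to registration delay <= ``lag_cut``."""
        cum = self._timely_cache.get(lag_cut)
        if cum is None:
            e = np.arange(self.n_weeks)[:, None]
            r = np.arange(self.n_weeks)[None, :]
            mask = (r >= e) & (r - e <= lag_cut)
            cum = np.cumsum(self._raw * mask[None, :, :], axis=2)
            self._timely_cache[lag_cut] = cum
        return cum[:, :, as_of_week]
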