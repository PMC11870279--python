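"""EARS-C2 aberration detection on weekly encounter counts.

The C2 statistic compares the current week's count with the mean of a
short baseline window separated from it by a guard band:

    C2(t) = (y_t - mean(y_{t-g-L} .. y_{t-g-1})) / sd(baseline)

with baseline length L (default 7), guard g (default 2) and sample
standard deviation (denominator L-1).  An alarm is raised when the
statistic reaches the threshold (default 3 standard deviations).  When
the baseline is perfectly flat (sd = 0) and no sd floor is configured,
any count above the baseline mean alarms (statistic reported as +inf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import InputError
from .views import DatasetView, EventCube, count_matrix

__all__ = ["DetectorConfig", "ears_c2", "run_ews", "run_ews_realtime"]

WARNING_COLUMNS = ["municipality", "week", "source", "statistic"]


@dataclass(frozen=True)
class DetectorConfig:
    baseline_len: int = 7
    guard: int = 2
    threshold: float = 3.0
    min_baseline_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_len < 2:
            raise InputError("baseline_len must be >= 2 (sample sd needs two points)")
        if self.guard < 0:
            raise InputError("guard must be nonnegative")
        if self.threshold <= 0:
            raise InputError("threshold must be positive")
        if self.min_baseline_sd < 0:
            raise InputError("min_baseline_sd must be nonnegative")

    @property
    def first_week(self) -> int:
        """Earliest evaluable week index."""
        return self.baseline_len + self.guard


def _c2_from_baseline(
    current: np.ndarray, baseline: np.ndarray, config: DetectorConfig
) -> np.ndarray:
    """C2 statistics given current values (...,) and baselines (..., L).

    sd = 0 with no floor maps to +/-inf (0 on exact ties) so the single
    rule `statistic >= threshold` decides the alarm everywhere.
    """
    mu = baseline.mean(axis=-1)
    sd = baseline.std(axis=-1, ddof=1)
    denom = np.maximum(sd, config.min_baseline_sd)
    diff = current - mu
    safe = np.where(denom > 0, denom, 1.0)
    stat = diff / safe
    degenerate = denom == 0
    if np.any(degenerate):
        stat = np.where(degenerate & (diff > 0), np.inf, stat)
        stat = np.where(degenerate & (diff < 0), -np.inf, stat)
        stat = np.where(degenerate & (diff == 0), 0.0, stat)
    return stat


def _c2_matrix(matrix: np.ndarray, config: DetectorConfig) -> np.ndarray:
    """C2 statistics for every municipality (rows) and week; NaN where the
    week is not evaluable (fewer than baseline_len + guard prior weeks)."""
    m_count, n_weeks = matrix.shape
    first = config.first_week
    stats = np.full((m_count, n_weeks), np.nan)
    if n_weeks <= first:
        return stats
    windows = np.lib.stride_tricks.sliding_window_view(matrix, config.baseline_len, axis=1)
    # baseline for week t starts at t - guard - baseline_len
    baselines = windows[:, : n_weeks - first, :].astype(float)
    stats[:, first:] = _c2_from_baseline(matrix[:, first:].astype(float), baselines, config)
    return stats


def ears_c2(series, config: DetectorConfig = DetectorConfig()) -> pd.DataFrame:
    """Evaluate the C2 statistic along one weekly count series.

    Returns a frame (week, statistic, alarm) over the evaluable weeks;
    empty when the series is too short for any evaluation.
    """
    arr = np.asarray(series, dtype=float).reshape(1, -1)
    stats = _c2_matrix(arr, config)[0]
    weeks = np.arange(arr.shape[1])
    ok = ~np.isnan(stats)
    return pd.DataFrame(
        {
            "week": weeks[ok],
            "statistic": stats[ok],
            "alarm": stats[ok] >= config.threshold,
        }
    )


def run_ews(
    view: DatasetView,
    config: DetectorConfig = DetectorConfig(),
    source: str | None = None,
) -> pd.DataFrame:
    """Apply C2 per municipality to a full weekly series (one fixed view).

    Missing municipality-weeks count as 0 — absence of registration is
    exactly the failure mode under study.  Returns the warning frame
    (municipality, week, source, statistic), alarms only.
    """
    if source is None:
        source = "backfilled" if view.kind == "backfilled" else "realtime"
    matrix, munis = count_matrix(view)
    stats = _c2_matrix(matrix, config)
    alarm = np.nan_to_num(stats, nan=-np.inf) >= config.threshold
    mi, wi = np.nonzero(alarm)
    return pd.DataFrame(
        {
            "municipality": np.asarray(munis)[mi],
            "week": wi,
            "source": source,
            "statistic": stats[mi, wi],
        }
    ).sort_values(["municipality", "week"]).reset_index(drop=True)


def run_ews_realtime(
    events: pd.DataFrame,
    config: DetectorConfig = DetectorConfig(),
    *,
    municipalities: list[str] | None = None,
    n_weeks: int | None = None,
    mode: str = "vintage",
) -> pd.DataFrame:
    """Real-time detection from registry events.

    ``mode="vintage"`` (default) judges each week ``w`` with the snapshot
    as of ``w`` — the weekly operation of a live system.  ``mode="final"``
    applies detection once to the last in-span snapshot.
    """
    if mode == "final":
        from .views import snapshot_view

        if n_weeks is None:
            n_weeks = int(events["encounter_week"].max()) + 1 if len(events) else 0
        view = snapshot_view(events, as_of_week=n_weeks - 1, n_weeks=n_weeks)
        if municipalities is not None:
            matrix, munis = count_matrix(view, municipalities=municipalities)
            stats = _c2_matrix(matrix, config)
            alarm = np.nan_to_num(stats, nan=-np.inf) >= config.threshold
            mi, wi = np.nonzero(alarm)
            return pd.DataFrame(
                {
                    "municipality": np.asarray(munis)[mi],
                    "week": wi,
                    "source": "realtime",
                    "statistic": stats[mi, wi],
                }
            ).sort_values(["municipality", "week"]).reset_index(drop=True)
        return run_ews(view, config, source="realtime")
    if mode != "vintage":
        raise InputError(f"unknown real-time mode {mode!r}; use 'vintage' or 'final'")

    cube = EventCube(events, municipalities=municipalities, n_weeks=n_weeks)
    munis = np.asarray(cube.municipalities)
    rows: list[pd.DataFrame] = []
    for w in range(config.first_week, cube.n_weeks):
        snap = cube.visible(w)
        current = snap[:, w].astype(float)
        baseline = snap[:, w - config.guard - config.baseline_len : w - config.guard].astype(float)
        stats = _c2_from_baseline(current, baseline, config)
        hit = stats >= config.threshold
        if hit.any():
            rows.append(
                pd.DataFrame(
                    {
                        "municipality": munis[hit],
                        "week": w,
                        "source": "realtime",
                        "statistic": stats[hit],
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=WARNING_COLUMNS).astype({"week": np.int64})
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["municipality", "week"]).reset_index(drop=True)
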