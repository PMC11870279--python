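"""Synthetic encounter-registry generator.

Produces (i) ground-truth weekly influenza-like-illness (ILI) encounter
counts per municipality, with seasonality and injected outbreaks, and
(ii) registry events describing when each slice of an encounter-week's
volume was first registered in the database.  Summing event counts over
registration weeks recovers the true counts exactly, so the backfilled
view reconstructed from events is conservative by construction, while
real-time snapshots diverge from it in controlled, profile-dependent ways.

Randomness uses one master seed with per-municipality substreams
(``default_rng([seed, municipality_index, stage])``) so changing the
number of municipalities never reshuffles the series of the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AMENDMENT_WINDOW_WEEKS,
    InputError,
    SimulationConfig,
    make_config,
)

__all__ = [
    "TrueSeries",
    "simulate_truth",
    "simulate_registration",
    "simulate_mixed",
    "truth_to_frame",
    "municipality_id",
]

_STAGE_TRUTH = 0
_STAGE_REGISTRATION = 1


def municipality_id(index: int) -> str:
    return f"m{index:05d}"


@dataclass
class TrueSeries:
    """Ground-truth weekly counts and outbreak labels for one municipality."""

    municipality: str
    counts: np.ndarray  # nonnegative integers, length n_weeks
    outbreak_flags: np.ndarray  # booleans, length n_weeks

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.outbreak_flags = np.asarray(self.outbreak_flags, dtype=bool)
        if self.counts.shape != self.outbreak_flags.shape:
            raise InputError("counts and outbreak_flags must have the same length")
        if (self.counts < 0).any():
            raise InputError("counts must be nonnegative")


def _seasonal_multiplier(n_weeks: int, amplitude: float) -> np.ndarray:
    # One annual sine cycle on the epidemiological-week grid; amplitude < 1
    # keeps the mean strictly positive.
    w = np.arange(n_weeks)
    return 1.0 + amplitude * np.sin(2.0 * np.pi * w / 52.0)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and size ``dispersion``.

    Var = mean + mean^2 / dispersion; dispersion = inf gives Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if np.isinf(dispersion):
        return rng.poisson(mean).astype(np.int64)
    counts = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = dispersion / (dispersion + mean[pos])
        counts[pos] = rng.negative_binomial(dispersion, p)
    return counts


def _outbreak_flags(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Sequential outbreak process: a new outbreak cannot start while one
    is active; each lasts ``outbreak_duration_weeks`` (truncated at span end)."""
    u = rng.random(config.n_weeks)
    flags = np.zeros(config.n_weeks, dtype=bool)
    remaining = 0
    for w in range(config.n_weeks):
        start = remaining == 0 and (
            u[w] < config.outbreak_prob_per_week or w == config.forced_outbreak_week
        )
        if start:
            remaining = config.outbreak_duration_weeks
        if remaining > 0:
            flags[w] = True
            remaining -= 1
    return flags


def simulate_truth(
    config: SimulationConfig, *, municipality_offset: int = 0
) -> list[TrueSeries]:
    """Simulate ground-truth weekly ILI encounter counts per municipality.

    ``municipality_offset`` shifts the municipality indices (and their
    random substreams), allowing disjoint cohorts with different
    registration behaviour to be simulated and concatenated.
    """
    seasonal = _seasonal_multiplier(config.n_weeks, config.seasonal_amplitude)
    out: list[TrueSeries] = []
    for i in range(config.n_municipalities):
        idx = municipality_offset + i
        rng = np.random.default_rng([config.seed, idx, _STAGE_TRUTH])
        flags = _outbreak_flags(rng, config)
        mean = config.baseline_rate * seasonal * np.where(flags, config.outbreak_fold, 1.0)
        counts = _draw_counts(rng, mean, config.dispersion)
        out.append(TrueSeries(municipality_id(idx), counts, flags))
    return out


def truth_to_frame(truth: list[TrueSeries]) -> pd.DataFrame:
    """Long-format ground truth: municipality, week, count, outbreak_flag."""
    frames = [
        pd.DataFrame(
            {
                "municipality": ts.municipality,
                "week": np.arange(len(ts.counts)),
                "count": ts.counts,
                "outbreak_flag": ts.outbreak_flags.astype(int),
            }
        )
        for ts in truth
    ]
    if not frames:
        return pd.DataFrame(columns=["municipality", "week", "count", "outbreak_flag"])
    return pd.concat(frames, ignore_index=True)


def _batch_to_monthly(reg_weeks: np.ndarray) -> np.ndarray:
    # Registration deferred to the next week index congruent to 3 (mod 4):
    # the simplest week-grid emulation of "update at least on a monthly basis".
    return reg_weeks + ((3 - reg_weeks) % 4)


def simulate_registration(
    truth: list[TrueSeries],
    config: SimulationConfig,
    *,
    municipality_offset: int = 0,
) -> pd.DataFrame:
    """Partition each true encounter-week count across registration weeks.

    Returns a registry-event frame with columns
    ``municipality, encounter_week, registration_week, count`` where, for
    every (municipality, encounter_week), event counts sum exactly to the
    true count.  Delays are drawn from ``delay_pmf``; monthly uploaders
    have registrations batched to the next week index that is 3 (mod 4);
    dropped-out municipality-weeks land 1..16 weeks past the final study
    week (late amendments, visible only in the backfilled view).
    """
    if len(truth) != config.n_municipalities:
        raise InputError(
            f"truth holds {len(truth)} municipalities but config expects "
            f"{config.n_municipalities}"
        )
    n_weeks = config.n_weeks
    pmf = np.asarray(config.delay_pmf, dtype=float)
    delays = np.arange(len(pmf))
    last_week = n_weeks - 1

    rows_m: list[np.ndarray] = []
    cols: dict[str, list[np.ndarray]] = {"enc": [], "reg": [], "cnt": []}
    munis: list[str] = []
    for i, ts in enumerate(truth):
        if len(ts.counts) != n_weeks:
            raise InputError(
                f"{ts.municipality}: series length {len(ts.counts)} != n_weeks {n_weeks}"
            )
        idx = municipality_offset + i
        rng = np.random.default_rng([config.seed, idx, _STAGE_REGISTRATION])
        monthly = rng.random() < config.monthly_uploader_fraction
        dropout = rng.random(n_weeks) < config.dropout_prob
        parts = rng.multinomial(ts.counts, pmf)  # (n_weeks, n_delays)

        enc_list: list[np.ndarray] = []
        reg_list: list[np.ndarray] = []
        cnt_list: list[np.ndarray] = []

        regular = ~dropout & (ts.counts > 0)
        if regular.any():
            e_idx, d_idx = np.nonzero(parts[regular])
            enc = np.flatnonzero(regular)[e_idx]
            cnt = parts[regular][e_idx, d_idx]
            reg = enc + delays[d_idx]
            if monthly:
                reg = _batch_to_monthly(reg)
            enc_list.append(enc)
            reg_list.append(reg)
            cnt_list.append(cnt)

        dropped = dropout & (ts.counts > 0)
        if dropped.any():
            enc = np.flatnonzero(dropped)
            reg = last_week + rng.integers(1, AMENDMENT_WINDOW_WEEKS + 1, size=enc.size)
            enc_list.append(enc)
            reg_list.append(reg)
            cnt_list.append(ts.counts[enc])

        if enc_list:
            enc = np.concatenate(enc_list)
            reg = np.concatenate(reg_list)
            cnt = np.concatenate(cnt_list)
            cols["enc"].append(enc)
            cols["reg"].append(reg)
            cols["cnt"].append(cnt)
            munis.extend([ts.municipality] * enc.size)

    if not munis:
        return pd.DataFrame(
            columns=["municipality", "encounter_week", "registration_week", "count"]
        ).astype({"encounter_week": np.int64, "registration_week": np.int64, "count": np.int64})

    events = pd.DataFrame(
        {
            "municipality": munis,
            "encounter_week": np.concatenate(cols["enc"]),
            "registration_week": np.concatenate(cols["reg"]),
            "count": np.concatenate(cols["cnt"]),
        }
    )
    events = (
        events.groupby(["municipality", "encounter_week", "registration_week"], as_index=False)[
            "count"
        ]
        .sum()
        .sort_values(["municipality", "encounter_week", "registration_week"])
        .reset_index(drop=True)
    )
    return events


def simulate_mixed(
    n_municipalities: int,
    *,
    profiles: tuple[str, ...] = ("prompt", "poor"),
    seed: int = 0,
    **base_overrides,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Simulate a cohort split evenly across quality profiles.

    Truth parameters are shared; only registration behaviour differs by
    profile.  Returns (truth frame, events frame, municipality→profile map).
    """
    if n_municipalities < len(profiles):
        raise InputError("need at least one municipality per profile")
    sizes = [n_municipalities // len(profiles)] * len(profiles)
    sizes[-1] += n_municipalities - sum(sizes)

    truth_frames: list[pd.DataFrame] = []
    event_frames: list[pd.DataFrame] = []
    profile_map: dict[str, str] = {}
    offset = 0
    for profile, size in zip(profiles, sizes):
        cfg = make_config(size, profile=profile, seed=seed, **base_overrides)
        truth = simulate_truth(cfg, municipality_offset=offset)
        events = simulate_registration(truth, cfg, municipality_offset=offset)
        truth_frames.append(truth_to_frame(truth))
        event_frames.append(events)
        for ts in truth:
            profile_map[ts.municipality] = profile
        offset += size
    truth_df = pd.concat(truth_frames, ignore_index=True)
    events_df = pd.concat(event_frames, ignore_index=True)
    return truth_df, events_df, profile_map
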