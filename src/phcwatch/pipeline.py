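"""End-to-end orchestration: simulate → assess → detect → evaluate → report.

Each stage reads and writes the plain-text interfaces in :mod:`phcwatch.io`,
so stages are independently runnable; :func:`run_all` chains them and
records a manifest (config snapshot, seed, per-stage row counts, file
paths).  Two runs with the same configuration produce byte-identical
outputs apart from the manifest timestamps.
"""

from __future__ import annotations

import logging
import time
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .concordance import (
    concordance_by_municipality_group,
    concordance_by_quality,
    concordance_summary,
    weekly_suitable_series,
)
from .config import ConfigError, InputError, PROFILES, make_config
from .detection import DetectorConfig, run_ews, run_ews_realtime
from .io import (
    write_assessments,
    write_concordance,
    write_events,
    write_json,
    write_truth,
    write_warnings,
)
from .quality import assess_all
from .report import build_report, summarize_dataset
from .synthetic import simulate_mixed, simulate_registration, simulate_truth, truth_to_frame
from .views import backfilled_view

__all__ = ["DEFAULT_RUN_CONFIG", "validate_run_config", "run_all"]

log = logging.getLogger("phcwatch")

DEFAULT_RUN_CONFIG: dict = {
    "profile": "mixed",
    "n_municipalities": 50,
    "n_weeks": 23,
    "seed": 0,
    "simulation": {},  # SimulationConfig overrides (baseline_rate, delay_pmf, ...)
    "quality": {
        "window_len": 8,
        "lag_cut": 2,
        "completeness_min": 1.0,
        "timeliness_min": 0.8,
    },
    "detector": {
        "baseline_len": 7,
        "guard": 2,
        "threshold": 3.0,
        "min_baseline_sd": 0.0,
    },
    "concordance": {
        "directions": ["vs_backfilled", "vs_realtime"],
        "tolerance_weeks": 0,
    },
    "realtime_mode": "vintage",
}

_VALID_PROFILES = tuple(sorted(PROFILES)) + ("mixed",)


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        where = f"{path}{key}"
        if key not in defaults and path and defaults:
            # free-form sections (e.g. simulation overrides) have empty defaults
            raise ConfigError(f"{where}: unknown configuration key")
        if isinstance(defaults.get(key), dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{where}: expected a mapping")
            out[key] = _merge(defaults[key], value, f"{where}.")
        else:
            out[key] = value
    return out


def validate_run_config(config: dict) -> dict:
    """Merge with defaults and check the schema; errors carry field paths."""
    unknown = set(config) - set(DEFAULT_RUN_CONFIG)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = _merge(DEFAULT_RUN_CONFIG, config)
    if cfg["profile"] is not None and cfg["profile"] not in _VALID_PROFILES:
        raise ConfigError(
            f"profile: must be one of {list(_VALID_PROFILES)} or null, got {cfg['profile']!r}"
        )
    for key in ("n_municipalities", "n_weeks"):
        if not isinstance(cfg[key], int) or cfg[key] < 1:
            raise ConfigError(f"{key}: must be a positive integer, got {cfg[key]!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError(f"seed: must be an integer, got {cfg['seed']!r}")
    q = cfg["quality"]
    if not isinstance(q["window_len"], int) or q["window_len"] < 1:
        raise ConfigError(f"quality.window_len: must be a positive integer, got {q['window_len']!r}")
    if not isinstance(q["lag_cut"], int) or q["lag_cut"] < 0:
        raise ConfigError(f"quality.lag_cut: must be a nonnegative integer, got {q['lag_cut']!r}")
    for key in ("completeness_min", "timeliness_min"):
        if not 0 <= q[key] <= 1:
            raise ConfigError(f"quality.{key}: must lie in [0, 1], got {q[key]!r}")
    if cfg["realtime_mode"] not in ("vintage", "final"):
        raise ConfigError(
            f"realtime_mode: must be 'vintage' or 'final', got {cfg['realtime_mode']!r}"
        )
    c = cfg["concordance"]
    for d in c["directions"]:
        if d not in ("vs_backfilled", "vs_realtime"):
            raise ConfigError(f"concordance.directions: unknown direction {d!r}")
    if not isinstance(c["tolerance_weeks"], int) or c["tolerance_weeks"] < 0:
        raise ConfigError(
            f"concordance.tolerance_weeks: must be a nonnegative integer, "
            f"got {c['tolerance_weeks']!r}"
        )
    # DetectorConfig and SimulationConfig run their own domain checks;
    # surface them now, before any stage executes
    try:
        DetectorConfig(**cfg["detector"])
    except (InputError, TypeError) as exc:
        raise ConfigError(f"detector: {exc}") from None
    sim = dict(cfg["simulation"])
    sim["seed"] = cfg["seed"]
    sim["n_weeks"] = cfg["n_weeks"]
    profile = None if cfg["profile"] in (None, "mixed") else cfg["profile"]
    try:
        make_config(cfg["n_municipalities"], profile=profile, **sim)
    except TypeError as exc:
        raise ConfigError(f"simulation: {exc}") from None
    return cfg


def _simulate_stage(cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    sim = dict(cfg["simulation"])
    sim["seed"] = cfg["seed"]
    sim["n_weeks"] = cfg["n_weeks"]
    if cfg["profile"] == "mixed":
        return simulate_mixed(cfg["n_municipalities"], profiles=("prompt", "poor"), **sim)
    config = make_config(cfg["n_municipalities"], profile=cfg["profile"], **sim)
    truth = simulate_truth(config)
    events = simulate_registration(truth, config)
    profile = cfg["profile"] or "custom"
    return truth_to_frame(truth), events, {t.municipality: profile for t in truth}


def run_all(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute every stage, write all artifacts under ``out_dir``, and
    return the run manifest (also written as manifest.json)."""
    started = datetime.now(timezone.utc).isoformat()
    t0 = time.perf_counter()
    cfg = validate_run_config(dict(config))
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulate: profile=%s n_municipalities=%d n_weeks=%d seed=%d",
             cfg["profile"], cfg["n_municipalities"], cfg["n_weeks"], cfg["seed"])
    truth_df, events_df, profile_map = _simulate_stage(cfg)
    municipalities = sorted(profile_map)
    n_weeks = cfg["n_weeks"]

    log.info("assess: %d events over %d municipalities", len(events_df), len(municipalities))
    q = cfg["quality"]
    assessments = assess_all(
        events_df,
        municipalities=municipalities,
        n_weeks=n_weeks,
        window_len=q["window_len"],
        lag_cut=q["lag_cut"],
        completeness_min=q["completeness_min"],
        timeliness_min=q["timeliness_min"],
    )

    detector = DetectorConfig(**cfg["detector"])
    back = backfilled_view(events_df, n_weeks=n_weeks)
    warnings_back = run_ews(back, detector, source="backfilled")
    warnings_rt = run_ews_realtime(
        events_df,
        detector,
        municipalities=municipalities,
        n_weeks=n_weeks,
        mode=cfg["realtime_mode"],
    )
    warnings = pd.concat([warnings_back, warnings_rt], ignore_index=True)
    log.info("detect: %d backfilled, %d real-time warnings", len(warnings_back), len(warnings_rt))

    directions = tuple(cfg["concordance"]["directions"])
    tol = cfg["concordance"]["tolerance_weeks"]
    overall = [
        concordance_summary(
            *(
                (warnings_back, warnings_rt)
                if d == "vs_backfilled"
                else (warnings_rt, warnings_back)
            ),
            direction=d,
            tolerance_weeks=tol,
        )
        for d in directions
    ]
    by_comp = concordance_by_quality(
        warnings_back, warnings_rt, assessments, "completeness", directions, tol
    )
    by_tim = concordance_by_quality(
        warnings_back, warnings_rt, assessments, "timeliness", directions, tol
    )
    by_suit = concordance_by_quality(
        warnings_back, warnings_rt, assessments, "suitable", directions, tol
    )
    by_group = concordance_by_municipality_group(
        warnings_back, warnings_rt, assessments, directions, tol
    )
    weekly, weekly_summary = weekly_suitable_series(assessments)
    concordance_df = pd.concat(
        [pd.DataFrame(overall), by_comp, by_tim, by_suit, by_group], ignore_index=True
    )

    dataset_summary = summarize_dataset(back, n_weeks, warnings=warnings_back)
    report = build_report(
        dataset_summary=dataset_summary,
        overall=overall,
        by_completeness=by_comp,
        by_timeliness=by_tim,
        by_suitable=by_suit,
        by_municipality_group=by_group,
        weekly_suitable=weekly,
        weekly_suitable_summary=weekly_summary,
    )

    files = {
        "truth.csv": (write_truth, truth_df),
        "events.csv": (write_events, events_df),
        "assessments.csv": (write_assessments, assessments),
        "warnings.csv": (write_warnings, warnings),
        "concordance.csv": (write_concordance, concordance_df),
    }
    outputs = {}
    for name, (writer, frame) in files.items():
        path = out / name
        writer(frame, path)
        outputs[name] = {"path": str(path), "rows": int(len(frame))}
    write_json(report, out / "report.json")
    outputs["report.json"] = {"path": str(out / "report.json"), "rows": None}

    manifest = {
        "package": "phcwatch",
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "elapsed_seconds": round(time.perf_counter() - t0, 3),
        "outputs": outputs,
    }
    write_json(manifest, out / "manifest.json")
    log.info("done in %.2fs; outputs under %s", manifest["elapsed_seconds"], out)
    return manifest
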