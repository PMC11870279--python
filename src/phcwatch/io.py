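"""Plain-text interchange formats for every pipeline stage.

All stage outputs are small CSVs with fixed headers so stages are
independently runnable and testable:

* events       — municipality,encounter_week,registration_week,count
* truth        — municipality,week,count,outbreak_flag
* assessments  — municipality,week,completeness,timeliness,suitable
                 (timeliness empty when undefined)
* warnings     — municipality,week,source,statistic
* concordance  — direction,stratum,n_reference,n_concordant,proportion
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import InputError

__all__ = [
    "write_events",
    "read_events",
    "write_truth",
    "read_truth",
    "write_assessments",
    "read_assessments",
    "write_warnings",
    "read_warnings",
    "write_concordance",
    "read_concordance",
    "write_json",
    "load_run_config",
]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{what} frame missing columns: {missing}")


def write_events(events: pd.DataFrame, path) -> None:
    cols = ["municipality", "encounter_week", "registration_week", "count"]
    _require(events, cols, "event")
    events[cols].to_csv(path, index=False)

def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "municipality": str,
            "encounter_week": np.int64,
            "registration_week": np.int64,
            "count": np.int64,
        },
    )
    _require(df, ["municipality", "encounter_week", "registration_week", "count"], "event")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    cols = ["municipality", "week", "count", "outbreak_flag"]
    _require(truth, cols, "truth")
    out = truth[cols].copy()
    out["outbreak_flag"] = out["outbreak_flag"].astype(int)
    out.to_csv(path, index=False)

def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"municipality": str, "week": np.int64, "count": np.int64, "outbreak_flag": np.int64},
    )
    _require(df, ["municipality", "week", "count", "outbreak_flag"], "truth")
    return df


def write_assessments(assessments: pd.DataFrame, path) -> None:
    cols = ["municipality", "week", "completeness", "timeliness", "suitable"]
    _require(assessments, cols, "assessment")
    out = assessments[cols].copy()
    out["suitable"] = out["suitable"].map({True: "true", False: "false"})
    out.to_csv(path, index=False, float_format="%.6f")  # NaN timeliness -> empty field

def read_assessments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"municipality": str, "week": np.int64})
    _require(df, ["municipality", "week", "completeness", "timeliness", "suitable"], "assessment")
    df["suitable"] = df["suitable"].map({"true": True, "false": False, True: True, False: False})
    return df


def write_warnings(warnings: pd.DataFrame, path) -> None:
    cols = ["municipality", "week", "source", "statistic"]
    _require(warnings, cols, "warning")
    warnings[cols].to_csv(path, index=False)

def read_warnings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"municipality": str, "source": str})
    _require(df, ["municipality", "week", "source", "statistic"], "warning")
    df["week"] = df["week"].astype(np.int64)
    return df


def write_concordance(summaries: pd.DataFrame, path) -> None:
    cols = ["direction", "stratum", "n_reference", "n_concordant", "proportion"]
    _require(summaries, cols, "concordance")
    summaries[cols].to_csv(path, index=False)

def read_concordance(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"direction": str, "stratum": str})
    _require(df, ["direction", "stratum", "n_reference", "n_concordant", "proportion"], "concordance")
    return df


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_run_config(path) -> dict:
    """Read a YAML (or JSON) run-configuration file into a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InputError(f"run configuration must be a mapping, got {type(cfg).__name__}")
    return cfg
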