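"""Dataset summaries and the run report."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import InputError
from .views import DatasetView

__all__ = ["average_per_week", "summarize_dataset", "warnings_per_municipality", "build_report"]


def average_per_week(total: int, n_weeks: int) -> int | float:
    """Average weekly volume; an exact integer is returned as int."""
    if n_weeks < 1:
        raise InputError("n_weeks must be >= 1")
    if total % n_weeks == 0:
        return total // n_weeks
    return total / n_weeks


def warnings_per_municipality(
    warnings: pd.DataFrame, municipalities: list[str]
) -> dict:
    """Median and IQR of the warning count per municipality (zeros included)."""
    counts = pd.Series(0, index=pd.Index(municipalities, name="municipality"), dtype=float)
    if len(warnings):
        observed = warnings.groupby("municipality")["week"].size()
        counts.loc[observed.index.intersection(counts.index)] = observed
    arr = counts.to_numpy()
    return {
        "median": float(np.median(arr)) if arr.size else float("nan"),
        "q1": float(np.percentile(arr, 25)) if arr.size else float("nan"),
        "q3": float(np.percentile(arr, 75)) if arr.size else float("nan"),
    }


def summarize_dataset(
    view: DatasetView, n_weeks: int, warnings: pd.DataFrame | None = None
) -> dict:
    """Totals for one dataset view: total encounters, weekly average, and
    (when warnings are given) the per-municipality warning median/IQR."""
    total = view.total_encounters()
    out = {
        "total_encounters": total,
        "average_per_week": average_per_week(total, n_weeks),
        "n_weeks": n_weeks,
        "n_municipalities": len(view.municipalities),
    }
    if warnings is not None:
        out["warnings_per_municipality"] = warnings_per_municipality(
            warnings, view.municipalities
        )
    return out


def build_report(
    *,
    dataset_summary: dict,
    overall: list[dict],
    by_completeness: pd.DataFrame,
    by_timeliness: pd.DataFrame,
    by_suitable: pd.DataFrame,
    by_municipality_group: pd.DataFrame,
    weekly_suitable: pd.DataFrame,
    weekly_suitable_summary: dict,
) -> dict:
    """Assemble the JSON-serialisable run report."""

    def records(df: pd.DataFrame) -> list[dict]:
        out = df.copy()
        if "proportion" in out:
            out["proportion"] = out["proportion"].astype(float).where(out["proportion"].notna(), None)
        return out.to_dict(orient="records")

    return {
        "dataset": dataset_summary,
        "concordance": {
            "overall": overall,
            "by_completeness": records(by_completeness),
            "by_timeliness": records(by_timeliness),
            "by_suitable": records(by_suitable),
            "by_municipality_group": records(by_municipality_group),
        },
        "weekly_suitable": {
            "series": records(weekly_suitable),
            "summary": weekly_suitable_summary,
        },
    }
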