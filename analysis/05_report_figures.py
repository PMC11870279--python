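"""Assemble the JSON report and summary figures.

Writes report.json (dataset totals, concordance by stratum, weekly
suitable series) and two figures: concordance by completeness level and
the weekly proportion of suitable municipalities.
"""

import json

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import phcwatch as pw
from phcwatch.io import read_assessments, read_events, read_warnings, write_json

from _common import N_WEEKS, OUT


def main() -> None:
    events = read_events(OUT / "events.csv")
    warnings = read_warnings(OUT / "warnings.csv")
    assessments = read_assessments(OUT / "assessments.csv")
    wb = warnings[warnings["source"] == "backfilled"]
    wr = warnings[warnings["source"] == "realtime"]

    back = pw.backfilled_view(events, n_weeks=N_WEEKS)
    weekly, weekly_summary = pw.weekly_suitable_series(assessments)
    by_comp = pw.concordance_by_quality(wb, wr, assessments, "completeness")
    report = pw.build_report(
        dataset_summary=pw.summarize_dataset(back, N_WEEKS, warnings=wb),
        overall=[
            pw.concordance_summary(wb, wr, "vs_backfilled"),
            pw.concordance_summary(wr, wb, "vs_realtime"),
        ],
        by_completeness=by_comp,
        by_timeliness=pw.concordance_by_quality(wb, wr, assessments, "timeliness"),
        by_suitable=pw.concordance_by_quality(wb, wr, assessments, "suitable"),
        by_municipality_group=pw.concordance_by_municipality_group(wb, wr, assessments),
        weekly_suitable=weekly,
        weekly_suitable_summary=weekly_summary,
    )
    write_json(report, OUT / "report.json")

    figdir = OUT / "figures"
    figdir.mkdir(exist_ok=True)

    sub = by_comp[by_comp["direction"] == "vs_realtime"].copy()
    sub = sub[sub["stratum"].str.contains("/")]
    sub["level"] = sub["stratum"].str.split("/").str[0].astype(int)
    sub = sub.sort_values("level")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(sub["level"], sub["proportion"], color="#29527a")
    ax.set_xlabel("completeness level (weeks with any register, out of 8)")
    ax.set_ylabel("proportion of real-time warnings concordant")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(figdir / "concordance_by_completeness.png", dpi=150)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(weekly["week"], weekly["proportion"], marker="o", color="#1f77b4")
    ax.axhline(weekly_summary["median"], ls="--", color="gray",
               label=f"median {weekly_summary['median']:.0%}")
    ax.set_xlabel("epidemiological week index")
    ax.set_ylabel("municipalities with suitable DQI")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "weekly_suitable.png", dpi=150)

    print(f"report written to {OUT / 'report.json'}")
    print(f"dataset: {report['dataset']['total_encounters']} encounters, "
          f"average {report['dataset']['average_per_week']:.0f}/week")
    print(f"figures under {figdir}")


if __name__ == "__main__":
    main()
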