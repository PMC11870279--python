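"""Weekly DQI assessment of the simulated registry.

Computes completeness, timeliness and the suitable/unsuitable grade per
municipality-week on per-week snapshots, writes assessments.csv, and
summarises the weekly proportion of suitable municipalities (median and
IQR over weeks) and the suitable fraction per upload profile.
"""

import pandas as pd

import phcwatch as pw
from phcwatch.io import read_events, read_truth, write_assessments

from _common import N_WEEKS, OUT


def main() -> None:
    events = read_events(OUT / "events.csv")
    truth = read_truth(OUT / "truth.csv")
    munis = sorted(truth["municipality"].unique())
    assessments = pw.assess_all(events, municipalities=munis, n_weeks=N_WEEKS)
    write_assessments(assessments, OUT / "assessments.csv")

    weekly, summary = pw.weekly_suitable_series(assessments)
    weekly.to_csv(OUT / "weekly_suitable.csv", index=False)
    print(f"assessed {len(assessments)} municipality-weeks "
          f"({assessments['suitable'].mean():.1%} suitable)")
    print(f"weekly suitable proportion: median {summary['median']:.1%} "
          f"(IQR {summary['q1']:.1%}-{summary['q3']:.1%})")

    # suitable fraction by upload profile (municipality index encodes cohort order)
    groups = pw.group_municipalities_by_suitable_weeks(assessments)
    print("municipality suitable-week groups:",
          groups["group"].value_counts().sort_index().to_dict())


if __name__ == "__main__":
    main()
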