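"""Concordance of real-time warnings with the backfilled gold standard.

Matches warnings by municipality-week in both directions, stratifies by
the real-time DQI (completeness levels, timeliness deciles, suitability)
and by each municipality's suitable-week group, and writes
concordance.csv.
"""

import pandas as pd

import phcwatch as pw
from phcwatch.io import read_assessments, read_warnings, write_concordance

from _common import OUT


def main() -> None:
    warnings = read_warnings(OUT / "warnings.csv")
    assessments = read_assessments(OUT / "assessments.csv")
    wb = warnings[warnings["source"] == "backfilled"]
    wr = warnings[warnings["source"] == "realtime"]

    overall = [
        pw.concordance_summary(wb, wr, "vs_backfilled"),
        pw.concordance_summary(wr, wb, "vs_realtime"),
    ]
    frames = [pd.DataFrame(overall)]
    for dimension in ("completeness", "timeliness", "suitable"):
        frames.append(pw.concordance_by_quality(wb, wr, assessments, dimension))
    frames.append(pw.concordance_by_municipality_group(wb, wr, assessments))
    table = pd.concat(frames, ignore_index=True)
    write_concordance(table, OUT / "concordance.csv")

    for row in overall:
        print(f"{row['direction']}: {row['n_concordant']}/{row['n_reference']} "
              f"warnings concordant ({row['proportion']:.1%})")
    suit = table[(table["direction"] == "vs_backfilled")
                 & table["stratum"].isin(["suitable", "unsuitable"])]
    for _, row in suit.iterrows():
        print(f"  {row['stratum']:10s}: {row['n_concordant']}/{row['n_reference']} "
              f"({row['proportion']:.1%})")


if __name__ == "__main__":
    main()
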