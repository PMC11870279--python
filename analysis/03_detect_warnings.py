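"""EARS-C2 outbreak detection on both dataset views.

Runs the detector on the backfilled gold standard (full series) and in
vintage real-time mode (each week judged with the snapshot available
that week), writes warnings.csv, and summarises warning counts per
municipality.
"""

import pandas as pd

import phcwatch as pw
from phcwatch.io import read_events, read_truth, write_warnings
from phcwatch.report import warnings_per_municipality

from _common import N_WEEKS, OUT


def main() -> None:
    events = read_events(OUT / "events.csv")
    truth = read_truth(OUT / "truth.csv")
    munis = sorted(truth["municipality"].unique())

    back = pw.backfilled_view(events, n_weeks=N_WEEKS)
    wb = pw.run_ews(back, source="backfilled")
    wr = pw.run_ews_realtime(events, municipalities=munis, n_weeks=N_WEEKS)
    write_warnings(pd.concat([wb, wr], ignore_index=True), OUT / "warnings.csv")

    stats = warnings_per_municipality(wb, munis)
    print(f"backfilled view: {len(wb)} warnings; per municipality median "
          f"{stats['median']:.0f} (IQR {stats['q1']:.0f}-{stats['q3']:.0f})")
    print(f"real-time view (vintage snapshots): {len(wr)} warnings")


if __name__ == "__main__":
    main()
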