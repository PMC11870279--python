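"""Simulate the mixed-quality encounter registry.

150 municipalities over 40 epidemiological weeks, split evenly across the
prompt / monthly / poor upload profiles, sharing the same incidence
process (seasonal negative-binomial counts with injected outbreaks).
Writes truth.csv and events.csv and reports how far the final real-time
snapshot falls short of the backfilled volume for each profile.
"""

import collections

import phcwatch as pw
from phcwatch.io import write_events, write_truth

from _common import N_MUNICIPALITIES, N_WEEKS, OUT, PROFILES, SEED


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth_df, events, profile_map = pw.simulate_mixed(
        N_MUNICIPALITIES, n_weeks=N_WEEKS, seed=SEED, profiles=PROFILES
    )
    write_truth(truth_df, OUT / "truth.csv")
    write_events(events, OUT / "events.csv")

    sizes = collections.Counter(profile_map.values())
    print(f"simulated {N_MUNICIPALITIES} municipalities x {N_WEEKS} weeks "
          f"({dict(sizes)}): {len(events)} registry events, "
          f"{int(truth_df['count'].sum())} encounters")

    # how much of the true volume was visible at the end of the study span
    visible = events[events["registration_week"] < N_WEEKS]
    for profile in PROFILES:
        munis = [m for m, p in profile_map.items() if p == profile]
        true_total = truth_df.loc[truth_df["municipality"].isin(munis), "count"].sum()
        seen = visible.loc[visible["municipality"].isin(munis), "count"].sum()
        print(f"  {profile:8s}: {seen / true_total:6.1%} of encounter volume "
              f"registered within the study span")


if __name__ == "__main__":
    main()
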