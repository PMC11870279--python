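"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import statistics

import numpy as np
import pandas as pd
import pytest

import phcwatch as pw


def c2_alarms_bruteforce(series, baseline_len=7, guard=2, threshold=3.0, min_sd=0.0):
    """Independent plain-Python evaluation of the C2 rule.

    Deliberately uses the statistics module and explicit loops so it shares
    no code path with the package implementation.
    """
    alarms = set()
    for t in range(baseline_len + guard, len(series)):
        base = [float(x) for x in series[t - guard - baseline_len : t - guard]]
        mu = sum(base) / len(base)
        sd = statistics.stdev(base)
        denom = max(sd, min_sd)
        if denom > 0:
            alarm = (series[t] - mu) / denom >= threshold
        else:
            alarm = series[t] > mu
        if alarm:
            alarms.add(t)
    return alarms


def delay_pmf_with_mass(mass: float) -> tuple[float, ...]:
    """Delay distribution with probability ``mass`` within <=2 weeks and the
    remainder spread over delays 3..6."""
    near = (0.5 * mass, 0.3 * mass, 0.2 * mass)
    far = (0.4, 0.3, 0.2, 0.1)
    return tuple(list(near) + [(1 - mass) * f for f in far])


def simulate_events(config: pw.SimulationConfig):
    truth = pw.simulate_truth(config)
    events = pw.simulate_registration(truth, config)
    munis = [t.municipality for t in truth]
    return truth, events, munis


def vs_backfilled_concordance(events, munis, n_weeks, detector=None):
    detector = detector or pw.DetectorConfig()
    back = pw.backfilled_view(events, n_weeks=n_weeks)
    wb = pw.run_ews(back, detector)
    wr = pw.run_ews_realtime(events, detector, municipalities=munis, n_weeks=n_weeks)
    return pw.concordance_summary(wb, wr, "vs_backfilled"), wb, wr


@pytest.fixture(scope="session")
def poor_cohort():
    """A 30-municipality poor-quality simulation reused across tests."""
    cfg = pw.make_config(30, profile="poor", seed=11)
    truth, events, munis = simulate_events(cfg)
    return cfg, truth, events, munis


@pytest.fixture(scope="session")
def mixed_cohort():
    """A 60-municipality half-prompt / half-poor simulation with its
    assessments and warnings, reused across concordance tests."""
    n_weeks = 30
    truth_df, events, profile_map = pw.simulate_mixed(60, n_weeks=n_weeks, seed=7)
    munis = sorted(profile_map)
    assessments = pw.assess_all(events, municipalities=munis, n_weeks=n_weeks)
    back = pw.backfilled_view(events, n_weeks=n_weeks)
    wb = pw.run_ews(back)
    wr = pw.run_ews_realtime(events, municipalities=munis, n_weeks=n_weeks)
    return {
        "n_weeks": n_weeks,
        "truth": truth_df,
        "events": events,
        "municipalities": munis,
        "profiles": profile_map,
        "assessments": assessments,
        "warnings_backfilled": wb,
        "warnings_realtime": wr,
    }
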