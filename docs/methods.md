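# Methods

## The evaluation design

A weekly early-warning system (EWS) for influenza-like-illness (ILI)
outbreaks consumes a municipality-level primary-health-care encounter
registry that is updated with delay. Two views of the same event stream
are compared: the **backfilled** view (all registrations, including late
amendments — the gold standard) and the **real-time** view (what was
visible each week). The pipeline measures how registry data quality,
summarised by a composite Data Quality Index (DQI), governs the agreement
between outbreak warnings raised on the two views.

## Synthetic registry model

The registry generator produces the data-generating structure this design
assumes; it is first-class, tested code, not a fixture.

**Incidence.** Municipality *m*'s true count in week *w* is negative
binomial with mean

    mu_mw = baseline_rate * (1 + A * sin(2*pi*w/52)) * fold_mw

and variance `mu + mu^2 / dispersion` (`dispersion = inf` recovers
Poisson). `fold_mw = outbreak_fold` during outbreak weeks, else 1.
Outbreaks start in a municipality-week with probability
`outbreak_prob_per_week`, last `outbreak_duration_weeks`, and cannot
start while one is active (back-to-back outbreaks are possible and show
up as flag runs that are multiples of the duration). An optional
`forced_outbreak_week` plants an outbreak deterministically, which gives
ground-truth-labelled series for detector sensitivity checks.

Defaults: `baseline_rate = 50` encounters/week (a mid-sized
municipality), `dispersion = 5` (counts noticeably overdispersed across
weeks), `seasonal_amplitude = 0.2`, `outbreak_prob_per_week = 0.02`,
`outbreak_fold = 5`, `outbreak_duration_weeks = 3`, `n_weeks = 23` (the
study-span length the evaluation design uses).

**Registration.** Each encounter-week's count is partitioned across
registration delays by a multinomial draw from `delay_pmf` (whole weeks;
delay = registration week − encounter week). Three mechanisms distort
the real-time view:

* *delay* — the `delay_pmf` itself;
* *monthly batching* — with probability `monthly_uploader_fraction` a
  municipality defers every registration to the next week index ≡ 3
  (mod 4), the simplest week-grid rendering of "upload at least
  monthly";
* *dropout* — with probability `dropout_prob` per municipality-week, the
  week's entire volume slips past the study horizon and is registered
  1–16 weeks after the final study week (the 4-month amendment window).
  It is therefore invisible to every in-study snapshot but present in
  the backfilled view.

Summing event counts over registration weeks reproduces the true counts
exactly, so conservation (backfilled = truth) holds by construction and
is asserted in tests.

**Quality profiles.** Three named presets span the observed spectrum:
`prompt` (all mass at delay 0, no batching, no dropout), `monthly`
(delays 0–2 plus full batching), `poor` (only 30% of mass within 2
weeks, half the municipalities batching, 25% dropout). The presets are
plausible renderings of prompt/batched/weak reporters, not calibrated to
any real registry's empirical delay distribution — no such distribution
is published for SISAB. `prompt` is deliberately the exact perfect-data
limit so that the prompt-profile pipeline run doubles as a structural
check (see invariants below).

**Randomness.** One master seed; municipality *i* draws from
`default_rng([seed, i, stage])` with separate stage constants for
incidence and registration, so enlarging the cohort never reshuffles
existing municipalities and registration variants can be paired against
identical truth.

## DQI

Assessed weekly per municipality on the snapshot as of the evaluation
week, over an 8-week rolling window:

* **completeness** = (window weeks with ≥ 1 visible encounter) / 8 —
  takes only the nine values k/8;
* **timeliness** = (visible window volume registered with delay ≤ 2
  weeks) / (total visible window volume) — volume-weighted; undefined
  when the window holds no visible volume, which grades unsuitable;
* **suitable** ⇔ completeness ≥ 100% and timeliness ≥ 80% (both
  thresholds configurable).

Design choices where the definition is genuinely open:

* *Window alignment*: the window ends at and includes the evaluation
  week (w−7…w), because the DQI gates the warning evaluated at week w
  and must describe the data feeding it.
* *Timeliness denominator*: volume visible in the snapshot, not the
  eventual backfilled volume — a real-time system cannot see
  unregistered encounters. Note this makes timeliness optimistic for
  very recent weeks (late registrations are not yet in the
  denominator); completeness, not timeliness, is what punishes still
  missing weeks.
* *Partial windows* at the series start are skipped, not rescaled, to
  avoid inflating early completeness.

## Detection

EARS-C2 per municipality: for week t, baseline = the `baseline_len = 7`
weeks ending `guard = 2` weeks before t; statistic = (current − baseline
mean) / baseline sample SD (ddof = 1); alarm when the statistic reaches
`threshold = 3`. The parameters follow the canonical C2 description and
are all configurable. Numerical edge cases: a flat baseline (SD = 0,
`min_baseline_sd = 0`) alarms iff the current count exceeds the baseline
mean, with the statistic reported ±inf (0 on exact ties) so the single
rule "statistic ≥ threshold" decides everywhere; an optional
`min_baseline_sd` floors the denominator instead. Weeks with fewer than
`baseline_len + guard` predecessors are not evaluable; series too short
for any evaluation yield an empty result, not an error. Missing
municipality-weeks in a view count as zero — absence of registration is
the failure mode under study.

Real-time detection defaults to **vintage** mode: the week-w decision
uses the snapshot as of w, like a live weekly system. A `final` mode
(one detection pass over the last in-span snapshot) is provided because
either reading of "the real-time dataset" is defensible; they coincide
when delays are zero.

Consecutive alarm weeks count as separate warnings (no episode merging):
concordance is defined week by week.

## Concordance

A reference warning is concordant iff the test set warns for the same
municipality in the same week (a ±k-week tolerance flag exists, default
0). Both directions are always computed — `vs_backfilled` (gold-standard
denominator; how many true warnings the real-time system reproduced) and
`vs_realtime` (real-time denominator; how many of its warnings were
corroborated) — because both denominators are analytically meaningful.
Concordant *counts* agree across directions; only denominators differ
(asserted as an invariant).

Stratification uses the real-time DQI at the warning's
municipality-week: completeness levels k/8, timeliness deciles
(half-open, upper-closed, lowest bin closed at 0), or the suitable flag;
warnings without an assessment (e.g. in the pre-window weeks) go to an
explicit "unassessed" stratum, so stratified reference counts always sum
to the total. Municipality grouping by fraction of suitable weeks uses
half-open upper-closed bins [0,.2], (.2,.4], (.4,.6], (.6,.8], (.8,1],
so boundary values land deterministically. DQI gating is per
municipality-week (a warning is judged by its own week's suitability),
not per municipality over the whole period, because the DQI is defined
weekly.

## What the tests demonstrate — and on what problem sizes

Deterministic contracts are tested on hand-built registries. Stochastic
properties are tested at sizes chosen to give comfortable statistical
margins while keeping the suite quick:

* perfect-quality limit: 50 municipalities × 23 weeks, zero delay, no
  dropout, `baseline_rate = 200` (large enough that every week has at
  least one encounter with overwhelming probability, so the limit is
  exercised rather than zero-count accidents) — every full-window week
  suitable, concordance 1.0 both directions;
* C2 oracle: 1,000 random Poisson series (length 23, rates 0.5–100)
  against an independently coded loop-and-stdlib evaluation — exact
  alarm-set agreement;
* timeliness response: within-2-week delay mass 0.3/0.6/0.9, 20 paired
  seeds of 40 municipalities × 36 weeks — mean `vs_backfilled`
  concordance nondecreasing (observed roughly 0.01 → 0.13 → 0.31);
* stratum separation: 20 seeds of 200 municipalities × 40 weeks, half
  prompt / half poor — the suitable stratum's concordance exceeds the
  unsuitable stratum's in a majority of seeds (observed 20/20).

Passing these shows the pipeline's *orderings and limits* are right
under the synthetic model. The synthetic registry has no spatial
correlation between municipalities, no age/sex or diagnostic-code
structure, a stylised sinusoidal season, and delay presets that are
plausible rather than calibrated; absolute concordance percentages
depend strongly on the profile mix and are therefore never asserted,
only computed and reported.

## Known limitations

* Timeliness of *detection* (lead time) and alarm-quality ROC analysis
  are out of scope; the design measures warning concordance only.
* The DQI covers completeness and timeliness only; accuracy or validity
  of diagnostic coding is unobservable in an aggregated registry.
* The weekly vintage evaluation assumes snapshots are retained; a
  registry that overwrites history can only support `final` mode.
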