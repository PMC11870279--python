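# phcwatch

Data-quality-aware early-warning surveillance on primary-health-care (PHC)
encounter registries.

National PHC registries such as Brazil's SISAB receive encounter records
with delay: municipalities may upload weekly, batch uploads monthly, or
miss weeks entirely and amend them months later. An early-warning system
(EWS) for influenza-like-illness (ILI) outbreaks that consumes the
*real-time* weekly snapshot therefore sees a different dataset from the
retrospectively consolidated (*backfilled*) registry — and its warnings
differ accordingly. `phcwatch` quantifies that effect end to end:

1. **synthetic registry** — municipality-week ILI encounter counts
   (seasonal negative-binomial incidence with injected outbreaks) plus a
   registration process (delay distribution, monthly batching, missed
   weeks amended within a 4-month window), so backfilled and real-time
   views diverge in controlled ways;
2. **DQI** — a composite Data Quality Index per municipality-week on an
   8-week rolling window ending at the evaluation week:
   *completeness* = proportion of window weeks with any registered
   encounter (k/8), *timeliness* = proportion of visible encounter volume
   registered within 2 weeks; graded **suitable** iff completeness = 100%
   and timeliness ≥ 80%;
3. **detection** — EARS-C2 per municipality:
   `C2(t) = (y_t − μ̂) / σ̂` with `μ̂, σ̂` the mean and sample SD of the 7
   weeks ending 2 weeks before `t` (guard band); alarm when `C2 ≥ 3`.
   The backfilled view is scored on its full series; the real-time view
   in *vintage* mode, judging each week with the snapshot available that
   week;
4. **concordance** — a warning is concordant when the other view warns
   for the same municipality in the same week; proportions are reported
   with either view as denominator and stratified by the real-time DQI
   (completeness levels, timeliness deciles, suitable flag) and by each
   municipality's fraction of suitable weeks (≤20%, 20–40%, 40–60%,
   60–80%, ≥80%).

## Worked example

The numbered scripts under `analysis/` run the whole study on one mixed
cohort — 150 municipalities over 40 weeks, equal thirds of `prompt`
(same-week uploads), `monthly` (batched to every 4th week) and `poor`
(heavy delays, 25% missed weeks) reporters:

```sh
python analysis/01_simulate_registry.py
python analysis/02_assess_quality.py
python analysis/03_detect_warnings.py
python analysis/04_evaluate_concordance.py
python analysis/05_report_figures.py
```

which prints, among other things:

```
  prompt  : 100.0% of encounter volume registered within the study span
  monthly :  99.3% of encounter volume registered within the study span
  poor    :  66.1% of encounter volume registered within the study span
assessed 4950 municipality-weeks (34.1% suitable)
weekly suitable proportion: median 33.3% (IQR 33.3%-34.7%)
backfilled view: 295 warnings; per municipality median 2 (IQR 1-3)
vs_backfilled: 110/295 warnings concordant (37.3%)
  suitable  : 102/103 (99.0%)
  unsuitable: 8/192 (4.2%)
```

Reading: prompt uploaders eventually register everything within the
span while poor reporters leave a third of their volume to post-study
amendments; only prompt municipality-weeks grade suitable; and warnings
raised in suitable municipality-weeks almost always agree with the
backfilled gold standard (99.0%) while warnings in unsuitable ones almost
never do (4.2%) — data quality, not the detector, decides whether the
real-time EWS can be trusted.

The same pipeline is available as a CLI (`phcwatch run-all --out DIR
--profile mixed --seed 1`, plus per-stage subcommands `simulate`,
`assess`, `detect`, `evaluate`, `report`) and as a library
(`phcwatch.run_all(config, out_dir)`); every stage reads and writes plain
CSV so stages can be rerun or replaced independently.

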