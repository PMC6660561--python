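# warnprofile

Characterize the performance of early-warning alarm systems on
continuously monitored records by the *timeliness* of every warning, not
just per-record hits and misses.

Each warning (onset time vs. event time) falls into one of five bins —
**False** (warning on a non-event record), **Early** (lead time ≥ T_max),
**On Time** (T_min ≤ lead < T_max), **Late** (lead < T_min, including
onsets after the event), **Missed** (event record with no warning) — and
the bin counts are normalized two ways:

* **warning proportions** — each bin over the total number of warnings
  (the Missed bin is included in the chart but not in the total);
* **warnings per record** — the False bin over the number of non-event
  records, the other four bins over the number of event records.

Traditional per-record metrics (PPV, sensitivity, false positive rate)
are computed alongside for comparison. The package also ships:

* a normalized shock-index indicator (`indicator`): HR/SBP mapped through
  a normal CDF parameterized by the pooled event-record baseline;
* two alarm strategies (`strategy`): **responsive** (direct thresholding)
  and **stay-on** (latched: stays on until the indicator has been below
  threshold for a configurable off-delay);
* a synthetic-data module (`synthetic`): drifting-MAP event records,
  stationary non-event records, and exact-count fixtures that reproduce
  any achievable set of bin counts through the full pipeline;
* CSV I/O (`io`), bar-chart/summary reporting (`report`), and a CLI.

## CLI

```sh
# generate a synthetic cohort (samples.csv + manifest.csv)
warnprofile simulate --n-event 16 --n-nonevent 12 --seed 1 --out cohort/

# full pipeline: indicator -> strategies -> binning -> charts + summary
warnprofile analyze --samples cohort/samples.csv --manifest cohort/manifest.csv \
    --out results/ --strategies responsive,stay_on

# characterize a pre-extracted fiducial table (skips the indicator stage)
warnprofile evaluate --fiducials results/fiducials_responsive.csv --out eval/

# charts only
warnprofile plot --fiducials results/fiducials_responsive.csv --out charts/
```

Configuration is a flat YAML file (defaults shown):

```yaml
t_min_min: 1        # minimum actionable lead time (minutes)
t_max_min: 14       # maximum meaningful lead time (minutes)
threshold: 0.9      # warning threshold on the normalized indicator
off_delay_min: 10   # stay-on latch off-delay (minutes)
sample_interval_min: 1
```

File formats (comma-separated UTF-8, header mandatory, `NA` for missing):

* samples: `record_id,time_min,hr,sbp,map`
* manifest: `record_id,record_type,event_time_min,baseline_start_min,baseline_end_min`
* fiducials: `record_id,record_type,time_event_min,time_warning_min`
  (one row per warning, plus one `NA`-warning row per warningless record)

## Library example

```python
import warnprofile as wp

cfg = wp.FrameworkConfig(t_min=1, t_max=14, threshold=0.9, off_delay=10)
records = wp.generate_cohort(16, 12, wp.GeneratorParams(), seed=1)
stats = wp.fit_baseline_stats(records)
traces = [
    wp.stay_on(
        wp.responsive(
            wp.normalize_si(wp.shock_index(r.hr, r.sbp), stats),
            r.times, cfg.threshold, r.record_id,
        ),
        cfg.off_delay,
    )
    for r in records
]
episodes = {t.record_id: wp.extract_episodes(t) for t in traces}
counts = wp.count_bins(wp.build_fiducials(episodes, records), cfg)
pair = wp.profile_pair(counts)
metrics = wp.traditional_metrics(traces, records, cfg)
```

Reported values are rounded half-to-even (2 decimals for profiles,
1 decimal for percentages); full precision is kept internally.
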