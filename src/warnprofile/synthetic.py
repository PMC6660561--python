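"""Synthetic cohorts and exact-count fixtures.

Two kinds of generated data:

* physiologically shaped records — event records whose mean arterial
  pressure drifts down from baseline until it has dropped by a configured
  amount (which defines the event time) with rising heart rate and falling
  systolic pressure, and stationary non-event records;
* exact fixtures — binary warning traces plus record annotations
  constructed so that the fiducial/binning pipeline reproduces a requested
  :class:`~warnprofile.core.BinCounts` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    BinCounts,
    Category,
    FrameworkConfig,
    RecordSeries,
    ValidationError,
    WarningTrace,
)


class NoEventError(RuntimeError):
    """The configured drift never produces the required pressure drop."""


class UnachievableSpecError(ValueError):
    """The requested bin counts cannot be realized."""


@dataclass(frozen=True)
class GeneratorParams:
    """Settings for the physiological record generators.

    Drifts are per-minute slopes applied after ``baseline_duration``;
    noise is independent additive Gaussian per channel per sample.
    """

    hr_baseline: float = 70.0
    sbp_baseline: float = 120.0
    map_baseline: float = 90.0
    hr_noise_sd: float = 2.0
    sbp_noise_sd: float = 3.0
    map_noise_sd: float = 2.0
    baseline_duration: float = 30.0
    hr_drift: float = 1.5
    sbp_drift: float = -1.0
    map_drift: float = -1.0
    map_drop: float = 30.0
    sample_interval: float = 1.0
    duration: float = 120.0

    def __post_init__(self) -> None:
        if not self.sample_interval > 0:
            raise ValidationError("sample_interval must be > 0")
        if not 0 < self.baseline_duration < self.duration:
            raise ValidationError("need 0 < baseline_duration < duration")
        for name in ("hr_noise_sd", "sbp_noise_sd", "map_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.map_drop <= 0:
            raise ValidationError("map_drop must be > 0")


def _time_grid(duration: float, dt: float) -> np.ndarray:
    return np.arange(0.0, duration + dt / 2, dt)


def generate_event_record(
    params: GeneratorParams, seed, record_id: str = "event"
) -> RecordSeries:
    """One event record: baselines, then linear drift plus noise; the event
    time is the first post-baseline sample where MAP has dropped by
    ``map_drop`` from its configured baseline mean."""
    rng = np.random.default_rng(seed)
    dt = params.sample_interval
    times = _time_grid(params.duration, dt)
    ramp = np.clip(times - params.baseline_duration, 0.0, None)
    hr = params.hr_baseline + params.hr_drift * ramp
    sbp = params.sbp_baseline + params.sbp_drift * ramp
    map_ = params.map_baseline + params.map_drift * ramp
    if params.hr_noise_sd > 0:
        hr = hr + rng.normal(0.0, params.hr_noise_sd, times.size)
    if params.sbp_noise_sd > 0:
        sbp = sbp + rng.normal(0.0, params.sbp_noise_sd, times.size)
    if params.map_noise_sd > 0:
        map_ = map_ + rng.normal(0.0, params.map_noise_sd, times.size)
    hr = np.maximum(hr, 1.0)
    sbp = np.maximum(sbp, 5.0)
    map_ = np.maximum(map_, 1.0)

    # the event can only occur during the drift phase
    crossed = (map_ <= params.map_baseline - params.map_drop) & (
        times > params.baseline_duration
    )
    idx = np.flatnonzero(crossed)
    if idx.size == 0:
        raise NoEventError(
            f"MAP never dropped {params.map_drop:g} mmHg below baseline within "
            f"{params.duration:g} min; steepen map_drift or extend duration"
        )
    return RecordSeries(
        record_id=record_id,
        times=times,
        hr=hr,
        sbp=sbp,
        map=map_,
        baseline_window=(0.0, params.baseline_duration),
        event_time=float(times[idx[0]]),
    )


def generate_nonevent_record(
    params: GeneratorParams, seed, record_id: str = "nonevent"
) -> RecordSeries:
    """One stable control record: stationary noise around the baselines,
    no event annotation."""
    rng = np.random.default_rng(seed)
    times = _time_grid(params.duration, params.sample_interval)
    n = times.size
    hr = np.full(n, params.hr_baseline)
    sbp = np.full(n, params.sbp_baseline)
    map_ = np.full(n, params.map_baseline)
    if params.hr_noise_sd > 0:
        hr = hr + rng.normal(0.0, params.hr_noise_sd, n)
    if params.sbp_noise_sd > 0:
        sbp = sbp + rng.normal(0.0, params.sbp_noise_sd, n)
    if params.map_noise_sd > 0:
        map_ = map_ + rng.normal(0.0, params.map_noise_sd, n)
    return RecordSeries(
        record_id=record_id,
        times=times,
        hr=np.maximum(hr, 1.0),
        sbp=np.maximum(sbp, 5.0),
        map=np.maximum(map_, 1.0),
        baseline_window=(0.0, min(params.baseline_duration, params.duration)),
        event_time=None,
    )


def generate_cohort(
    n_event: int,
    n_nonevent: int,
    params: GeneratorParams,
    seed,
) -> list[RecordSeries]:
    """A cohort of independently seeded event and non-event records."""
    if n_event + n_nonevent < 1:
        raise ValidationError("cohort must contain at least one record")
    children = np.random.SeedSequence(seed).spawn(n_event + n_nonevent)
    records = [
        generate_event_record(params, children[i], record_id=f"ev{i + 1:03d}")
        for i in range(n_event)
    ]
    records += [
        generate_nonevent_record(
            params, children[n_event + j], record_id=f"ne{j + 1:03d}"
        )
        for j in range(n_nonevent)
    ]
    return records


def _ceil_grid(x: float, dt: float) -> float:
    return math.ceil(x / dt - 1e-9) * dt


def generate_fixture(
    spec: BinCounts, config: FrameworkConfig, seed
) -> tuple[list[WarningTrace], list[RecordSeries]]:
    """Traces and records that reproduce ``spec`` exactly through
    ``build_fiducials`` -> ``count_bins``.

    Warnings are placed as isolated single-sample episodes at grid-aligned
    lead times inside the appropriate category region: on-time onsets start
    at the first grid point at or past ``t_min``, early onsets one sample
    beyond the grid point covering ``t_max``, late onsets just below the
    on-time region, and false warnings anywhere on non-event records.
    Exactly ``spec.n_missed`` event records carry no warning.
    """
    dt = config.sample_interval
    n_warned = spec.n_event_records - spec.n_missed
    n_event_warnings = spec.n_early + spec.n_on_time + spec.n_late
    if n_event_warnings > 0 and n_warned == 0:
        raise UnachievableSpecError(
            "event-side warnings requested but every event record is missed"
        )
    if n_event_warnings < n_warned:
        raise UnachievableSpecError(
            f"{n_warned} warned event records need at least one warning each, "
            f"but only {n_event_warnings} event-side warnings were requested"
        )
    if spec.n_false > 0 and spec.n_nonevent_records == 0:
        raise UnachievableSpecError("false warnings requested without non-event records")

    on_time_base = _ceil_grid(config.t_min, dt)
    early_base = _ceil_grid(config.t_max, dt) + dt
    late_base = on_time_base - 2 * dt
    # on-time leads step by 2*dt and must stay below both t_max and the
    # early region (one quiet sample between any two episodes)
    on_time_top = _ceil_grid(config.t_max, dt) - dt
    on_time_capacity = (
        int((on_time_top - on_time_base) // (2 * dt)) + 1
        if on_time_base <= on_time_top
        else 0
    )

    rng = np.random.default_rng(seed)
    labels = (
        [Category.EARLY] * spec.n_early
        + [Category.ON_TIME] * spec.n_on_time
        + [Category.LATE] * spec.n_late
    )
    rng.shuffle(labels)
    per_record: list[dict[Category, int]] = [
        {Category.EARLY: 0, Category.ON_TIME: 0, Category.LATE: 0}
        for _ in range(max(n_warned, 1))
    ]
    for i, label in enumerate(labels):
        per_record[i % n_warned][label] += 1

    leads_by_record: list[list[float]] = []
    for counts in per_record[:n_warned]:
        if counts[Category.ON_TIME] > on_time_capacity:
            raise UnachievableSpecError(
                f"window [{config.t_min:g}, {config.t_max:g}) holds at most "
                f"{on_time_capacity} separated on-time onsets per record at "
                f"sample interval {dt:g}"
            )
        leads = [early_base + 2 * k * dt for k in range(counts[Category.EARLY])]
        leads += [on_time_base + 2 * k * dt for k in range(counts[Category.ON_TIME])]
        leads += [late_base - 2 * k * dt for k in range(counts[Category.LATE])]
        leads_by_record.append(leads)

    all_leads = [lead for leads in leads_by_record for lead in leads]
    max_lead = max(all_leads, default=0.0)
    min_lead = min(all_leads, default=0.0)
    event_time = max(dt, _ceil_grid(max_lead, dt) + dt)
    duration = max(event_time, event_time - min_lead) + dt

    max_false_per_rec = (
        math.ceil(spec.n_false / spec.n_nonevent_records)
        if spec.n_nonevent_records
        else 0
    )
    duration = max(duration, (2 * max_false_per_rec + 1) * dt)
    times = _time_grid(duration, dt)
    n = times.size

    def make_record(rid: str, te: float | None) -> RecordSeries:
        return RecordSeries(
            record_id=rid,
            times=times.copy(),
            hr=np.full(n, 80.0),
            sbp=np.full(n, 120.0),
            map=np.full(n, 90.0),
            baseline_window=(0.0, dt),
            event_time=te,
        )

    traces: list[WarningTrace] = []
    records: list[RecordSeries] = []
    for r in range(spec.n_event_records):
        rid = f"ev{r + 1:03d}"
        records.append(make_record(rid, event_time))
        state = np.zeros(n, dtype=np.int8)
        if r < n_warned:
            for lead in leads_by_record[r]:
                i = round((event_time - lead) / dt)
                assert 0 <= i < n
                state[i] = 1
        traces.append(WarningTrace(rid, times.copy(), state))

    false_per_rec = [0] * spec.n_nonevent_records
    for i in range(spec.n_false):
        false_per_rec[i % spec.n_nonevent_records] += 1
    for r in range(spec.n_nonevent_records):
        rid = f"ne{r + 1:03d}"
        records.append(make_record(rid, None))
        state = np.zeros(n, dtype=np.int8)
        for k in range(false_per_rec[r]):
            state[1 + 2 * k] = 1
        traces.append(WarningTrace(rid, times.copy(), state))
    return traces, records
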