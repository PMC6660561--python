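"""Core characterization: fiducials, five-bin categorization, profiles,
and per-record traditional metrics.

Every warning is categorized by its onset lead time ``T_warning =
time_event - time_warning`` into one of five bins:

* False — warning on a non-event record
* Early — event record, ``T_warning >= t_max``
* On Time — event record, ``t_max > T_warning >= t_min``
* Late — event record, ``T_warning < t_min`` (including onsets after the
  event, where the lead time is negative)
* Missed — event record on which no warning fired

The bin counts are normalized two ways: by the total number of warnings
(warning proportions) and by the record denominators of each side
(warnings per record).
"""

from __future__ import annotations

import warnings as _warnings
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    BinCounts,
    Category,
    FiducialRow,
    FrameworkConfig,
    ProfilePair,
    RecordSeries,
    RecordType,
    TraditionalMetrics,
    ValidationError,
    WarningTrace,
)
from .strategy import WarningEpisode


class RecordLengthWarning(UserWarning):
    """Record lengths differ enough to make pooled profiles misleading."""


def build_fiducials(
    episodes_by_record: Mapping[str, Sequence[WarningEpisode]],
    records: Iterable[RecordSeries],
) -> list[FiducialRow]:
    """One row per warning episode (onset as ``time_warning``), plus one
    NA-warning row for every record with zero episodes."""
    record_map = {rec.record_id: rec for rec in records}
    unknown = set(episodes_by_record) - set(record_map)
    if unknown:
        raise ValidationError(
            f"episodes reference unknown record(s): {', '.join(sorted(unknown))}"
        )
    rows: list[FiducialRow] = []
    for rid, rec in record_map.items():
        episodes = episodes_by_record.get(rid, ())
        if not episodes:
            rows.append(
                FiducialRow(
                    record_id=rid,
                    record_type=rec.record_type,
                    time_event=rec.event_time,
                    time_warning=None,
                )
            )
            continue
        for ep in episodes:
            rows.append(
                FiducialRow(
                    record_id=rid,
                    record_type=rec.record_type,
                    time_event=rec.event_time,
                    time_warning=float(ep.onset),
                )
            )
    return rows


def categorize(row: FiducialRow, config: FrameworkConfig) -> Category:
    """Assign a fiducial row to one of the five bins.

    A nonevent row without a warning is not categorizable (it contributes
    only to the record denominator) and raises ``ValidationError``.
    """
    if row.record_type is RecordType.NONEVENT:
        if row.time_warning is None:
            raise ValidationError(
                f"row {row.record_id!r}: warningless nonevent rows are not warnings"
            )
        return Category.FALSE
    if row.time_warning is None:
        return Category.MISSED
    lead = row.time_event - row.time_warning
    if lead >= config.t_max:
        return Category.EARLY
    if lead >= config.t_min:
        return Category.ON_TIME
    return Category.LATE


def count_bins(rows: Iterable[FiducialRow], config: FrameworkConfig) -> BinCounts:
    """Tally the five bins and the record denominators from a fiducial set."""
    tallies = {cat: 0 for cat in Category}
    ids_by_type: dict[RecordType, set[str]] = {
        RecordType.EVENT: set(),
        RecordType.NONEVENT: set(),
    }
    for row in rows:
        ids_by_type[row.record_type].add(row.record_id)
        if row.record_type is RecordType.NONEVENT and row.time_warning is None:
            continue  # quiet control record: denominator only
        tallies[categorize(row, config)] += 1
    both = ids_by_type[RecordType.EVENT] & ids_by_type[RecordType.NONEVENT]
    if both:
        raise ValidationError(
            f"record(s) appear under both record types: {', '.join(sorted(both))}"
        )
    return BinCounts(
        n_false=tallies[Category.FALSE],
        n_early=tallies[Category.EARLY],
        n_on_time=tallies[Category.ON_TIME],
        n_late=tallies[Category.LATE],
        n_missed=tallies[Category.MISSED],
        n_event_records=len(ids_by_type[RecordType.EVENT]),
        n_nonevent_records=len(ids_by_type[RecordType.NONEVENT]),
    )


def warning_proportions(counts: BinCounts) -> dict[Category, float]:
    """Each bin (including Missed) divided by the total number of warnings.

    The four warning bins sum to exactly 1; the Missed bin can push the
    overall sum above 1.
    """
    total = counts.total_warnings
    if total == 0:
        raise ValidationError("warning proportions undefined: no warnings")
    return {cat: n / total for cat, n in counts.by_category().items()}


def warnings_per_record(counts: BinCounts) -> tuple[dict[Category, float], frozenset[Category]]:
    """False bin over non-event records; the four event bins over event records.

    Returns the profile and the set of bins that were 0/0 (reported as 0
    but flagged as undefined). A nonzero numerator over a zero denominator
    is an error.
    """
    profile: dict[Category, float] = {}
    undefined: set[Category] = set()
    for cat, n in counts.by_category().items():
        denom = (
            counts.n_nonevent_records
            if cat is Category.FALSE
            else counts.n_event_records
        )
        if denom == 0:
            if n > 0:
                raise ValidationError(
                    f"bin {cat.value}: {n} warnings but zero records in denominator"
                )
            profile[cat] = 0.0
            undefined.add(cat)
        else:
            profile[cat] = n / denom
    return profile, frozenset(undefined)


def profile_pair(counts: BinCounts) -> ProfilePair:
    """Convenience: both normalized profiles from one set of counts."""
    per_record, undefined = warnings_per_record(counts)
    return ProfilePair(
        warning_proportions=warning_proportions(counts),
        warnings_per_record=per_record,
        undefined_bins=undefined,
    )


def traditional_metrics(
    traces: Iterable[WarningTrace],
    records: Iterable[RecordSeries],
    config: FrameworkConfig,
) -> TraditionalMetrics:
    """Per-record metrics: an event record is a true positive if the warning
    state is on at any sample whose lead time falls in ``[t_min, t_max)``;
    a non-event record is a false positive if any sample is on."""
    record_map = {rec.record_id: rec for rec in records}
    trace_map: dict[str, WarningTrace] = {}
    for trace in traces:
        if trace.record_id in trace_map:
            raise ValidationError(f"duplicate trace for record {trace.record_id!r}")
        trace_map[trace.record_id] = trace
    if set(trace_map) != set(record_map):
        diff = set(trace_map) ^ set(record_map)
        raise ValidationError(
            f"traces and records do not match: {', '.join(sorted(diff))}"
        )
    tp = fp = n_event = n_nonevent = 0
    for rid, rec in record_map.items():
        trace = trace_map[rid]
        if trace.times.shape != rec.times.shape or not np.allclose(
            trace.times, rec.times
        ):
            raise ValidationError(f"trace for record {rid!r} is on a different grid")
        if rec.record_type is RecordType.EVENT:
            n_event += 1
            lead = rec.event_time - trace.times
            in_window = (lead >= config.t_min) & (lead < config.t_max)
            if np.any((trace.state == 1) & in_window):
                tp += 1
        else:
            n_nonevent += 1
            if np.any(trace.state == 1):
                fp += 1
    return TraditionalMetrics(
        n_true_positive_records=tp,
        n_false_positive_records=fp,
        n_event_records=n_event,
        n_nonevent_records=n_nonevent,
    )


def check_record_lengths(records: Iterable[RecordSeries], max_ratio: float = 2.0) -> None:
    """Warn when record durations are dissimilar enough to bias the profiles."""
    durations = [rec.duration for rec in records]
    if len(durations) < 2:
        return
    lo, hi = min(durations), max(durations)
    if lo > 0 and hi / lo > max_ratio:
        _warnings.warn(
            f"record lengths differ by more than {max_ratio}x "
            f"(min {lo:g} min, max {hi:g} min); pooled profiles may mislead",
            RecordLengthWarning,
            stacklevel=2,
        )
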