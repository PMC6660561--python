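"""Shared domain types for warning-system performance characterization.

Everything downstream operates on a handful of small value types: a
framework configuration (lead-time window, threshold, latch off-delay),
per-record vital-sign series, binary warning traces, per-warning fiducial
rows, and the five-bin count/profile containers. All timestamps are in
minutes relative to the start of the record.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: The only token used to serialize an undefined fiducial value.
NA_TOKEN = "NA"

#: Relative tolerance for the uniform-sampling check on record time grids.
GRID_RTOL = 1e-6


class ValidationError(ValueError):
    """Input violates a domain invariant (named record/row where possible)."""


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class Category(enum.Enum):
    """Timeliness category of a warning (or of a warningless event record)."""

    FALSE = "False"
    EARLY = "Early"
    ON_TIME = "On Time"
    LATE = "Late"
    MISSED = "Missed"


#: Canonical display order of the five bins.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.FALSE,
    Category.EARLY,
    Category.ON_TIME,
    Category.LATE,
    Category.MISSED,
)

#: Bins populated only by event records.
EVENT_CATEGORIES: tuple[Category, ...] = (
    Category.EARLY,
    Category.ON_TIME,
    Category.LATE,
    Category.MISSED,
)


class RecordType(str, enum.Enum):
    EVENT = "event"
    NONEVENT = "nonevent"


def round_half_even(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties to even.

    This is the convention of the reference tables (e.g. 0.625 -> 0.62,
    1.125 -> 1.12), matching IEC 60559 rounding.
    """
    return float(round(x, ndigits))


@dataclass(frozen=True)
class FrameworkConfig:
    """Configuration of the characterization framework.

    Parameters
    ----------
    t_min, t_max
        Minimum / maximum lead time (minutes) before the event for which a
        warning counts as on time. ``t_min`` may be zero or negative.
    threshold
        Warning threshold on the normalized indicator, in [0, 1].
    off_delay
        Latch off-delay (minutes) of the stay-on strategy.
    sample_interval
        Sampling interval (minutes) of the record time grids.
    """

    t_min: float
    t_max: float
    threshold: float = 0.9
    off_delay: float = 10.0
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_max > self.t_min:
            raise ValidationError(
                f"t_max ({self.t_max}) must be greater than t_min ({self.t_min})"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.off_delay < 0:
            raise ValidationError(f"off_delay must be >= 0, got {self.off_delay}")
        if not self.sample_interval > 0:
            raise ValidationError(
                f"sample_interval must be > 0, got {self.sample_interval}"
            )


def _as_float_array(x, name: str, rid: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"record {rid!r}: {name} must be one-dimensional")
    return arr


@dataclass
class RecordSeries:
    """One monitored subject's uniformly sampled vital-sign traces.

    ``event_time`` is ``None`` for non-event (control) records. The
    ``baseline_window`` is a half-open interval ``[start, end)`` in minutes
    marking the protocol baseline used for indicator normalization.
    """

    record_id: str
    times: np.ndarray
    hr: np.ndarray
    sbp: np.ndarray
    map: np.ndarray | None = None
    baseline_window: tuple[float, float] | None = None
    event_time: float | None = None

    def __post_init__(self) -> None:
        rid = self.record_id
        self.times = _as_float_array(self.times, "times", rid)
        self.hr = _as_float_array(self.hr, "hr", rid)
        self.sbp = _as_float_array(self.sbp, "sbp", rid)
        if self.map is not None:
            self.map = _as_float_array(self.map, "map", rid)
        n = self.times.size
        if n < 2:
            raise ValidationError(f"record {rid!r}: needs at least 2 samples")
        for name, arr in (("hr", self.hr), ("sbp", self.sbp), ("map", self.map)):
            if arr is not None and arr.size != n:
                raise ValidationError(
                    f"record {rid!r}: {name} length {arr.size} != times length {n}"
                )
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise ValidationError(f"record {rid!r}: times must be strictly increasing")
        dt = diffs[0]
        if not np.allclose(diffs, dt, rtol=GRID_RTOL, atol=GRID_RTOL * max(dt, 1.0)):
            raise ValidationError(
                f"record {rid!r}: nonuniform sampling (intervals range "
                f"{diffs.min():g}..{diffs.max():g} min)"
            )
        for name, arr in (("hr", self.hr), ("sbp", self.sbp)):
            vals = arr[np.isfinite(arr)]
            if np.any(vals <= 0):
                raise ValidationError(f"record {rid!r}: {name} must be positive")
        if self.baseline_window is None:
            self.baseline_window = (float(self.times[0]), float(self.times[0] + dt))
        b0, b1 = self.baseline_window
        if not b1 > b0:
            raise ValidationError(f"record {rid!r}: baseline_window must be nonempty")
        if self.event_time is not None:
            te = float(self.event_time)
            if not (self.times[0] <= te <= self.times[-1]):
                raise ValidationError(
                    f"record {rid!r}: event_time {te:g} outside record span "
                    f"[{self.times[0]:g}, {self.times[-1]:g}]"
                )
            if b1 > te:
                raise ValidationError(
                    f"record {rid!r}: baseline_window must precede event_time"
                )

    @property
    def record_type(self) -> RecordType:
        return RecordType.NONEVENT if self.event_time is None else RecordType.EVENT

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def baseline_mask(self) -> np.ndarray:
        """Boolean mask of samples inside the half-open baseline window."""
        b0, b1 = self.baseline_window
        return (self.times >= b0) & (self.times < b1)


@dataclass
class WarningTrace:
    """Binary warning-state array aligned to a record's time grid.

    ``state[i] == 1`` means a warning is active at ``times[i]``.
    """

    record_id: str
    times: np.ndarray
    state: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times", self.record_id)
        state = np.asarray(self.state)
        if state.shape != self.times.shape:
            raise ValidationError(
                f"trace {self.record_id!r}: state length {state.size} != "
                f"times length {self.times.size}"
            )
        if not np.isin(state, (0, 1)).all():
            raise ValidationError(f"trace {self.record_id!r}: state must be 0/1")
        self.state = state.astype(np.int8)


@dataclass(frozen=True)
class WarningEpisode:
    """A maximal contiguous run of active warning state."""

    record_id: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValidationError(
                f"episode on {self.record_id!r}: offset {self.offset:g} before "
                f"onset {self.onset:g}"
            )


@dataclass(frozen=True)
class FiducialRow:
    """Fiducial points for one warning, or for a warningless record.

    ``time_warning is None`` represents a record on which no warning fired
    (a missed event record, or a quiet non-event record that contributes
    only to the record denominator).
    """

    record_id: str
    record_type: RecordType
    time_event: float | None
    time_warning: float | None

    def __post_init__(self) -> None:
        if self.record_type is RecordType.NONEVENT and self.time_event is not None:
            raise ValidationError(
                f"row {self.record_id!r}: nonevent record cannot have time_event"
            )
        if self.record_type is RecordType.EVENT and self.time_event is None:
            raise ValidationError(
                f"row {self.record_id!r}: event record must have time_event"
            )

    @property
    def lead_time(self) -> float | None:
        """Event time minus warning onset (minutes); ``None`` if undefined."""
        if self.time_event is None or self.time_warning is None:
            return None
        return self.time_event - self.time_warning


@dataclass(frozen=True)
class BinCounts:
    """Five-bin tallies plus record denominators.

    ``total_warnings`` excludes the missed bin: missed rows are event
    records without a warning, not warnings.
    """

    n_false: int
    n_early: int
    n_on_time: int
    n_late: int
    n_missed: int
    n_event_records: int
    n_nonevent_records: int

    def __post_init__(self) -> None:
        for name in (
            "n_false",
            "n_early",
            "n_on_time",
            "n_late",
            "n_missed",
            "n_event_records",
            "n_nonevent_records",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_missed > self.n_event_records:
            raise ValidationError(
                f"n_missed ({self.n_missed}) exceeds n_event_records "
                f"({self.n_event_records})"
            )

    @property
    def total_warnings(self) -> int:
        return self.n_false + self.n_early + self.n_on_time + self.n_late

    def by_category(self) -> dict[Category, int]:
        return {
            Category.FALSE: self.n_false,
            Category.EARLY: self.n_early,
            Category.ON_TIME: self.n_on_time,
            Category.LATE: self.n_late,
            Category.MISSED: self.n_missed,
        }


@dataclass(frozen=True)
class ProfilePair:
    """The two five-bin profiles: warning proportions and warnings per record.

    ``undefined_bins`` flags per-record bins whose numerator and denominator
    were both zero (reported as 0 but not meaningful).
    """

    warning_proportions: Mapping[Category, float]
    warnings_per_record: Mapping[Category, float]
    undefined_bins: frozenset[Category] = frozenset()

    def __post_init__(self) -> None:
        for profile in (self.warning_proportions, self.warnings_per_record):
            if set(profile) != set(CATEGORY_ORDER):
                raise ValidationError("profiles must have exactly the five bins")
            if any(v < 0 or not math.isfinite(v) for v in profile.values()):
                raise ValidationError("profile values must be finite and nonnegative")


@dataclass(frozen=True)
class TraditionalMetrics:
    """Per-record true/false positive counts and the derived percentages."""

    n_true_positive_records: int
    n_false_positive_records: int
    n_event_records: int
    n_nonevent_records: int

    @property
    def ppv(self) -> float | None:
        denom = self.n_true_positive_records + self.n_false_positive_records
        if denom == 0:
            return None
        return 100.0 * self.n_true_positive_records / denom

    @property
    def sensitivity(self) -> float | None:
        if self.n_event_records == 0:
            return None
        return 100.0 * self.n_true_positive_records / self.n_event_records

    @property
    def false_positive_rate(self) -> float | None:
        if self.n_nonevent_records == 0:
            return None
        return 100.0 * self.n_false_positive_records / self.n_nonevent_records
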