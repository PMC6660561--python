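from __future__ import annotations

import numpy as np
import pytest

from warnprofile import BinCounts, FiducialRow, FrameworkConfig, RecordSeries, RecordType

# Case-study configuration: actionable window 1-14 min before the event,
# 0.9 threshold, 10 min latch off-delay, 1 min sampling.
CASE_CONFIG = FrameworkConfig(
    t_min=1.0, t_max=14.0, threshold=0.9, off_delay=10.0, sample_interval=1.0
)

RESPONSIVE_COUNTS = BinCounts(
    n_false=30,
    n_early=18,
    n_on_time=12,
    n_late=2,
    n_missed=1,
    n_event_records=16,
    n_nonevent_records=12,
)

STAY_ON_COUNTS = BinCounts(
    n_false=8,
    n_early=6,
    n_on_time=10,
    n_late=1,
    n_missed=1,
    n_event_records=16,
    n_nonevent_records=12,
)


@pytest.fixture
def config() -> FrameworkConfig:
    return CASE_CONFIG


@pytest.fixture
def responsive_counts() -> BinCounts:
    return RESPONSIVE_COUNTS


@pytest.fixture
def stay_on_counts() -> BinCounts:
    return STAY_ON_COUNTS


def make_rows(counts: BinCounts, config: FrameworkConfig) -> list[FiducialRow]:
    """Build a fiducial table realizing ``counts``, independent of the
    package's own fixture generator.

    Each warned event record receives warnings round-robin at fixed lead
    times well inside each category region; missed event records and quiet
    non-event records get NA-warning rows.
    """
    event_time = 100.0
    leads = {
        "early": config.t_max + 5.0,
        "on_time": (config.t_min + config.t_max) / 2.0,
        "late": config.t_min - 0.5,
    }
    n_warned = counts.n_event_records - counts.n_missed
    labels = (
        ["early"] * counts.n_early
        + ["on_time"] * counts.n_on_time
        + ["late"] * counts.n_late
    )
    if labels and n_warned == 0:
        raise ValueError("counts not realizable: warnings but all records missed")
    rows: list[FiducialRow] = []
    for i, label in enumerate(labels):
        rid = f"ev{i % n_warned + 1:03d}"
        rows.append(
            FiducialRow(rid, RecordType.EVENT, event_time, event_time - leads[label])
        )
    for m in range(counts.n_missed):
        rows.append(
            FiducialRow(f"ev-missed{m + 1:03d}", RecordType.EVENT, event_time, None)
        )
    for i in range(counts.n_false):
        rid = f"ne{i % counts.n_nonevent_records + 1:03d}"
        rows.append(FiducialRow(rid, RecordType.NONEVENT, None, 10.0 + i))
    warned_ne = min(counts.n_false, counts.n_nonevent_records)
    for q in range(warned_ne, counts.n_nonevent_records):
        rows.append(FiducialRow(f"ne{q + 1:03d}", RecordType.NONEVENT, None, None))
    return rows


@pytest.fixture
def make_fiducial_rows():
    return make_rows


def make_record(
    record_id: str = "r1",
    duration: float = 120.0,
    dt: float = 1.0,
    event_time: float | None = None,
    hr: float = 80.0,
    sbp: float = 120.0,
) -> RecordSeries:
    times = np.arange(0.0, duration + dt / 2, dt)
    n = times.size
    return RecordSeries(
        record_id=record_id,
        times=times,
        hr=np.full(n, hr),
        sbp=np.full(n, sbp),
        map=np.full(n, 90.0),
        baseline_window=(0.0, dt),
        event_time=event_time,
    )


@pytest.fixture
def simple_record():
    return make_record
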