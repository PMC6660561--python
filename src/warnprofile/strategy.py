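"""Warning strategies: direct thresholding and latching, plus episode extraction."""

from __future__ import annotations

import math

import numpy as np

from .core import ValidationError, WarningEpisode, WarningTrace


def responsive(
    si_norm: np.ndarray,
    times: np.ndarray,
    threshold: float,
    record_id: str = "",
) -> WarningTrace:
    """Direct binary interpretation: warning active wherever the indicator
    is at or above the threshold."""
    si_norm = np.asarray(si_norm, dtype=float)
    times = np.asarray(times, dtype=float)
    if si_norm.shape != times.shape:
        raise ValidationError("si_norm and times must be aligned")
    return WarningTrace(
        record_id=record_id,
        times=times,
        state=(si_norm >= threshold).astype(np.int8),
    )


def _off_delay_samples(off_delay: float, dt: float) -> int:
    # a gap terminates the latch once its duration reaches off_delay
    return int(math.ceil(off_delay / dt - 1e-9))


def stay_on(trace: WarningTrace, off_delay: float) -> WarningTrace:
    """Latch a trace: once on, stay on until the input has been off for
    ``off_delay`` minutes.

    Sub-off-delay quiet gaps between episodes are filled, and the latch
    remains on to the end of the record if the record ends inside such a
    gap. ``off_delay == 0`` is the identity.
    """
    if off_delay < 0:
        raise ValidationError(f"off_delay must be >= 0, got {off_delay}")
    state = trace.state
    n = state.size
    if n == 0 or off_delay == 0:
        return WarningTrace(trace.record_id, trace.times.copy(), state.copy())
    dt = float(trace.times[1] - trace.times[0])
    k = _off_delay_samples(off_delay, dt)
    idx = np.arange(n)
    # index of the most recent active sample at or before each position
    last_on = np.maximum.accumulate(np.where(state == 1, idx, -1))
    held = (last_on >= 0) & (idx - last_on < k)
    out = ((state == 1) | held).astype(np.int8)
    return WarningTrace(trace.record_id, trace.times.copy(), out)


def extract_episodes(trace: WarningTrace) -> list[WarningEpisode]:
    """Decompose a trace into maximal runs of active state.

    Onset/offset are the timestamps of the first/last sample of each run;
    episodes are returned ordered by onset.
    """
    state = trace.state
    padded = np.concatenate(([0], state, [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return [
        WarningEpisode(
            record_id=trace.record_id,
            onset=float(trace.times[s]),
            offset=float(trace.times[e]),
        )
        for s, e in zip(starts, ends)
    ]


def stay_on_episodes(trace: WarningTrace, off_delay: float) -> list[WarningEpisode]:
    """Latched episodes with onsets from the latched state but offsets at
    the last genuine (pre-latch) active sample of each merged run."""
    latched = extract_episodes(stay_on(trace, off_delay))
    raw_times = trace.times[trace.state == 1]
    episodes = []
    for ep in latched:
        genuine = raw_times[(raw_times >= ep.onset) & (raw_times <= ep.offset)]
        episodes.append(
            WarningEpisode(
                record_id=ep.record_id,
                onset=ep.onset,
                offset=float(genuine[-1]) if genuine.size else ep.offset,
            )
        )
    return episodes
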