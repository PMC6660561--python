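"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the behaviors under test from first
principles (exhaustive case analysis / direct automaton simulation) and
share no code with the package.
"""

from __future__ import annotations

from collections import Counter


def categorize_oracle(record_type, time_event, time_warning, t_min, t_max):
    """Exhaustive five-way case analysis on raw row fields.

    Returns one of the category label strings, or ``None`` for a
    warningless non-event row (not a warning at all).
    """
    if record_type == "nonevent":
        if time_warning is None:
            return None
        return "False"
    # event record
    if time_warning is None:
        return "Missed"
    lead = time_event - time_warning
    if lead >= t_max:
        return "Early"
    if t_max > lead >= t_min:
        return "On Time"
    if lead < t_min:
        return "Late"
    raise AssertionError("unreachable")


def count_oracle(raw_rows, t_min, t_max):
    """Tally categories and record denominators from raw row tuples
    ``(record_id, record_type, time_event, time_warning)``."""
    tally = Counter()
    event_ids, nonevent_ids = set(), set()
    for rid, rtype, te, tw in raw_rows:
        (event_ids if rtype == "event" else nonevent_ids).add(rid)
        label = categorize_oracle(rtype, te, tw, t_min, t_max)
        if label is not None:
            tally[label] += 1
    return {
        "False": tally["False"],
        "Early": tally["Early"],
        "On Time": tally["On Time"],
        "Late": tally["Late"],
        "Missed": tally["Missed"],
        "n_event_records": len(event_ids),
        "n_nonevent_records": len(nonevent_ids),
    }


def latch_oracle(times, state, off_delay):
    """Simulate the stay-on latch sample by sample in time space.

    Output is on wherever the input is on, or while the time elapsed since
    the most recent input-on sample is strictly less than ``off_delay``.
    """
    out = []
    last_on = None
    for t, s in zip(times, state):
        if s == 1:
            last_on = t
            out.append(1)
        elif last_on is not None and (t - last_on) < off_delay:
            out.append(1)
        else:
            out.append(0)
    return out
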