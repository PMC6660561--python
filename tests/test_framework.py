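import numpy as np
import pytest

from warnprofile import (
    BinCounts,
    Category,
    FiducialRow,
    FrameworkConfig,
    RecordType,
    ValidationError,
    WarningEpisode,
    WarningTrace,
    build_fiducials,
    categorize,
    count_bins,
    profile_pair,
    traditional_metrics,
    warning_proportions,
    warnings_per_record,
)
from warnprofile.framework import RecordLengthWarning, check_record_lengths
from warnprofile.core import round_half_even
from conftest import make_record
from oracles import count_oracle


def ep(rid, onset):
    return WarningEpisode(rid, onset, onset + 1.0)


class TestBuildFiducials:
    def test_per_warning_expansion(self, simple_record):
        rec = simple_record("r1", event_time=40.0)
        rows = build_fiducials({"r1": [ep("r1", 20.0), ep("r1", 35.0)]}, [rec])
        assert [(r.time_event, r.time_warning) for r in rows] == [
            (40.0, 20.0),
            (40.0, 35.0),
        ]

    def test_missed_event_record(self, simple_record):
        rec = simple_record("r1", event_time=40.0)
        (row,) = build_fiducials({}, [rec])
        assert row.record_type is RecordType.EVENT
        assert row.time_event == 40.0
        assert row.time_warning is None

    def test_nonevent_warning(self, simple_record):
        rec = simple_record("r1")
        (row,) = build_fiducials({"r1": [ep("r1", 12.0)]}, [rec])
        assert row.record_type is RecordType.NONEVENT
        assert row.time_event is None
        assert row.time_warning == 12.0

    def test_unknown_record_rejected(self, simple_record):
        with pytest.raises(ValidationError, match="ghost"):
            build_fiducials({"ghost": [ep("ghost", 1.0)]}, [simple_record("r1")])

    def test_row_total(self, simple_record):
        records = [
            simple_record("a", event_time=40.0),
            simple_record("b", event_time=40.0),
            simple_record("c"),
        ]
        episodes = {"a": [ep("a", 5.0), ep("a", 20.0)]}
        rows = build_fiducials(episodes, records)
        # total rows = total episodes + number of warningless records
        assert len(rows) == 2 + 2


class TestCategorize:
    @pytest.mark.parametrize(
        "time_warning, expected",
        [
            (26.0, Category.EARLY),  # lead 14 = t_max boundary
            (27.0, Category.ON_TIME),  # lead 13
            (39.0, Category.ON_TIME),  # lead 1 = t_min boundary
            (39.5, Category.LATE),  # lead 0.5
            (45.0, Category.LATE),  # lead -5: after the event
            (10.0, Category.EARLY),  # lead 30
        ],
    )
    def test_event_rows(self, config, time_warning, expected):
        row = FiducialRow("r1", RecordType.EVENT, 40.0, time_warning)
        assert categorize(row, config) is expected

    def test_nonevent_warning_is_false(self, config):
        row = FiducialRow("r1", RecordType.NONEVENT, None, 12.0)
        assert categorize(row, config) is Category.FALSE

    def test_missed(self, config):
        row = FiducialRow("r1", RecordType.EVENT, 40.0, None)
        assert categorize(row, config) is Category.MISSED

    def test_warningless_nonevent_not_categorizable(self, config):
        row = FiducialRow("r1", RecordType.NONEVENT, None, None)
        with pytest.raises(ValidationError):
            categorize(row, config)

    def test_time_shift_invariance(self, config):
        rng = np.random.default_rng(7)
        for _ in range(50):
            te = float(rng.uniform(0, 200))
            tw = float(rng.uniform(-50, 250))
            shift = float(rng.uniform(-100, 100))
            a = categorize(FiducialRow("r", RecordType.EVENT, te, tw), config)
            b = categorize(
                FiducialRow("r", RecordType.EVENT, te + shift, tw + shift), config
            )
            assert a is b


class TestCountBins:
    def test_case_study_responsive(self, config, responsive_counts, make_fiducial_rows):
        rows = make_fiducial_rows(responsive_counts, config)
        counts = count_bins(rows, config)
        assert counts == responsive_counts
        assert counts.total_warnings == 62

    def test_case_study_stay_on(self, config, stay_on_counts, make_fiducial_rows):
        counts = count_bins(make_fiducial_rows(stay_on_counts, config), config)
        assert counts == stay_on_counts
        assert counts.total_warnings == 25

    def test_empty_input(self, config):
        counts = count_bins([], config)
        assert counts.total_warnings == 0
        assert counts.n_event_records == 0

    def test_record_under_both_types_rejected(self, config):
        rows = [
            FiducialRow("x", RecordType.EVENT, 40.0, 30.0),
            FiducialRow("x", RecordType.NONEVENT, None, 5.0),
        ]
        with pytest.raises(ValidationError, match="both record types"):
            count_bins(rows, config)

    def test_quiet_nonevent_counts_only_as_record(self, config):
        rows = [FiducialRow("n1", RecordType.NONEVENT, None, None)]
        counts = count_bins(rows, config)
        assert counts.total_warnings == 0
        assert counts.n_nonevent_records == 1

    def test_matches_brute_force_oracle(self, config):
        rng = np.random.default_rng(123)
        for _ in range(100):
            raw, rows = _random_fiducials(rng)
            counts = count_bins(rows, config)
            expect = count_oracle(raw, config.t_min, config.t_max)
            assert counts.by_category() == {
                Category.FALSE: expect["False"],
                Category.EARLY: expect["Early"],
                Category.ON_TIME: expect["On Time"],
                Category.LATE: expect["Late"],
                Category.MISSED: expect["Missed"],
            }
            assert counts.n_event_records == expect["n_event_records"]
            assert counts.n_nonevent_records == expect["n_nonevent_records"]


def _random_fiducials(rng, max_rows=60):
    raw, rows = [], []
    for _ in range(int(rng.integers(0, max_rows))):
        if rng.random() < 0.5:
            rid = f"e{rng.integers(0, 15)}"
            te = float(np.round(rng.uniform(0, 120), 2))
            tw = None if rng.random() < 0.2 else float(np.round(rng.uniform(-30, 150), 2))
            raw.append((rid, "event", te, tw))
            rows.append(FiducialRow(rid, RecordType.EVENT, te, tw))
        else:
            rid = f"n{rng.integers(0, 15)}"
            tw = None if rng.random() < 0.15 else float(np.round(rng.uniform(0, 120), 2))
            raw.append((rid, "nonevent", None, tw))
            rows.append(FiducialRow(rid, RecordType.NONEVENT, None, tw))
    return raw, rows


class TestWarningProportions:
    def test_case_study_responsive(self, responsive_counts):
        props = warning_proportions(responsive_counts)
        rounded = [round_half_even(props[c], 2) for c in Category]
        assert rounded == [0.48, 0.29, 0.19, 0.03, 0.02]

    def test_case_study_stay_on(self, stay_on_counts):
        props = warning_proportions(stay_on_counts)
        rounded = [round_half_even(props[c], 2) for c in Category]
        assert rounded == [0.32, 0.24, 0.40, 0.04, 0.04]

    def test_ideal_system(self):
        counts = BinCounts(0, 0, 5, 0, 0, n_event_records=5, n_nonevent_records=1)
        props = warning_proportions(counts)
        assert [props[c] for c in Category] == [0, 0, 1, 0, 0]

    def test_zero_warnings_undefined(self):
        counts = BinCounts(0, 0, 0, 0, 1, n_event_records=1, n_nonevent_records=0)
        with pytest.raises(ValidationError, match="undefined"):
            warning_proportions(counts)

    def test_four_warning_bins_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            f, e, o, l = (int(x) for x in rng.integers(0, 40, 4))
            m = int(rng.integers(0, 5))
            if f + e + o + l == 0:
                continue
            counts = BinCounts(f, e, o, l, m, n_event_records=m + 10, n_nonevent_records=3)
            props = warning_proportions(counts)
            four = (
                props[Category.FALSE]
                + props[Category.EARLY]
                + props[Category.ON_TIME]
                + props[Category.LATE]
            )
            assert four == pytest.approx(1.0, abs=1e-12)
            assert sum(props.values()) >= 1.0 - 1e-9


class TestWarningsPerRecord:
    def test_case_study_responsive(self, responsive_counts):
        per, undefined = warnings_per_record(responsive_counts)
        rounded = [round_half_even(per[c], 2) for c in Category]
        assert rounded == [2.5, 1.12, 0.75, 0.12, 0.06]
        assert undefined == frozenset()

    def test_case_study_stay_on(self, stay_on_counts):
        per, _ = warnings_per_record(stay_on_counts)
        rounded = [round_half_even(per[c], 2) for c in Category]
        assert rounded == [0.67, 0.38, 0.62, 0.06, 0.06]

    def test_single_timely_warning_per_event_record(self):
        counts = BinCounts(0, 0, 7, 0, 0, n_event_records=7, n_nonevent_records=2)
        per, _ = warnings_per_record(counts)
        assert [per[c] for c in Category] == [0, 0, 1, 0, 0]

    def test_zero_denominator_with_warnings_errors(self):
        counts = BinCounts(3, 0, 0, 0, 0, n_event_records=1, n_nonevent_records=0)
        with pytest.raises(ValidationError, match="False"):
            warnings_per_record(counts)

    def test_zero_over_zero_flagged(self):
        counts = BinCounts(2, 0, 0, 0, 0, n_event_records=0, n_nonevent_records=3)
        per, undefined = warnings_per_record(counts)
        assert undefined == frozenset(
            {Category.EARLY, Category.ON_TIME, Category.LATE, Category.MISSED}
        )
        assert per[Category.EARLY] == 0.0

    def test_event_side_sum_is_burden_ratio(
        self, responsive_counts, stay_on_counts
    ):
        for counts, expected in [(responsive_counts, 2.06), (stay_on_counts, 1.12)]:
            per, _ = warnings_per_record(counts)
            event_sum = sum(
                per[c]
                for c in (Category.EARLY, Category.ON_TIME, Category.LATE, Category.MISSED)
            )
            direct = (
                counts.n_early + counts.n_on_time + counts.n_late + counts.n_missed
            ) / counts.n_event_records
            assert event_sum == pytest.approx(direct)
            assert round_half_even(event_sum, 2) == expected


def _cohort_with_traces(config, n_event=16, n_nonevent=12, n_tp=14, n_fp=5):
    records, traces = [], []
    event_time, dur = 60.0, 120.0
    in_window_idx = int(event_time - (config.t_min + config.t_max) / 2)
    out_window_idx = int(event_time + 5)  # after the event: not in window
    for i in range(n_event):
        rid = f"e{i}"
        records.append(make_record(rid, duration=dur, event_time=event_time))
        state = np.zeros(int(dur) + 1, dtype=int)
        if i < n_tp:
            state[in_window_idx] = 1
        else:
            state[out_window_idx] = 1  # warned, but never inside the window
        traces.append(WarningTrace(rid, records[-1].times, state))
    for j in range(n_nonevent):
        rid = f"n{j}"
        records.append(make_record(rid, duration=dur))
        state = np.zeros(int(dur) + 1, dtype=int)
        if j < n_fp:
            state[3] = 1
        traces.append(WarningTrace(rid, records[-1].times, state))
    return records, traces


class TestTraditionalMetrics:
    def test_case_study_tallies(self, config):
        records, traces = _cohort_with_traces(config)
        m = traditional_metrics(traces, records, config)
        assert m.n_true_positive_records == 14
        assert m.n_false_positive_records == 5
        assert round_half_even(m.ppv, 1) == 73.7
        assert round_half_even(m.sensitivity, 1) == 87.5
        # computed FPR is 5/12 = 41.7%
        assert round_half_even(m.false_positive_rate, 1) == 41.7

    def test_no_warnings(self, config):
        records, traces = _cohort_with_traces(config, n_tp=0, n_fp=0)
        for t in traces:
            t.state[:] = 0
        m = traditional_metrics(traces, records, config)
        assert m.ppv is None
        assert m.sensitivity == 0.0
        assert m.false_positive_rate == 0.0

    def test_mismatched_traces_rejected(self, config, simple_record):
        rec = simple_record("r1")
        trace = WarningTrace("other", rec.times, np.zeros_like(rec.times, dtype=int))
        with pytest.raises(ValidationError):
            traditional_metrics([trace], [rec], config)

    def test_window_boundary_half_open(self, config, simple_record):
        # state on only at lead exactly t_max: outside the half-open window
        rec = simple_record("r1", event_time=60.0)
        state = np.zeros(rec.times.size, dtype=int)
        state[int(60 - config.t_max)] = 1
        m = traditional_metrics([WarningTrace("r1", rec.times, state)], [rec], config)
        assert m.n_true_positive_records == 0
        # at lead exactly t_min: inside
        state[:] = 0
        state[int(60 - config.t_min)] = 1
        m = traditional_metrics([WarningTrace("r1", rec.times, state)], [rec], config)
        assert m.n_true_positive_records == 1

    def test_tp_at_least_on_time_records(self, config):
        # any record with an On Time onset has an active in-window sample
        from warnprofile import count_bins, extract_episodes, generate_fixture

        spec = BinCounts(4, 3, 6, 2, 1, n_event_records=8, n_nonevent_records=5)
        traces, records = generate_fixture(spec, config, seed=3)
        eps = {t.record_id: extract_episodes(t) for t in traces}
        rows = build_fiducials(eps, records)
        on_time_records = {
            r.record_id
            for r in rows
            if r.time_warning is not None
            and r.record_type is RecordType.EVENT
            and categorize(r, config) is Category.ON_TIME
        }
        m = traditional_metrics(traces, records, config)
        assert m.n_true_positive_records >= len(on_time_records)


def test_profile_pair_combines_both():
    counts = BinCounts(2, 1, 3, 0, 1, n_event_records=4, n_nonevent_records=2)
    pair = profile_pair(counts)
    assert pair.warning_proportions[Category.ON_TIME] == pytest.approx(0.5)
    assert pair.warnings_per_record[Category.FALSE] == pytest.approx(1.0)


def test_record_length_warning(simple_record):
    short = simple_record("a", duration=30.0)
    long = simple_record("b", duration=120.0)
    with pytest.warns(RecordLengthWarning):
        check_record_lengths([short, long])
    with np.testing.assert_no_warnings():
        check_record_lengths([long, long])
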