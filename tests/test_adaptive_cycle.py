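import numpy as np
import pytest

from ecocycler.adaptive_cycle import (
    PhaseParams,
    anchor_reorganization,
    classify_phases,
    phase_durations,
    phase_schedule_indices,
    trend_signature,
)
from ecocycler.ena import IndexSeries


def make_indices(a, c, r, start_year=2019, span=0.3):
    a, c, r = (np.asarray(v, dtype=float) for v in (a, c, r))
    years = np.arange(start_year, start_year + len(a))
    from ecocycler.ena import smooth_series

    xs = years.astype(float)
    sm = (lambda v: smooth_series(v, span=span, x=xs)) if len(a) >= 3 else (lambda v: v)
    return IndexSeries(
        years=years, tst=a + r, ascendency=a, capacity=c, overhead=r,
        ascendency_smoothed=sm(a), capacity_smoothed=sm(c), overhead_smoothed=sm(r),
    )


def planted_scenario(rep):
    """Random growth -> collapse -> reorganization -> growth schedule over
    2019-2090 with 1 or 2 full cycles."""
    rng = np.random.default_rng(5000 + rep)
    y = 2019
    sched = []
    n_cycles = int(rng.integers(1, 3))
    for _ in range(n_cycles):
        g = int(rng.integers(12, 20))
        c = int(rng.integers(6, 10))
        a = int(rng.integers(5, 9))
        sched += [
            (y, y + g - 1, "growth_rK"),
            (y + g, y + g + c - 1, "collapse"),
            (y + g + c, y + g + c + a - 1, "reorganization"),
        ]
        y = y + g + c + a
    sched.append((y, 2090, "growth_rK"))
    return sched, int(rng.integers(2**31)), n_cycles


class TestTrendSignature:
    def test_rising_index_positive_slope(self):
        n = 30
        idx = make_indices(np.arange(n, dtype=float), np.full(n, 5.0), np.full(n, 3.0))
        sig = trend_signature(idx, 2034)
        assert sig.connectedness_slope > 0

    def test_constant_index_zero_slope(self):
        n = 30
        idx = make_indices(np.arange(n, dtype=float), np.full(n, 5.0), np.full(n, 3.0))
        sig = trend_signature(idx, 2034, epsilon=1e-6)
        assert sig.resilience_slope == 0.0

    def test_known_slope_recovered(self):
        n = 40
        line = 0.5 * np.arange(n) + 2.0
        idx = make_indices(line, line, line)
        sig = trend_signature(idx, 2039, epsilon=0.0)
        assert sig.connectedness_slope == pytest.approx(0.5, abs=1e-6)

    def test_year_outside_series_rejected(self):
        idx = make_indices(np.arange(10.0), np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            trend_signature(idx, 1990)


class TestAnchoring:
    def test_reorganization_signature_anchors(self):
        sched = [(2019, 2040, "growth_rK"), (2041, 2048, "collapse"),
                 (2049, 2056, "reorganization"), (2057, 2090, "growth_rK")]
        idx = phase_schedule_indices(sched, seed=1)
        anchored, rejected = anchor_reorganization([2049], idx)
        assert anchored == [2049]

    def test_all_rising_not_anchored(self):
        n = 72
        rising = np.arange(n, dtype=float)
        idx = make_indices(rising, rising + 2, rising + 5)
        anchored, rejected = anchor_reorganization([2019 + 36], idx)
        assert anchored == []
        assert rejected[0][1] == "connectedness not falling"

    def test_no_changepoints_no_reorganization(self):
        sched = [(2019, 2090, "growth_rK")]
        idx = phase_schedule_indices(sched, seed=2)
        seg = classify_phases(idx, [])
        assert seg.cycle_count == 0
        assert all(s.phase != "reorganization" for s in seg.segments)


class TestClassification:
    def test_pure_growth(self):
        n = 72
        rising = 50 + 0.8 * np.arange(n)
        falling = 80 - 0.5 * np.arange(n)
        idx = make_indices(rising, rising * 1.2, falling)
        seg = classify_phases(idx, [])
        assert seg.cycle_count == 0
        assert len(seg.segments) == 1
        assert seg.segments[0].phase == "growth_rK"
        assert (seg.segments[0].start_year, seg.segments[0].end_year) == (2019, 2090)

    def test_planted_schedule_recovered(self):
        sched = [(2019, 2033, "growth_rK"), (2034, 2041, "collapse"),
                 (2042, 2049, "reorganization"), (2050, 2090, "growth_rK")]
        idx = phase_schedule_indices(sched, seed=3)
        seg = classify_phases(idx, [2042])
        assert seg.cycle_count == 1
        true = {y: p for s, e, p in sched for y in range(s, e + 1)}
        pred = {y: s.phase for s in seg.segments for y in range(s.start_year, s.end_year + 1)}
        acc = np.mean([pred[y] == true[y] for y in true])
        assert acc >= 0.9

    def test_three_anchors_three_cycles(self):
        sched, seed, _ = planted_scenario(0)
        # build a 3-cycle schedule explicitly
        sched = [
            (2019, 2032, "growth_rK"), (2033, 2039, "collapse"), (2040, 2046, "reorganization"),
            (2047, 2058, "growth_rK"), (2059, 2065, "collapse"), (2066, 2072, "reorganization"),
            (2073, 2079, "growth_rK"), (2080, 2084, "collapse"), (2085, 2090, "reorganization"),
        ]
        idx = phase_schedule_indices(sched, seed=4)
        anchors = [2040, 2066, 2085]
        seg = classify_phases(idx, anchors)
        assert seg.cycle_count == 3

    def test_partition_invariant(self):
        for rep in range(10):
            sched, seed, _ = planted_scenario(rep)
            idx = phase_schedule_indices(sched, seed=seed)
            anchors = [s[0] for s in sched if s[2] == "reorganization"]
            seg = classify_phases(idx, anchors)
            # contiguous, non-overlapping, covering the window
            assert seg.segments[0].start_year == 2019
            assert seg.segments[-1].end_year == 2090
            for a, b in zip(seg.segments[:-1], seg.segments[1:]):
                assert b.start_year == a.end_year + 1
            assert sum(s.duration for s in seg.segments) == 72

    def test_cyclic_order_never_violated(self):
        for rep in range(20):
            sched, seed, _ = planted_scenario(rep)
            idx = phase_schedule_indices(sched, seed=seed)
            anchors = [s[0] for s in sched if s[2] == "reorganization"]
            seg = classify_phases(idx, anchors)
            phases = [s.phase for s in seg.segments if s.phase != "unclassified"]
            for prev, cur in zip(phases[:-1], phases[1:]):
                assert not (prev == "reorganization" and cur == "collapse")

    def test_anchoring_soundness(self):
        sched, seed, _ = planted_scenario(1)
        idx = phase_schedule_indices(sched, seed=seed)
        anchors = [s[0] for s in sched if s[2] == "reorganization"]
        anchored, _ = anchor_reorganization(anchors, idx)
        seg = classify_phases(idx, anchored)
        starts = {s.start_year for s in seg.segments if s.phase == "reorganization"}
        assert starts <= set(anchored)
        assert seg.cycle_count == len(starts)

    def test_empty_indices_rejected(self):
        idx = make_indices(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            classify_phases(idx, [])


class TestDurations:
    def test_single_segment(self):
        n = 91
        rising = 50 + 0.8 * np.arange(n)
        falling = 80 - 0.5 * np.arange(n)
        idx = make_indices(rising, rising * 1.2, falling, start_year=2000)
        seg = classify_phases(idx, [])
        df = phase_durations(seg)
        assert df["duration"].tolist() == [91]

    def test_durations_partition_window(self):
        sched, seed, _ = planted_scenario(2)
        idx = phase_schedule_indices(sched, seed=seed)
        anchors = [s[0] for s in sched if s[2] == "reorganization"]
        seg = classify_phases(idx, anchors)
        df = phase_durations(seg)
        assert df["duration"].sum() == 72
        for phase, sub in df.groupby("phase"):
            assert np.allclose(sub["phase_mean_duration"], sub["duration"].mean())


def test_schedule_builder_requires_contiguity():
    with pytest.raises(ValueError, match="contiguous"):
        phase_schedule_indices([(2019, 2030, "growth_rK"), (2032, 2040, "collapse")])
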