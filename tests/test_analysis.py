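"""Event-locked metrics on synthetic traces."""

import numpy as np
import pytest

from vtanet.analysis import (
    NOT_ACQUIRED,
    burst_duration,
    has_sub_criterion_run,
    selectivity_census,
    trials_to_dip,
    window_extremum,
)
from vtanet.protocol import ProbeMetrics


def bump(n=2000, center=1000, width=100, amp=1.0, base=0.2):
    t = np.arange(n)
    return base + amp * np.exp(-0.5 * ((t - center) / (width / 2.355)) ** 2)


class TestWindowExtremum:
    def test_constant_trace(self):
        tr = np.full(1000, 0.2)
        assert window_extremum(tr, 500, 100, "max") == 0.2
        assert window_extremum(tr, 500, 100, "min") == 0.2

    def test_finds_peak_inside_window(self):
        tr = bump(center=700, amp=0.8)
        assert window_extremum(tr, 700, 100, "max") == pytest.approx(1.0, abs=1e-6)
        assert window_extremum(tr, 1500, 100, "max") < 0.3

    def test_max_at_least_min(self):
        rng = np.random.default_rng(3)
        tr = rng.uniform(0, 1, 3000)
        hi = window_extremum(tr, 1500, 100, "max")
        lo = window_extremum(tr, 1500, 100, "min")
        assert hi >= lo

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="outside"):
            window_extremum(np.zeros(500), 450, 100, "max")

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            window_extremum(np.zeros(500), 250, 10, "median")


class TestBurstDuration:
    def test_flat_trace_zero(self):
        assert burst_duration(np.full(2000, 0.2), 1000) == 0.0

    def test_known_width(self):
        tr = np.full(2000, 0.2)
        tr[950:1150] = 1.0  # 200 ms above threshold
        assert burst_duration(tr, 1000, threshold=0.25) == 200.0

    def test_time_shift_invariance(self):
        tr1 = np.full(3000, 0.2)
        tr1[950:1150] = 0.9
        tr2 = np.roll(tr1, 700)
        d1 = burst_duration(tr1, 1000)
        d2 = burst_duration(tr2, 1700)
        assert d1 == d2

    def test_run_extends_beyond_window(self):
        # the contiguous run containing the peak is followed outside the
        # +-100 ms search window
        tr = np.full(3000, 0.2)
        tr[950:1500] = 0.9
        assert burst_duration(tr, 1000) == 550.0


class TestSubCriterionRun:
    def test_requires_consecutive_samples(self):
        tr = np.full(1000, 0.2)
        tr[100:119] = 0.0   # 19 ms only
        assert not has_sub_criterion_run(tr, 0.05, 20)
        tr[100:120] = 0.0   # 20 ms
        assert has_sub_criterion_run(tr, 0.05, 20)

    def test_interrupted_run_does_not_count(self):
        tr = np.full(1000, 0.2)
        tr[100:160] = 0.0
        tr[130] = 0.1  # single noise sample splits the run into 30 + 29 ms
        assert not has_sub_criterion_run(tr, 0.05, 31)
        assert has_sub_criterion_run(tr, 0.05, 30)


class TestTrialsToDip:
    def metrics(self, dips_at):
        out = []
        for a, first in dips_at.items():
            for k in range(1, 16):
                dipped = first is not None and k >= first
                out.append(ProbeMetrics(assoc_id=a, trial_index=k,
                                        min_vta=0.0 if dipped else 0.2,
                                        max_nacc=1.0 if dipped else 0.0,
                                        dipped=dipped))
        return out

    def test_first_dip_index(self):
        pm = self.metrics({1: 3, 2: 7, 3: 2})
        assert trials_to_dip(pm, 1) == 3
        assert trials_to_dip(pm, 2) == 7
        assert trials_to_dip(pm, 3) == 2

    def test_never_acquired_sentinel(self):
        pm = self.metrics({1: None})
        assert trials_to_dip(pm, 1) == NOT_ACQUIRED


class TestSelectivityCensus:
    def test_single_winner_per_reward(self):
        n, t = 10, 3000
        traces = {}
        for a, winner in [(1, 2), (2, 5), (3, 8)]:
            tr = np.zeros((t, n))
            tr[1000:1200, winner] = 0.9
            tr[1000:1200, (winner + 1) % n] = 0.05
            traces[a] = tr
        census = selectivity_census(traces, {a: (1100, 100) for a in traces})
        assert census == {1: (1, 2), 2: (1, 5), 3: (1, 8)}

    def test_no_winner_before_learning(self):
        tr = {1: np.full((2000, 10), 0.05)}
        census = selectivity_census(tr, {1: (1000, 100)})
        assert census[1][0] == 0
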