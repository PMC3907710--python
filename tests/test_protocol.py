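"""Trial timelines and schedule structure."""

import numpy as np
import pytest

from vtanet import build_network
from vtanet.protocol import (
    ASSOCIATIONS,
    Schedule,
    TrialSpec,
    make_trial,
    run_trial,
)


class TestTrialTimelines:
    def test_paired_duration_is_interval_plus_three_seconds(self):
        for a, assoc in ASSOCIATIONS.items():
            tl = make_trial(TrialSpec(a, "paired"))
            assert tl.n_steps == int(assoc.interval * 1000) + 3000

    def test_paired_event_times(self):
        tl = make_trial(TrialSpec(3, "paired"))
        assert tl.events["cs_onset"] == 1000
        assert tl.events["us_onset"] == 5000      # 4 s interval
        assert tl.events["us_offset"] == 6000
        # CS stays on through the US
        assert np.all(tl.cs[1000:6000, 2] == 1.0)
        assert np.all(tl.cs[:1000] == 0.0) and np.all(tl.cs[6000:] == 0.0)
        assert np.all(tl.us[5000:6000] == [1, 0, 1, 1])

    def test_omission_has_no_us_anywhere(self):
        tl = make_trial(TrialSpec(2, "omission"))
        assert np.all(tl.us == 0.0)
        assert tl.events["expected_us"] == 4000
        # CS timeline identical to the paired variant
        paired = make_trial(TrialSpec(2, "paired"))
        np.testing.assert_array_equal(tl.cs, paired.cs)

    def test_early_delivery_moves_us_one_second_forward(self):
        tl = make_trial(TrialSpec(1, "early"))
        assert tl.events["us_onset"] == 2000      # trained time is 3000
        assert tl.events["trained_us"] == 3000
        # the CS ends together with the US
        assert tl.events["cs_offset"] == 3000
        assert np.all(tl.cs[3000:] == 0.0)

    def test_early_with_one_second_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            TrialSpec(1, "early", interval=1.0)

    def test_sensitization_has_no_cs(self):
        tl = make_trial(TrialSpec(1, "sensitization"))
        assert tl.n_steps == 3000
        assert np.all(tl.cs == 0.0)
        assert np.all(tl.us[1000:2000] == [1, 1, 0, 0])

    def test_magnitude_defaults_from_association(self):
        assert TrialSpec(1).magnitude == 0.8
        assert TrialSpec(2).magnitude == 0.5
        assert TrialSpec(3, magnitude=0.25).magnitude == 0.25

    def test_unknown_association_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec(4)


class TestSchedule:
    def test_standard_counts_and_phase_boundary(self):
        s = Schedule.standard()
        assert len(s.trials) == 30 + 45
        assert s.phase_switch_index == 30
        assert all(t.variant == "sensitization"
                   for t in s.trials[:s.phase_switch_index])
        # conditioning interleaved in ascending order
        assocs = [t.assoc_id for t in s.trials[s.phase_switch_index:]]
        assert assocs == [1, 2, 3] * 15


class TestDeterminism:
    @pytest.mark.parametrize("engine", ["numba", "numpy"])
    def test_same_seed_identical_traces(self, engine):
        tl = make_trial(TrialSpec(1, "sensitization"))
        out = []
        for _ in range(2):
            net = build_network(rng=77)
            tr = run_trial(net, tl, learning_on=True, record=("VTA", "BLA"),
                           engine=engine)
            out.append(tr)
        np.testing.assert_array_equal(out[0]["VTA"], out[1]["VTA"])
        np.testing.assert_array_equal(out[0]["BLA"], out[1]["BLA"])

    def test_learning_off_leaves_weights_untouched(self):
        net = build_network(rng=3)
        before = net.weights_snapshot()
        run_trial(net, make_trial(TrialSpec(1, "paired")), learning_on=False,
                  record=())
        after = net.weights_snapshot()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])


class TestEngineAgreement:
    def test_numba_matches_numpy_reference(self):
        """The compiled kernel and the numpy step integrate the same system:
        identical noise streams must give near-identical trajectories."""
        from vtanet._kernel import HAVE_NUMBA

        if not HAVE_NUMBA:
            pytest.skip("numba unavailable; only one engine to compare")
        tl = make_trial(TrialSpec(1, "paired"))
        tr = {}
        for engine in ("numba", "numpy"):
            net = build_network(rng=11)
            tr[engine] = run_trial(net, tl, learning_on=True,
                                   record=("VTA", "BLA", "NAcc"), engine=engine)
        for key in ("VTA", "BLA", "NAcc"):
            np.testing.assert_allclose(tr["numba"][key], tr["numpy"][key],
                                       atol=1e-9)
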