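"""Penalized change-point solver: costs, PELT vs the exhaustive dynamic
program, penalty calibration and the frame/second conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitring import segmentation as sg
from gaitring.preprocess import SpectralSeries


def piecewise_signal(rng, n, d, n_breaks, snr=8.0):
    """Noisy piecewise-constant signal; breaks kept >= 4 frames apart so the
    annotation respects the solver's minimum segment length."""
    raw = np.sort(rng.choice(np.arange(4, n - 4), size=n_breaks, replace=False))
    bks = []
    for b in raw:
        if not bks or b - bks[-1] >= 4:
            bks.append(int(b))
    levels = rng.normal(0, snr, size=(len(bks) + 1, d))
    y = np.empty((n, d))
    for lev, a, b in zip(levels, [0, *bks], [*bks, n]):
        y[a:b] = lev + rng.normal(0, 1.0, size=(b - a, d))
    return y, bks


class TestSegmentCost:
    def test_constant_segment_is_free(self):
        assert sg.segment_cost(np.ones(10), 0, 10) == 0.0

    def test_hand_example(self):
        # values [0,0,4,4]: mean 2, squared deviations 4+4+4+4 = 16
        assert sg.segment_cost(np.array([0.0, 0, 4, 4]), 0, 4) == pytest.approx(16.0)

    def test_matches_naive_two_pass(self, rng):
        y = rng.normal(size=(60, 5))
        cm = sg.CostModel(y)
        for a, b in [(0, 60), (3, 17), (30, 32), (59, 60)]:
            seg = y[a:b]
            naive = float(np.sum((seg - seg.mean(axis=0)) ** 2))
            assert cm.cost(a, b) == pytest.approx(naive, abs=1e-9)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            sg.segment_cost(np.ones(5), 3, 3)


class TestPenalizedRisk:
    def test_constant_signal_no_breaks(self):
        assert sg.penalized_risk(np.ones(8), [], beta=1.0) == 0.0

    def test_hand_example(self):
        y = np.array([0.0, 0, 0, 4, 4, 4])
        assert sg.penalized_risk(y, [3], beta=1.0) == pytest.approx(1.0)
        assert sg.penalized_risk(y, [], beta=1.0) == pytest.approx(24.0)

    def test_exact_piecewise_constant_costs_only_penalty(self):
        y = np.repeat([1.0, 5.0, -2.0], 10)
        assert sg.penalized_risk(y, [10, 20], beta=7.0) == pytest.approx(14.0)


class TestPelt:
    def test_step_signal(self):
        y = np.array([0.0, 0, 0, 4, 4, 4])
        assert sg.pelt_segment(y, beta=1.0, min_size=2).breakpoints == (3,)
        assert sg.pelt_segment(y, beta=30.0, min_size=2).breakpoints == ()

    def test_constant_signal_never_splits(self):
        for beta in (1e-6, 1.0, 1e6):
            assert sg.pelt_segment(np.ones(50), beta).breakpoints == ()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sg.pelt_segment(np.ones(3), 1.0, min_size=2)

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        """Risk-value equivalence with the exhaustive dynamic program
        (ties may differ in breakpoints but never in risk)."""
        for trial in range(40):
            d = 1 if trial % 2 == 0 else 3
            n = int(rng.integers(20, 45))
            y, _ = piecewise_signal(rng, n, d, int(rng.integers(0, 4)))
            beta = float(10 ** rng.uniform(-1, 3))
            a = sg.pelt_segment(y, beta)
            b = sg.brute_force_segment(y, beta)
            ra = sg.penalized_risk(y, a, beta)
            rb = sg.penalized_risk(y, b, beta)
            assert ra == pytest.approx(rb, rel=1e-9, abs=1e-9)

    def test_numpy_and_numba_cores_agree(self, rng):
        y, _ = piecewise_signal(rng, 80, 2, 3)
        cm = sg.CostModel(y)
        for beta in (0.5, 10.0, 300.0):
            last_py = sg._pelt_py(cm._s1, cm._s2, beta, 2)
            bks_py = sg.Segmentation(sg._backtrack(last_py), 80)
            bks = sg.pelt_segment(y, beta)
            assert sg.penalized_risk(y, bks, beta) == pytest.approx(
                sg.penalized_risk(y, bks_py, beta)
            )

    def test_break_count_non_increasing_in_beta(self, rng):
        y, _ = piecewise_signal(rng, 120, 4, 5)
        ks = [sg.pelt_segment(y, b).K for b in np.logspace(-2, 4, 15)]
        assert all(k2 <= k1 for k1, k2 in zip(ks, ks[1:]))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=8, max_size=20),
           st.integers(min_value=1, max_value=6))
    def test_adding_a_break_never_increases_unpenalized_risk(self, vals, pos):
        y = np.asarray(vals, dtype=float)
        pos = 1 + pos % (len(y) - 2)
        r0 = sg.penalized_risk(y, [], beta=0.0)
        r1 = sg.penalized_risk(y, [pos], beta=0.0)
        assert r1 <= r0 + 1e-9

    def test_tiny_beta_min_size_one_drives_risk_to_zero(self, rng):
        y = rng.normal(size=12)
        seg = sg.brute_force_segment(y, beta=1e-12, min_size=1)
        assert sg.penalized_risk(y, seg, beta=0.0) == pytest.approx(0.0, abs=1e-9)


class TestCalibration:
    def test_zero_gap_interval_recovered(self, rng):
        """When PELT already reproduces the annotation on an interval of
        beta, the calibrated beta lies in that interval with gap 0."""
        y, bks = piecewise_signal(rng, 60, 2, 2, snr=20.0)
        cal = sg.calibrate_penalty([(y, bks)])
        assert cal.objective_value == pytest.approx(0.0, abs=1e-9)
        seg = sg.pelt_segment(y, cal.beta_opt)
        assert sg.penalized_risk(y, seg, cal.beta_opt) == pytest.approx(
            sg.penalized_risk(y, bks, cal.beta_opt)
        )

    def test_gap_non_negative_on_grid(self, rng):
        """The excess penalized risk of the annotation over the PELT optimum
        is non-negative for every beta, by optimality of the solver."""
        pairs = []
        for _ in range(3):
            y, bks = piecewise_signal(rng, 50, 2, 2, snr=3.0)
            pairs.append((y, bks))
        cal = sg.calibrate_penalty(pairs, n_grid=15)
        for trace in cal.per_signal_gaps:
            assert all(g >= -1e-8 for g in trace["gaps"])

    def test_recovers_truth_on_high_snr_signals(self, rng):
        train, test = [], []
        for i in range(8):
            y, bks = piecewise_signal(rng, 80, 3, 2, snr=15.0)
            (train if i < 4 else test).append((y, bks))
        cal = sg.calibrate_penalty(train)
        for y, bks in test:
            assert sg.pelt_segment(y, cal.beta_opt).breakpoints == tuple(bks)

    def test_per_signal_mode(self, rng):
        pairs = [piecewise_signal(rng, 50, 2, 2, snr=15.0) for _ in range(3)]
        cal = sg.calibrate_penalty(pairs, per_signal=True, n_grid=10)
        assert cal.beta_opt > 0
        assert len(cal.per_signal_gaps) == 3

    def test_annotation_out_of_range_rejected(self, rng):
        y, _ = piecewise_signal(rng, 30, 1, 1)
        with pytest.raises(ValueError):
            sg.calibrate_penalty([(y, [40])])


class TestFrameTimeConventions:
    def test_frame_to_seconds_arithmetic(self):
        spec = SpectralSeries(
            frames=np.zeros((200, 28)),
            frame_times_s=1.5 + 0.1 * np.arange(200),
        )
        seg = sg.Segmentation(breakpoints=(100,), n=200)
        assert sg.frames_to_seconds(seg, spec)[0] == pytest.approx(11.5)

    def test_seconds_round_trip_within_half_hop(self):
        spec = SpectralSeries(
            frames=np.zeros((500, 28)),
            frame_times_s=1.5 + 0.1 * np.arange(500),
        )
        for t in (2.04, 17.31, 40.0):
            idx = sg.seconds_to_frames([t], spec)
            back = spec.frame_times_s[idx[0]]
            assert abs(back - t) <= 0.05 + 1e-12

    def test_interior_only(self):
        spec = SpectralSeries(frames=np.zeros((50, 28)),
                              frame_times_s=1.5 + 0.1 * np.arange(50))
        idx = sg.seconds_to_frames([0.0, 100.0], spec)
        assert all(0 < i < 50 for i in idx)
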