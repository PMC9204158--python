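"""Grasp-onset alignment, averaged curves, t_i, d_p and confusion."""

import numpy as np
import pytest

import emgrasp as eg
from emgrasp.evaluation import EvaluationCurves


def _proba(rows):
    """Rows of (class -> prob) dicts to (n, 14) arrays; rest goes to col 0."""
    out = np.zeros((len(rows), 14))
    for i, row in enumerate(rows):
        for c, p in row.items():
            out[i, c] = p
    return out


def _aligned(times, proba, gesture, phases=None, trial_id="t"):
    times = np.asarray(times, dtype=float)
    if phases is None:
        phases = ["grasping"] * times.size
    return eg.AlignedTrial(
        times_ms=times, proba=proba, phases=phases, gesture=gesture,
        prepended=np.zeros(times.size, dtype=bool), has_prepend=False,
        trial_id=trial_id,
    )


def _curves(times, g, r, top=None, support=None, n_trials=10):
    times = np.asarray(times, dtype=float)
    g = np.asarray(g, dtype=float)
    r = np.asarray(r, dtype=float)
    top = np.zeros_like(g) if top is None else np.asarray(top, dtype=float)
    support = np.full(times.size, n_trials) if support is None else support
    ones = np.ones_like(g)
    return EvaluationCurves(
        times_ms=times, p_grasp=g, p_rest=r, p_top=top,
        acc_grasp=ones, acc_rest=ones,
        support=support, support_grasp=support, support_rest=support,
        n_trials=n_trials,
    )


class TestAlign:
    def test_window_at_grasp_onset_maps_to_zero(self):
        times = np.arange(0, 400, 40.0)
        tr = eg.align(times, _proba([{1: 1.0}] * 10), ["reaching"] * 10,
                      grasp_onset_ms=120.0, gesture=1)
        assert tr.times_ms[3] == 0.0

    def test_offset_snaps_to_grid(self):
        times = np.arange(0, 400, 40.0)
        tr = eg.align(times, _proba([{1: 1.0}] * 10), ["reaching"] * 10,
                      grasp_onset_ms=118.0, gesture=1)
        assert np.all(np.mod(tr.times_ms, 40.0) == 0)
        assert tr.times_ms[3] == 0.0  # 118 rounds to the 120 grid line

    def test_no_predecessor_flagged(self):
        tr = _aligned([0, 40], _proba([{1: 1}, {1: 1}]), 1)
        assert not tr.has_prepend
        assert not tr.prepended.any()


class TestAverageCurves:
    def test_single_trial_curves_equal_its_values(self):
        p = _proba([{3: 0.7, 0: 0.2, 5: 0.1}, {3: 0.6, 0: 0.3, 5: 0.1}])
        tr = _aligned([-40, 0], p, 3)
        c = eg.average_curves([tr])
        np.testing.assert_allclose(c.p_grasp, [0.7, 0.6])
        np.testing.assert_allclose(c.p_rest, [0.2, 0.3])
        np.testing.assert_allclose(c.p_top, [0.1, 0.1])

    def test_two_constant_trials_average(self):
        a = _aligned([0, 40], _proba([{2: 0.2}] * 2), 2)
        b = _aligned([0, 40], _proba([{2: 0.6}] * 2), 2)
        c = eg.average_curves([a, b])
        np.testing.assert_allclose(c.p_grasp, [0.4, 0.4])
        np.testing.assert_array_equal(c.support, [2, 2])

    def test_support_counts_cover_union_grid(self):
        a = _aligned([0, 40], _proba([{1: 1}] * 2), 1)
        b = _aligned([40, 80], _proba([{1: 1}] * 2), 1)
        c = eg.average_curves([a, b])
        np.testing.assert_array_equal(c.times_ms, [0, 40, 80])
        np.testing.assert_array_equal(c.support, [1, 2, 1])

    def test_mean_between_pointwise_min_and_max(self, rng):
        trials = []
        for _ in range(6):
            p = rng.dirichlet(np.ones(14), size=5)
            trials.append(_aligned(np.arange(5) * 40.0, p, 4))
        c = eg.average_curves(trials)
        stack = np.stack([t.proba[:, 4] for t in trials])
        assert np.all(c.p_grasp <= stack.max(axis=0) + 1e-12)
        assert np.all(c.p_grasp >= stack.min(axis=0) - 1e-12)

    def test_top_competitor_excludes_rest_and_gesture(self):
        p = _proba([{0: 0.5, 4: 0.3, 9: 0.2}])
        tr = _aligned([0], p, 4)
        assert tr.top_competitor()[0] == pytest.approx(0.2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            eg.average_curves([])


class TestIntersectionTime:
    def test_grasp_always_above_gives_earliest_time(self):
        c = _curves(np.arange(-200, 1, 40), [0.6] * 6, [0.4] * 6)
        assert eg.intersection_time(c) == -200.0

    def test_symmetric_linear_crossing_at_midpoint(self):
        t = np.arange(-1000, 1, 40.0)
        g = np.linspace(0, 1, t.size)
        r = np.linspace(1, 0, t.size)
        assert eg.intersection_time(_curves(t, g, r)) == pytest.approx(-500.0)

    def test_bracketed_crossing_interpolated(self):
        t = np.array([-560.0, -520.0, -480.0, -440.0, -400.0])
        g = np.array([0.40, 0.45, 0.55, 0.60, 0.65])
        r = np.array([0.55, 0.50, 0.50, 0.45, 0.40])
        # linear crossing between -520 and -480: deltas -0.05 -> +0.05
        assert eg.intersection_time(_curves(t, g, r)) == pytest.approx(-500.0)

    def test_no_crossing_returns_none(self):
        c = _curves(np.arange(-200, 1, 40), [0.2] * 6, [0.7] * 6)
        assert eg.intersection_time(c) is None

    def test_transient_crossing_rejected_by_persistence(self):
        t = np.arange(-280, 1, 40.0)
        g = np.array([0.3, 0.6, 0.3, 0.3, 0.6, 0.6, 0.6, 0.6])
        r = np.full(8, 0.5)
        # first exceedance lasts one grid point; persistent run starts at -120
        ti = eg.intersection_time(_curves(t, g, r), persistence=3)
        assert -160.0 < ti <= -120.0

    def test_low_support_tail_masked(self):
        t = np.arange(-280, 1, 40.0)
        g = np.array([0.9, 0.9, 0.2, 0.2, 0.6, 0.6, 0.6, 0.6])
        r = np.full(8, 0.5)
        support = np.array([1, 1, 10, 10, 10, 10, 10, 10])
        ti = eg.intersection_time(_curves(t, g, r, support=support), persistence=3)
        assert ti > -200.0  # the under-supported early exceedance is ignored


class TestProbabilityMargin:
    def test_peak_minus_competitor(self):
        t = np.arange(-80, 81, 40.0)
        g = [0.2, 0.5, 0.9, 0.5, 0.2]
        top = [0.1, 0.1, 0.05, 0.1, 0.1]
        assert eg.probability_margin(_curves(t, g, [0.1] * 5, top)) == pytest.approx(0.85)

    def test_coinciding_curves_give_zero(self):
        t = np.arange(-80, 81, 40.0)
        g = [0.2, 0.5, 0.9, 0.5, 0.2]
        assert eg.probability_margin(_curves(t, g, [0.1] * 5, g)) == 0.0

    def test_three_class_toy_matches_hand_computation(self):
        # two trials, gesture 1; classes {0, 1, 2} only
        a = _aligned([0, 40], _proba([{1: 0.5, 0: 0.3, 2: 0.2},
                                      {1: 0.7, 0: 0.1, 2: 0.2}]), 1)
        b = _aligned([0, 40], _proba([{1: 0.9, 0: 0.05, 2: 0.05},
                                      {1: 0.3, 0: 0.3, 2: 0.4}]), 1)
        c = eg.average_curves([a, b])
        # p_grasp = [0.7, 0.5], peak at t=0; p_top there = (0.2 + 0.05)/2
        assert eg.probability_margin(c, min_support_frac=0.0) == pytest.approx(0.7 - 0.125)
        assert -1.0 <= eg.probability_margin(c, min_support_frac=0.0) <= 1.0

    def test_earliest_peak_wins_ties(self):
        t = np.arange(-80, 81, 40.0)
        g = [0.2, 0.9, 0.9, 0.5, 0.2]
        top = [0.0, 0.3, 0.1, 0.0, 0.0]
        assert eg.probability_margin(_curves(t, g, [0.1] * 5, top)) == pytest.approx(0.6)


class TestAccuracyCurves:
    def test_perfect_predictor_gives_unit_accuracy(self):
        phases = ["reaching", "grasping", "returning", "resting"]
        p = _proba([{2: 1.0}, {2: 1.0}, {2: 1.0}, {0: 1.0}])
        tr = _aligned(np.arange(4) * 40.0, p, 2, phases=phases)
        _, acc_g, acc_r = eg.accuracy_curves([tr])
        assert np.all(acc_g[:3] == 1.0)
        assert acc_r[3] == 1.0

    def test_uniform_random_predictor_near_chance(self, rng):
        trials = []
        for _ in range(1000):
            p = rng.dirichlet(np.ones(14), size=4)
            trials.append(_aligned(np.arange(4) * 40.0, p,
                                   int(rng.integers(1, 14)),
                                   phases=["grasping"] * 4))
        c = eg.average_curves(trials)
        assert np.all(np.abs(c.acc_grasp - 1 / 14) < 0.03)

    def test_curve_values_bounded(self, rng):
        trials = [
            _aligned(np.arange(6) * 40.0, rng.dirichlet(np.ones(14), size=6), 3,
                     phases=["reaching"] * 3 + ["resting"] * 3)
            for _ in range(10)
        ]
        c = eg.average_curves(trials)
        for curve in (c.p_grasp, c.p_rest, c.p_top):
            assert np.all((curve >= 0) & (curve <= 1))
        assert np.all((c.acc_grasp[:3] >= 0) & (c.acc_grasp[:3] <= 1))


class TestConfusion:
    def test_perfect_predictor_identity(self):
        trials = [
            _aligned([-80, -40, 0], _proba([{g: 1.0}] * 3), g)
            for g in range(1, 6)
        ]
        conf = eg.confusion(trials, window_ms=(-100.0, 0.0))
        assert conf.mean_diagonal == 1.0
        pop = conf.populated_classes()
        np.testing.assert_array_equal(pop, np.arange(1, 6))
        assert np.all(conf.matrix[pop, pop] == 1.0)

    def test_constant_class_three_predictor(self):
        trials = [
            _aligned([-40, 0], _proba([{3: 1.0}] * 2), g)
            for g in (1, 2, 4)
        ]
        conf = eg.confusion(trials, window_ms=(-100.0, 0.0))
        assert np.all(conf.matrix[[1, 2, 4], 3] == 1.0)
        assert conf.mean_diagonal == 0.0

    def test_rows_normalized_where_populated(self, rng):
        trials = [
            _aligned(np.arange(-3, 1) * 40.0, rng.dirichlet(np.ones(14), size=4), g)
            for g in range(1, 8)
        ]
        conf = eg.confusion(trials)
        pop = conf.populated_classes()
        np.testing.assert_allclose(conf.matrix[pop].sum(axis=1), 1.0)

    def test_windows_outside_range_excluded(self):
        tr = _aligned([-2000, 0], _proba([{5: 1.0}, {1: 1.0}]), 1)
        conf = eg.confusion([tr], window_ms=(-100.0, 0.0))
        assert conf.counts.sum() == 1
        assert conf.matrix[1, 1] == 1.0

    def test_empty_window_rejected(self):
        tr = _aligned([0], _proba([{1: 1.0}]), 1)
        with pytest.raises(ValueError, match="no windows"):
            eg.confusion([tr], window_ms=(-400.0, -200.0))
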