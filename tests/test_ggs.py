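"""Segmentation: score formula, greedy fit vs exact oracle, phase annotation."""

import numpy as np
import pytest

import emgrasp as eg
from emgrasp.ggs import ABS_FLOOR


def _blocks(stds, n_per, d, rng, means=None):
    """Piecewise-stationary series: one block per std, i.i.d. Gaussian."""
    parts = []
    for k, s in enumerate(stds):
        mu = 0.0 if means is None else means[k]
        parts.append(mu + s * rng.standard_normal((n_per, d)))
    return np.concatenate(parts, axis=0)


def _direct_score(x, lam):
    """Independent re-derivation of the segment score (plain numpy)."""
    x = np.atleast_2d(x.T).T
    n, d = x.shape
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / n
    reg = lam * np.trace(cov) / d + ABS_FLOOR
    sign, logdet = np.linalg.slogdet(cov + reg * np.eye(d))
    return -(n / 2) * logdet


class TestSegmentScore:
    def test_matches_direct_formula(self, rng):
        x = rng.standard_normal((200, 4))
        for (i, j) in [(0, 200), (10, 55), (120, 200)]:
            assert eg.segment_score(x, i, j, 0.05) == pytest.approx(
                _direct_score(x[i:j], 0.05), rel=1e-12
            )

    def test_unit_variance_segment_scores_near_zero(self):
        x = np.random.default_rng(0).standard_normal(100)
        # -(n/2) log(sigma^2) with sigma^2 ~ 1 -> near 0 for tiny lambda
        assert abs(eg.segment_score(x, 0, 100, 1e-9)) < 20

    def test_constant_segment_finite_via_floor(self):
        x = np.full((50, 3), 2.5)
        s = eg.segment_score(x, 0, 50, 1e-3)
        assert np.isfinite(s)

    def test_offset_invariance(self, rng):
        x = rng.standard_normal((120, 3))
        a = eg.segment_score(x, 0, 120, 0.1)
        b = eg.segment_score(x + 7.3, 0, 120, 0.1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_degenerate_interval_rejected(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            eg.segment_score(x, 5, 5, 0.1)


class TestGreedyFit:
    CFG = dict(cov_reg=0.1, min_segment_samples=20)

    def test_no_breakpoints_objective_is_whole_series_score(self, rng):
        x = rng.standard_normal((150, 2))
        cfg = eg.GgsConfig(n_breakpoints=0, **self.CFG)
        seg = eg.ggs_fit(x, cfg)
        assert seg.n_breakpoints == 0
        assert seg.objective == pytest.approx(eg.segment_score(x, 0, 150, 0.1))

    def test_four_block_recovery(self):
        rng = np.random.default_rng(8)
        x = _blocks([0.1, 1.0, 0.5, 0.1], 100, 12, rng)
        seg = eg.ggs_fit(x, eg.GgsConfig(n_breakpoints=3, **self.CFG))
        np.testing.assert_allclose(seg.breakpoints, [100, 200, 300], atol=2)

    def test_objective_history_non_decreasing(self, rng):
        for x in (
            rng.standard_normal((200, 3)),
            _blocks([0.2, 1.0, 0.4, 0.1], 60, 3, rng),
        ):
            seg = eg.ggs_fit(x, eg.GgsConfig(n_breakpoints=3, **self.CFG))
            h = np.array(seg.objective_history)
            assert np.all(np.diff(h) >= -1e-9 * np.abs(h[:-1]))

    def test_scale_equivariance_of_breakpoints(self, rng):
        x = _blocks([0.2, 1.0, 0.4], 80, 3, rng)
        cfg = eg.GgsConfig(n_breakpoints=2, **self.CFG)
        a = eg.ggs_fit(x, cfg)
        b = eg.ggs_fit(10.0 * x, cfg)
        np.testing.assert_array_equal(a.breakpoints, b.breakpoints)

    def test_infeasible_length_rejected(self):
        x = np.zeros((30, 2))
        with pytest.raises(ValueError):
            eg.ggs_fit(x, eg.GgsConfig(n_breakpoints=3, cov_reg=0.1, min_segment_samples=20))


class TestExhaustiveOracle:
    def test_never_below_greedy(self, rng):
        for _ in range(10):
            x = rng.standard_normal((80, 2))
            greedy = eg.ggs_fit(
                x, eg.GgsConfig(n_breakpoints=2, cov_reg=0.1, min_segment_samples=8)
            )
            _, best = eg.exhaustive_fit(x, 2, 0.1, 8)
            assert best >= greedy.objective - 1e-9 * abs(best)

    def test_greedy_matches_oracle_on_separated_blocks(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(20):
            # variance ratio >= 10 between neighboring blocks
            x = _blocks([0.1, 1.0, 0.1, 1.0], 30, 2, rng)
            bps, best = eg.exhaustive_fit(x, 3, 0.1, 8)
            greedy = eg.ggs_fit(
                x, eg.GgsConfig(n_breakpoints=3, cov_reg=0.1, min_segment_samples=8)
            )
            assert greedy.objective >= best - 0.01 * abs(best)
            hits += np.array_equal(bps, greedy.breakpoints)
        assert hits == 20

    def test_single_split_matches_brute_force(self, rng):
        x = _blocks([0.2, 1.5], 50, 2, rng)
        bps, best = eg.exhaustive_fit(x, 1, 0.1, 8)
        # independent brute force over every feasible single split
        scores = {
            t: eg.segment_score(x, 0, t, 0.1) + eg.segment_score(x, t, 100, 0.1)
            for t in range(8, 93)
        }
        t_star = max(scores, key=lambda t: (scores[t], -t))
        assert bps[0] == t_star
        assert abs(bps[0] - 50) <= 1
        assert best == pytest.approx(scores[t_star])

    def test_refuses_large_instances(self, rng):
        x = rng.standard_normal((5000, 2))
        with pytest.raises(ValueError, match="too large"):
            eg.exhaustive_fit(x, 3, 0.1, 2)


class TestPhaseAnnotation:
    def _seg(self, bps=(100, 200, 300), n=400):
        return eg.SegmentedTrial(
            breakpoints=np.array(bps), n_samples=n, fs_seg=100.0,
            breakpoints_orig=np.array(bps), n_samples_orig=n, fs_orig=100.0,
            objective=0.0,
        )

    def test_assign_phases_canonical_order(self):
        seg = eg.assign_phases(self._seg())
        assert seg.phase_names == ("reaching", "grasping", "returning", "resting")
        assert seg.phase_at(500.0) == "reaching"
        assert seg.phase_at(1500.0) == "grasping"
        assert seg.phase_at(3999.0) == "resting"

    def test_segment_durations_partition_trial(self):
        seg = eg.assign_phases(self._seg())
        total = sum(e - s for s, e in seg.segments)
        assert total == seg.n_samples

    def test_assign_phases_requires_three_breakpoints(self):
        seg = eg.SegmentedTrial(
            breakpoints=np.array([100]), n_samples=400, fs_seg=100.0,
            breakpoints_orig=np.array([100]), n_samples_orig=400, fs_orig=100.0,
            objective=0.0,
        )
        with pytest.raises(ValueError):
            eg.assign_phases(seg)

    def test_gesture_annotation_labels(self):
        seg = self._seg()
        labels = eg.annotate_gesture(seg, 5)
        assert set(labels) == {0, 5}
        assert np.all(labels[:300] == 5)
        assert np.all(labels[300:] == 0)
        with pytest.raises(ValueError):
            eg.annotate_gesture(seg, 14)

    def test_grasp_onset_is_first_breakpoint(self):
        seg = eg.assign_phases(self._seg())
        assert seg.grasp_onset_ms == pytest.approx(1000.0)


class TestEnvelopeSegmentation:
    def test_breakpoints_map_back_to_original_rate(self, small_envelopes, small_session):
        envs, _ = small_envelopes
        t = small_session.trials[0]
        seg = eg.segment_envelope(envs[t.trial_id], eg.GgsConfig())
        assert seg.fs_orig == pytest.approx(1562.5)
        assert seg.fs_seg == pytest.approx(100.0)
        ms_from_orig = seg.breakpoints_orig / seg.fs_orig * 1000.0
        np.testing.assert_allclose(ms_from_orig, seg.breakpoints_ms, atol=10.0)

    def test_recovers_ground_truth_roughly(self, small_envelopes, small_session):
        envs, _ = small_envelopes
        errs = []
        for t in small_session.trials:
            seg = eg.segment_envelope(envs[t.trial_id], eg.GgsConfig())
            errs.extend(
                np.abs(np.asarray(seg.breakpoints_ms) - np.asarray(t.timeline.breakpoints_ms))
            )
        assert np.median(errs) <= 50.0

    def test_roundtrip_through_dict(self, small_envelopes, small_session):
        envs, _ = small_envelopes
        t = small_session.trials[0]
        seg = eg.segment_envelope(envs[t.trial_id], eg.GgsConfig(), trial_id=t.trial_id)
        back = eg.SegmentedTrial.from_dict(seg.to_dict())
        np.testing.assert_array_equal(back.breakpoints_orig, seg.breakpoints_orig)
        assert back.phase_names == seg.phase_names
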