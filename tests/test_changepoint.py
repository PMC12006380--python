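"""WBS2 candidate generation, SDLL model selection and segment statistics."""

import numpy as np
import pytest

import asap
from asap.changepoint import cusum_stats, mad_sigma

from .conftest import beats_from_hr


def brute_force_cusum_max(x: np.ndarray, min_seg: int = 2) -> float:
    """Exhaustive CUSUM maximum over every interval and every split."""
    best = -np.inf
    n = x.size
    for s in range(n):
        for e in range(s + 2 * min_seg, n + 1):
            _, stats_ = cusum_stats(x, s, e, min_seg)
            if stats_.size:
                best = max(best, stats_.max())
    return best


class TestWbs2Candidates:
    def test_clean_step_found_exactly(self):
        x = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        cands = asap.wbs2_candidates(x, seed=0)
        top = max(cands, key=lambda c: c.cusum_mag)
        assert top.index == 50

    def test_constant_series_near_zero_magnitudes(self):
        cands = asap.wbs2_candidates(np.full(40, 7.0), seed=0)
        assert all(c.cusum_mag < 1e-9 for c in cands)

    def test_winner_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 12)
        cands = asap.wbs2_candidates(x, n_intervals=500, min_seg=2, seed=1)
        assert cands[0].cusum_mag == pytest.approx(brute_force_cusum_max(x), rel=1e-12)

    def test_too_short_returns_empty(self):
        assert asap.wbs2_candidates(np.array([1.0, 2.0, 3.0]), min_seg=2) == []


class TestSdllSelect:
    def test_noise_free_two_shifts_exact(self):
        x = np.concatenate([np.full(60, 100.0), np.full(50, 90.0), np.full(70, 98.0)])
        cands = asap.wbs2_candidates(x, seed=0)
        sel = asap.sdll_select(cands, mad_sigma(x), x.size)
        assert list(sel) == [60, 110]

    def test_three_shifts_exact(self):
        x = np.concatenate(
            [np.full(40, 120.0), np.full(35, 112.0), np.full(45, 119.0), np.full(40, 126.0)]
        )
        cands = asap.wbs2_candidates(x, seed=3)
        sel = asap.sdll_select(cands, mad_sigma(x), x.size)
        assert list(sel) == [40, 75, 120]

    def test_pure_noise_mostly_empty(self):
        hits = 0
        for seed in range(20):
            z = np.random.default_rng(seed).normal(0, 1, 400)
            sel = asap.sdll_select(asap.wbs2_candidates(z, seed=seed + 1), mad_sigma(z), 400)
            hits += sel.size == 0
        assert hits >= 18

    def test_planted_shift_localised(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.concatenate([np.full(200, 120.0), np.full(200, 112.0)]) + rng.normal(0, 2, 400)
            sel = asap.sdll_select(asap.wbs2_candidates(x, seed=seed + 1), mad_sigma(x), 400)
            ok += any(abs(int(p) - 200) <= 2 for p in sel)
        assert ok >= 19

    def test_empty_candidates(self):
        assert asap.sdll_select([], 1.0, 100).size == 0


class TestSegmentStats:
    def test_delta_and_direction(self):
        x = np.concatenate([np.full(20, 120.0), np.full(20, 112.0)])
        seg = asap.segment_stats(x, [20])
        assert seg.deltas[0] == pytest.approx(-8.0)
        assert seg.directions[0] == "descending"

    def test_no_changepoints_single_segment(self):
        x = np.random.default_rng(0).normal(100, 2, 30)
        seg = asap.segment_stats(x, [])
        assert seg.n_segments == 1
        assert seg.segment_means[0] == pytest.approx(x.mean())

    def test_means_match_brute_force(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        cps = [13, 29]
        seg = asap.segment_stats(x, cps)
        assert seg.segment_means == pytest.approx(
            [x[:13].mean(), x[13:29].mean(), x[29:].mean()]
        )

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            asap.segment_stats(np.zeros(10), [10])

    def test_times_taken_from_beats(self):
        beats = beats_from_hr(np.full(30, 120.0))
        seg = asap.segment_stats(beats.hr_bpm, [10], beats=beats)
        assert seg.times[0] == pytest.approx(beats.hr_times[10])


class TestInvariances:
    def test_location_equivariance(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([np.full(80, 0.0), np.full(80, 6.0)]) + rng.normal(0, 1, 160)
        sel_a = asap.sdll_select(asap.wbs2_candidates(x, seed=2), mad_sigma(x), x.size)
        y = x + 57.3
        sel_b = asap.sdll_select(asap.wbs2_candidates(y, seed=2), mad_sigma(y), y.size)
        assert list(sel_a) == list(sel_b)

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([np.full(80, 0.0), np.full(80, 6.0)]) + rng.normal(0, 1, 160)
        y = 3.7 * x
        sel_a = asap.sdll_select(asap.wbs2_candidates(x, seed=4), mad_sigma(x), x.size)
        sel_b = asap.sdll_select(asap.wbs2_candidates(y, seed=4), mad_sigma(y), y.size)
        assert list(sel_a) == list(sel_b)

    def test_selected_locations_minimise_rss(self):
        """With the true K, greedy selection matches the exhaustive RSS optimum."""
        x = np.concatenate([np.full(10, 0.0), np.full(8, 9.0), np.full(12, 3.0)])
        sel = asap.sdll_select(asap.wbs2_candidates(x, seed=0), mad_sigma(x), x.size)
        assert sel.size == 2

        def rss(cps):
            bounds = [0, *cps, x.size]
            return sum(
                np.sum((x[a:b] - x[a:b].mean()) ** 2) for a, b in zip(bounds[:-1], bounds[1:])
            )

        best = min(
            ((p, q) for p in range(2, x.size - 3) for q in range(p + 2, x.size - 1)),
            key=rss,
        )
        assert tuple(sel) == best

    def test_detection_rate_on_simulator_sessions(self):
        """Simulator sessions produce one change point per 5-15 heartbeats."""
        rates = []
        for seed in range(3):
            sess = asap.simulate_session(asap.SimParams(duration_s=600, seed=seed))
            seg = asap.detect_changepoints(sess.beats, seed=0)
            rates.append((sess.beats.n_beats - 1) / max(seg.change_points.size, 1))
        assert 5.0 <= np.mean(rates) <= 15.0
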