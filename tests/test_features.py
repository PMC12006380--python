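"""Wavelet packet bands, wavelet coherence, SDRR and matrix assembly."""

import numpy as np
import pytest

import asap
from asap.features import (
    FEATURE_NAMES,
    modwpt_coefficients,
    segment_covariates,
)

from .conftest import beats_from_hr


def uniform(values, rate=2.0, mask=None):
    return asap.UniformSeries(0.0, rate, np.asarray(values, float), mask)


class TestModwpt:
    def test_bands_sum_to_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 600)
        bands = asap.modwpt_bands(x)
        assert bands.shape == (16, 600)
        err = np.linalg.norm(bands.sum(axis=0) - x) / np.linalg.norm(x)
        assert err <= 1e-8

    def test_coefficient_energy_conserved(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 500)
        coeffs = modwpt_coefficients(x)
        rel = abs(np.sum(coeffs**2) - np.sum(x**2)) / np.sum(x**2)
        assert rel <= 1e-6

    def test_white_noise_band_energies_roughly_equal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 2**14)
        coeffs = modwpt_coefficients(x)
        shares = np.sum(coeffs**2, axis=1) / np.sum(x**2)
        assert np.all(np.abs(shares - 1 / 16) < 0.2 / 16)

    def test_sinusoid_localised_to_its_band(self):
        # 0.10 Hz at 2 Hz sampling falls in band 2 (0.0625-0.125 Hz)
        t = np.arange(4096) / 2.0
        x = np.sin(2 * np.pi * 0.10 * t)
        bands = asap.modwpt_bands(x)
        energies = np.sum(bands**2, axis=1)
        assert energies[1] / energies.sum() > 0.5

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            asap.modwpt_bands(np.zeros(10))


class TestLswCoherence:
    def test_self_coherence_at_clip_ceiling(self):
        rng = np.random.default_rng(3)
        x = uniform(rng.normal(0, 1, 512))
        z = asap.lsw_coherence(x, x)
        assert z.shape == (12, 512)
        assert np.all(np.tanh(z) > 0.999)

    def test_shared_slow_signal_prefers_coarse_scales(self):
        rng = np.random.default_rng(4)
        t = np.arange(2048) / 2.0
        slow = np.sin(2 * np.pi * 0.05 * t)
        x = uniform(slow + 0.3 * rng.normal(0, 1, t.size))
        y = uniform(slow + 0.3 * rng.normal(0, 1, t.size))
        z = asap.lsw_coherence(x, y)
        coarse = np.abs(np.tanh(z[4:8])).mean()
        finest = np.abs(np.tanh(z[:2])).mean()
        assert coarse > finest

    def test_coherence_bounded(self):
        rng = np.random.default_rng(5)
        x = uniform(rng.normal(0, 1, 300))
        y = uniform(rng.normal(0, 1, 300))
        z = asap.lsw_coherence(x, y)
        assert np.all(np.abs(np.tanh(z)) <= 1.0 - 1e-7)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            asap.lsw_coherence(uniform(np.zeros(128)), uniform(np.zeros(256)))


class TestSdrr:
    def test_constant_ibi_zero(self):
        assert asap.sdrr(asap.BeatSeries(np.arange(20) * 0.45)) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_case(self):
        beats = asap.BeatSeries(np.array([0.0, 0.4, 0.9, 1.5]))
        assert asap.sdrr(beats) == pytest.approx(0.1)

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(6)
        ibis = rng.uniform(0.35, 0.55, 50)
        beats = asap.BeatSeries(np.concatenate([[0.0], np.cumsum(ibis)]))
        mean = ibis.mean()
        expected = np.sqrt(np.sum((ibis - mean) ** 2) / (ibis.size - 1))
        assert asap.sdrr(beats) == pytest.approx(expected)

    def test_too_few_beats_raises(self):
        with pytest.raises(ValueError):
            asap.sdrr(asap.BeatSeries(np.array([0.0, 0.5])))


class TestSegmentCovariates:
    def test_single_interval(self):
        grid = uniform(np.zeros(120))  # 60 s at 2 Hz
        cp, dur, lat = segment_covariates(asap.AttentionIntervals([(10.0, 20.0)]), grid)
        inside = (grid.times >= 10) & (grid.times < 20)
        assert np.all(cp[inside] == 1) and np.all(cp[~inside] == 0)
        assert np.allclose(dur[inside], 10.0)

    def test_latency_between_intervals(self):
        grid = uniform(np.zeros(120))
        step1 = asap.AttentionIntervals([(10.0, 20.0), (30.0, 40.0)])
        _, _, lat = segment_covariates(step1, grid)
        second = (grid.times >= 30) & (grid.times < 40)
        assert np.allclose(lat[second], 10.0)  # 30 - 20

    def test_matches_brute_force_lookup(self):
        rng = np.random.default_rng(7)
        onsets = np.sort(rng.uniform(0, 80, 4))
        ivs = []
        for on in onsets:
            off = on + rng.uniform(2, 6)
            if not ivs or on > ivs[-1][1]:
                ivs.append((on, min(off, 100.0)))
        step1 = asap.AttentionIntervals(ivs)
        grid = uniform(np.zeros(200))
        cp, dur, lat = segment_covariates(step1, grid)
        bounds = sorted({0.0, 100.0, *(x for iv in ivs for x in iv)})
        for i, t in enumerate(grid.times):
            for a, b in zip(bounds[:-1], bounds[1:]):
                if a <= t < b:
                    assert dur[i] == pytest.approx(b - a)
                    prev_ends = [q1 for _, q1 in ivs if q1 <= a]
                    expected_lat = a - prev_ends[-1] if prev_ends else 0.0
                    assert lat[i] == pytest.approx(expected_lat)
                    break


class TestAssemble:
    def _build(self, n=256, mask=None):
        rng = np.random.default_rng(8)
        hr = uniform(120 + rng.normal(0, 2, n), mask=mask)
        acc = uniform(np.abs(rng.normal(0.3, 0.1, n)), mask=mask)
        step1 = asap.AttentionIntervals([(10.0, 20.0)])
        return asap.assemble(
            hr, acc,
            asap.modwpt_bands(hr), asap.modwpt_bands(acc),
            asap.lsw_coherence(hr, acc),
            0.05, segment_covariates(step1, hr), 12.0,
        )

    def test_exactly_51_columns_in_order(self):
        m = self._build()
        assert tuple(m.data.columns) == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 51

    def test_mask_propagates(self):
        mask = np.zeros(256, dtype=bool)
        mask[40:60] = True
        m = self._build(mask=mask)
        assert m.row_mask[40:60].all()
        assert np.isfinite(m.X.to_numpy()).all()

    def test_wpt_columns_sum_to_source(self):
        m = self._build()
        wpt_hr = m.data[[f"WPT-HR-{i}" for i in range(1, 17)]].to_numpy().sum(axis=1)
        assert np.allclose(wpt_hr, m.data["HR"].to_numpy(), rtol=1e-8, atol=1e-8)

    def test_csv_roundtrip(self, tmp_path):
        m = self._build()
        path = tmp_path / "matrix.csv"
        m.to_csv(path)
        back = asap.FeatureMatrix.from_csv(path)
        assert np.allclose(back.data.to_numpy(), m.data.to_numpy())
        assert np.array_equal(back.row_mask, m.row_mask)
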