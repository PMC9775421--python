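"""Smoothing operators, cross-wavelet coherence and gated phase."""

import numpy as np
import pytest

from cawave.cwt_core import build_scale_grid, cwt_forward
from cawave.errors import ConfigError
from cawave.wavelet_coherence import (
    CoherencePhaseMap,
    SmoothingConfig,
    coherence_map,
    coherence_sq,
    cross_spectrum,
    phase_shift,
    smooth_scale,
    smooth_time,
)


class TestSmoothTime:
    def test_constant_row_preserved(self):
        scales = np.array([0.5])
        row = np.full((1, 256), 2.0 - 1.5j)
        out = smooth_time(row, scales, 0.01)
        assert np.allclose(out, row, atol=1e-12)

    def test_impulse_becomes_gaussian(self):
        # closed form: inverse transform of the Gaussian kernel
        n, dt, s, c = 1024, 0.01, 0.3, 0.25
        row = np.zeros((1, n), complex)
        row[0, 400] = 1.0
        out = smooth_time(row, np.array([s]), dt, c).real[0]
        m = (np.arange(n) - 400) * dt
        expected = dt / (2 * s * np.sqrt(np.pi * c)) * np.exp(-(m**2) / (4 * c * s**2))
        assert np.argmax(out) == 400
        k = np.arange(1, 100)
        assert np.allclose(out[400 + k], out[400 - k], atol=1e-12)  # symmetry
        assert np.allclose(out, expected, atol=1e-6 * expected.max())

    def test_gaussian_semigroup(self):
        rng = np.random.default_rng(0)
        scales = np.array([0.1, 0.5, 2.0])
        mat = rng.normal(size=(3, 512)) + 1j * rng.normal(size=(3, 512))
        twice = smooth_time(smooth_time(mat, scales, 0.01, 0.25), scales, 0.01, 0.25)
        once = smooth_time(mat, scales, 0.01, 0.5)
        assert np.max(np.abs(twice - once)) < 1e-10

    def test_shape_mismatch(self):
        with pytest.raises(ConfigError):
            smooth_time(np.zeros((2, 64)), np.array([1.0]), 0.01)


class TestSmoothScale:
    def test_identity_and_pair_mean(self):
        mat = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(smooth_scale(mat, 1), mat)
        out = smooth_scale(mat, 2)
        assert np.allclose(out[0], [2.0, 3.0])
        assert np.allclose(out[1], mat[1])  # renormalized partial mean

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(20, 8)) + 1j * rng.normal(size=(20, 8))
        ls = 7
        out = smooth_scale(mat, ls)
        for j in range(20):
            rows = mat[j : min(j + ls, 20)]
            expected = sum(rows[i] for i in range(len(rows))) / len(rows)
            assert np.allclose(out[j], expected, atol=1e-12)

    def test_window_too_long(self):
        with pytest.raises(ConfigError):
            smooth_scale(np.zeros((3, 4)), 4)


class TestCrossSpectrum:
    def test_self_is_real_nonnegative(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(3, 16)) + 1j * rng.normal(size=(3, 16))
        c = cross_spectrum(a, a)
        assert np.allclose(c.imag, 0.0)
        assert np.all(c.real >= 0)

    def test_constant_rotation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(2, 16)) + 1j * rng.normal(size=(2, 16))
        phi = 0.7
        c = cross_spectrum(a, a * np.exp(1j * phi))
        assert np.allclose(np.angle(c), phi)

    def test_shape_mismatch(self):
        with pytest.raises(ConfigError):
            cross_spectrum(np.zeros((2, 3)), np.zeros((3, 2)))


class TestSmoothingConfig:
    def test_disabled_smoothing_refused(self):
        with pytest.raises(ConfigError, match="identically 1"):
            SmoothingConfig(time_kernel_coeff=0.0)
        with pytest.raises(ConfigError):
            SmoothingConfig(time_kernel_coeff=-1.0)
        with pytest.raises(ConfigError):
            SmoothingConfig(ls=0)

    def test_default_scale_window_is_seven_voices(self):
        assert SmoothingConfig().resolve_ls(1 / 12) == 7


@pytest.fixture(scope="module")
def coeffs():
    rng = np.random.default_rng(4)
    dt, n = 0.01, 1024
    t = np.arange(n) * dt
    x = np.sin(2 * np.pi * 0.5 * t) + 0.3 * rng.normal(size=n)
    y = np.sin(2 * np.pi * 0.5 * t + 0.8) + 0.3 * rng.normal(size=n)
    g = build_scale_grid(dt, n).restrict(0.1, 3.0)
    return cwt_forward(x, g), cwt_forward(y, g), g


class TestCoherence:

    def test_self_coherence_is_one(self, coeffs):
        cx, _, g = coeffs
        cmap = coherence_sq(cx, cx)
        ok = np.isfinite(cmap.coh2)
        assert np.all(cmap.coh2[ok] >= 1 - 1e-9)

    def test_literal_unsmoothed_form_is_degenerate(self, coeffs):
        # pointwise normalized product of (smoothed) coefficients == 1:
        # the guard the smoothing requirement protects against
        cx, cy, _ = coeffs
        num = np.abs(np.conj(cx.values) * cy.values) ** 2
        den = np.abs(cx.values) ** 2 * np.abs(cy.values) ** 2
        assert np.allclose(num / den, 1.0)

    def test_swap_symmetry(self, coeffs):
        cx, cy, _ = coeffs
        m1 = coherence_map(cx, cy)
        m2 = coherence_map(cy, cx)
        assert np.nanmax(np.abs(m1.coh2 - m2.coh2)) < 1e-12
        both = np.isfinite(m1.phase) & np.isfinite(m2.phase)
        assert np.allclose(m1.phase[both], -m2.phase[both], atol=1e-12)

    def test_scaling_invariance(self, coeffs):
        cx, cy, _ = coeffs
        m1 = coherence_map(cx, cy)
        m2 = coherence_map(cx * 3.0, cy * 0.25)
        assert np.nanmax(np.abs(m1.coh2 - m2.coh2)) < 1e-12
        both = np.isfinite(m1.phase) & np.isfinite(m2.phase)
        assert np.allclose(m1.phase[both], m2.phase[both], atol=1e-12)

    def test_gate_monotone_in_threshold(self, coeffs):
        cx, cy, _ = coeffs
        lo = coherence_sq(cx, cy, threshold=0.5)
        hi = coherence_sq(cx, cy, threshold=0.8)
        assert not np.any(hi.gate & ~lo.gate)

    def test_coh2_bounded(self, coeffs):
        cx, cy, _ = coeffs
        cmap = coherence_sq(cx, cy)
        ok = np.isfinite(cmap.coh2)
        assert np.all((cmap.coh2[ok] >= 0) & (cmap.coh2[ok] <= 1))

    def test_band_limited_coupling(self, mk_pair, mk_map, narrow_cfg):
        # signals sharing only the Mayer component cohere there, not off-band
        from cawave.config import RunConfig

        cfg = RunConfig({"cwt.fmin": 0.05, "cwt.fmax": 0.6})
        in_band, off_band = [], []
        for seed in range(3):
            rec = mk_pair(phase_lead=1.0, seed=seed + 50, duration_s=81.92)
            cmap, grid = mk_map(rec, frame_len=8192, cfg=cfg)
            bi = grid.band_indices(0.08, 0.12)
            oi = grid.band_indices(0.3, 0.5)
            in_band.append(np.nanmean(cmap.coh2[bi]))
            off_band.append(np.nanmean(cmap.coh2[oi]))
        assert np.mean(in_band) > np.mean(off_band)


class TestPhaseShift:
    def _map_for(self, cross):
        shape = cross.shape
        g = build_scale_grid(0.01, 256).restrict(1.0, 50.0)
        return CoherencePhaseMap(
            coh2=np.ones(shape),
            phase=np.full(shape, np.nan),
            gate=np.ones(shape, dtype=bool),
            threshold=0.6,
            grid=g,
            times=np.arange(shape[1]) * 0.01,
        )

    def test_axis_cases(self):
        cross = np.array([[1.0 + 0.0j, 1j, -1j, -1.0 + 0.0j]])
        cmap = phase_shift(self._map_for(cross), cross)
        assert cmap.phase[0, 0] == 0.0
        assert cmap.phase[0, 1] == pytest.approx(np.pi / 2)
        assert cmap.phase[0, 2] == pytest.approx(-np.pi / 2)
        assert cmap.phase[0, 3] == pytest.approx(np.pi)  # (-pi, pi] convention

    def test_ungated_phase_is_missing(self):
        cross = np.full((1, 4), 1j)
        cmap = self._map_for(cross)
        cmap.gate[0, 2] = False
        cmap = phase_shift(cmap, cross)
        assert np.isnan(cmap.phase[0, 2])
        assert np.isfinite(cmap.phase[0, 1])

    def test_known_lead_recovered(self, coupled_map):
        # construction: flow velocity leads pressure by 1.0 rad at 0.1 Hz
        j = coupled_map.grid.nearest_index(0.1)
        ph = coupled_map.phase[j]
        assert np.nanmedian(ph) == pytest.approx(1.0, abs=0.05)


class TestLadderRestriction:
    def test_band_rows_unchanged_by_restriction(self, mk_pair):
        from cawave.config import RunConfig
        from cawave.pipeline import _grid, process_frame_cwt
        from cawave.signal_io import make_frames

        rec = mk_pair(phase_lead=0.9, seed=11, duration_s=40.96)
        frame = make_frames(rec, 4096, 4096)[0]
        full_cfg = RunConfig({})
        nar_cfg = RunConfig({"cwt.fmin": 0.055, "cwt.fmax": 0.13})
        gf = _grid(full_cfg, frame.n, rec.dt)
        gn = _grid(nar_cfg, frame.n, rec.dt)
        mf = process_frame_cwt(frame, gf, full_cfg)
        mn = process_frame_cwt(frame, gn, nar_cfg)
        bf = gf.band_indices(0.08, 0.12)
        bn = gn.band_indices(0.08, 0.12)
        assert np.array_equal(mf.coh2[bf], mn.coh2[bn], equal_nan=True)
        assert np.array_equal(mf.phase[bf], mn.phase[bn], equal_nan=True)
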