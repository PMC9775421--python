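"""Band extraction, subrange scanning, sensitivity, subject summaries."""

import numpy as np
import pytest

from cawave.cwt_core import build_scale_grid
from cawave.errors import ConfigError, InsufficientDataError, UndefinedSensitivityError
from cawave.mayer_metrics import (
    BandSeries,
    extract_band,
    sensitivity,
    subrange_scan,
    summarize_subject,
)
from cawave.wavelet_coherence import CoherencePhaseMap


def _toy_map(coh_rows=None, n_times=6, threshold=0.6):
    """Small map on the default 16384-sample grid."""
    g = build_scale_grid(0.01, 16384)
    shape = (len(g), n_times)
    coh2 = np.zeros(shape)
    if coh_rows:
        for j, val in coh_rows.items():
            coh2[j] = val
    gate = coh2 >= threshold
    phase = np.where(gate, 0.5, np.nan)
    return CoherencePhaseMap(
        coh2=coh2,
        phase=phase,
        gate=gate,
        threshold=threshold,
        grid=g,
        times=np.arange(n_times) * 0.01,
        frame_meta={"center_s": 1.0},
    )


def _series(times, phase, side="left", method="cwt"):
    times = np.asarray(times, float)
    phase = np.asarray(phase, float)
    return BandSeries(
        times=times,
        phase=phase,
        coh2=np.where(np.isfinite(phase), 0.9, 0.1),
        freq_used=np.full(len(times), 0.0988),
        side=side,
        method=method,
    )


class TestExtractBand:
    def test_unique_maximum_selected(self):
        g = build_scale_grid(0.01, 16384)
        j = g.nearest_index(0.098)
        cmap = _toy_map({j: 1.0})
        series = extract_band(cmap)
        assert series.freq_used[0] == pytest.approx(0.0988, abs=1e-3)
        assert series.phase[0] == pytest.approx(0.5)

    def test_all_below_threshold_gives_missing(self):
        g = build_scale_grid(0.01, 16384)
        cmap = _toy_map({g.nearest_index(0.1): 0.4})
        series = extract_band(cmap)
        assert np.isnan(series.phase[0])

    def test_fixed_picker(self):
        g = build_scale_grid(0.01, 16384)
        j1, j2 = g.nearest_index(0.088), g.nearest_index(0.104)
        cmap = _toy_map({j1: 1.0, j2: 0.7})
        series = extract_band(cmap, picker="fixed", fixed_freq=0.104)
        assert series.freq_used[0] == pytest.approx(g.pseudo_freqs[j2])

    def test_errors(self):
        cmap = _toy_map()
        with pytest.raises(ConfigError):
            extract_band(cmap, band=(0.0001, 0.0002))
        with pytest.raises(ConfigError):
            extract_band(cmap, picker="fixed")
        with pytest.raises(ConfigError):
            extract_band(cmap, picker="nope")


class TestSubrangeScan:
    def test_all_gated_selected(self):
        g = build_scale_grid(0.01, 16384)
        j = g.nearest_index(0.11)
        table = subrange_scan([_toy_map({j: 0.9})])
        sel = table[table.selected]
        assert len(sel) == 1
        assert sel.iloc[0]["fraction"] == 1.0
        assert sel.iloc[0]["freq_hz"] == pytest.approx(g.pseudo_freqs[j])

    def test_all_ungated_selection_undefined(self):
        table = subrange_scan([_toy_map()])
        assert np.all(table["fraction"] == 0.0)
        assert not table["selected"].any()

    def test_agrees_with_fixed_picker_gating(self, coupled_map):
        # fraction at f == non-missing share of the per-sample fixed-f series
        table = subrange_scan([coupled_map], band=(0.08, 0.12))
        for _, row in table.iterrows():
            series = extract_band(
                coupled_map,
                band=(0.08, 0.12),
                picker="fixed",
                fixed_freq=row["freq_hz"],
                mode="sample",
            )
            share = np.isfinite(series.phase).mean()
            assert share == pytest.approx(row["fraction"], abs=1e-12)

    def test_coupling_selection_within_smoothing_window(self, mk_pair, mk_map):
        # The forward scale window averages a tone's coherence into the
        # Ls-1 voices above it, so the recommended subrange lies at or
        # above the coupled frequency, within that window - and well above
        # the uncoupled band bottom.
        for seed in range(5):
            rec = mk_pair(
                phase_lead=1.0, seed=seed + 30, duration_s=163.84,
                white_sd=1.0, amplitude=0.2,
            )
            cmap, grid = mk_map(rec)
            table = subrange_scan([cmap])
            sel = table[table.selected].iloc[0]
            f0 = grid.pseudo_freqs[grid.nearest_index(0.1)]
            assert f0 * 0.999 <= sel["freq_hz"] <= f0 * 2 ** (7 / 12)
            bottom = table.iloc[-1]  # lowest in-band frequency
            assert sel["fraction"] > bottom["fraction"]


class TestSensitivity:
    def test_direct_arithmetic(self):
        s = _series([0, 1, 2, 3, 4, 10, 11, 12, 13, 14], [1.0] * 5 + [0.85] * 5)
        res = sensitivity(s, (10, 14), (0, 4), "min")
        assert res.eta == pytest.approx(0.15)
        assert res.theta_ext == pytest.approx(0.85)

    def test_null_effect(self):
        s = _series(np.arange(10), [1.0] * 10)
        res = sensitivity(s, (5, 9), (0, 4), "max")
        assert res.eta == 0.0

    def test_invariant_to_ungated_samples(self):
        times = np.arange(12)
        base = [1.0] * 5 + [0.7] * 5
        s1 = _series(times[:10], base)
        padded = base[:5] + [np.nan, np.nan] + base[5:]
        s2 = _series(times, padded)
        r1 = sensitivity(s1, (5, 9), (0, 4), "min")
        r2 = sensitivity(s2, (7, 11), (0, 4), "min")
        assert r1.eta == r2.eta

    def test_insufficient_gated_samples(self):
        s = _series(np.arange(6), [1.0, 1.0, np.nan, 0.8, 0.8, 0.8])
        with pytest.raises(InsufficientDataError):
            sensitivity(s, (3, 5), (0, 2), "min")

    def test_nonpositive_baseline_undefined(self):
        s = _series(np.arange(10), [0.0] * 5 + [0.5] * 5)
        with pytest.raises(UndefinedSensitivityError):
            sensitivity(s, (5, 9), (0, 4), "max")

    def test_direction_validated(self):
        s = _series(np.arange(10), [1.0] * 10)
        with pytest.raises(ConfigError):
            sensitivity(s, (5, 9), (0, 4), "down")


class TestSummarizeSubject:
    def test_identical_sides(self):
        rng = np.random.default_rng(8)
        ph = 1.0 + 0.05 * rng.normal(size=20)
        s = summarize_subject(_series(np.arange(20), ph), _series(np.arange(20), ph, "right"))
        assert s.asymmetry_p == 1.0
        assert s.left.mean == s.right.mean
        assert s.left.ci_low <= s.left.mean <= s.left.ci_high

    def test_distinct_sides_significant(self):
        rng = np.random.default_rng(9)
        left = 1.0 + 1e-4 * rng.normal(size=15)
        right = 0.5 + 1e-4 * rng.normal(size=15)
        s = summarize_subject(_series(np.arange(15), left), _series(np.arange(15), right, "right"))
        assert s.asymmetry_p < 0.001
        assert s.left.mean > s.right.mean

    def test_matches_hand_computed_pooled_t(self):
        # 3-vs-3 textbook worked example
        a = np.array([1.1, 1.3, 1.2])
        b = np.array([0.9, 1.0, 0.8])
        s = summarize_subject(_series(np.arange(3), a), _series(np.arange(3), b, "right"))
        na, nb = 3, 3
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        tstat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        import scipy.stats

        p = 2 * scipy.stats.t.sf(abs(tstat), na + nb - 2)
        assert s.asymmetry_p == pytest.approx(p, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        ph = 1.0 + 0.1 * rng.normal(size=12)
        perm = rng.permutation(12)
        s1 = summarize_subject(_series(np.arange(12), ph), _series(np.arange(12), ph[perm], "right"))
        assert s1.left.mean == pytest.approx(s1.right.mean, rel=1e-12)
        assert s1.left.sd == pytest.approx(s1.right.sd, rel=1e-12)

    def test_zero_variance_distinct_means(self):
        s = summarize_subject(
            _series(np.arange(4), [1.0] * 4), _series(np.arange(4), [0.5] * 4, "right")
        )
        assert s.asymmetry_p == 0.0

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            summarize_subject(
                _series(np.arange(3), [1.0, np.nan, np.nan]),
                _series(np.arange(3), [1.0, 1.0, 1.0], "right"),
            )

    def test_wraparound_warning(self):
        with pytest.warns(UserWarning, match="wraparound"):
            summarize_subject(
                _series(np.arange(4), [3.1, 3.05, -3.1, 3.0]),
                _series(np.arange(4), [1.0, 1.1, 0.9, 1.0], "right"),
            )
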