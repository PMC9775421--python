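"""Mayer-band extraction, subrange scanning, sensitivity and summaries.

The Mayer band (nominally 0.08-0.12 Hz; the default 12-voice grid spans it
with pseudo-frequencies 0.078-0.124 Hz) is where the phase shift between
pressure and cerebral flow velocity reports the autoregulation state.
Phase values are used only where the coherence gate holds; everything in
this module treats ungated cells as missing, never as zero.

Phase averaging is plain (non-circular): gated autoregulation phases live
well inside (-pi, pi) in the intended regimes.  A warning is emitted if
any gated phase comes within 0.2 rad of the branch cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError, InsufficientDataError, UndefinedSensitivityError
from .stft_coherence import StftSeries
from .wavelet_coherence import CoherencePhaseMap

__all__ = [
    "MAYER_BAND",
    "BandSeries",
    "extract_band",
    "stft_band_series",
    "subrange_scan",
    "SensitivityResult",
    "sensitivity",
    "PhaseStats",
    "SubjectSummary",
    "summarize_subject",
]

#: Nominal Mayer-wave band in Hz.
MAYER_BAND = (0.08, 0.12)

_WRAP_MARGIN = 0.2


@dataclass
class BandSeries:
    """Time series of gated Mayer-band phase shift.

    ``phase`` is NaN where no gated value exists.  ``freq_used`` records
    the pseudo-frequency (Hz) each value was read from.
    """

    times: np.ndarray
    phase: np.ndarray
    coh2: np.ndarray
    freq_used: np.ndarray
    side: str = ""
    method: str = "cwt"
    threshold: float = 0.6

    def gated(self) -> np.ndarray:
        return np.isfinite(self.phase)

    @property
    def n_gated(self) -> int:
        return int(self.gated().sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "phase_rad": self.phase,
                "coh2": self.coh2,
                "freq_hz": self.freq_used,
                "side": self.side,
                "method": self.method,
            }
        )


def _warn_wraparound(phases: np.ndarray) -> None:
    ph = phases[np.isfinite(phases)]
    if ph.size and np.any(np.abs(ph) > np.pi - _WRAP_MARGIN):
        warnings.warn(
            "gated phases close to +/-pi: plain (non-circular) averaging may be "
            "biased by wraparound",
            stacklevel=3,
        )


def _nanmean(a: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    return float(a.mean()) if a.size else float("nan")


def extract_band(
    maps: CoherencePhaseMap | Iterable[CoherencePhaseMap],
    band: tuple[float, float] = MAYER_BAND,
    picker: str = "maxcoh",
    fixed_freq: Optional[float] = None,
    mode: str = "frame",
    center_window_s: Optional[float] = None,
    side: str = "",
) -> BandSeries:
    """Gated Mayer-band phase from one or more coherence maps.

    picker "maxcoh" selects, per frame, the in-band pseudo-frequency with
    the greatest mean coherence; "fixed" always reads the grid frequency
    nearest ``fixed_freq``.  mode "frame" emits one value per map (mean of
    gated phases, timestamped at the frame center); mode "sample" emits
    every time sample.  ``center_window_s`` restricts the values used to a
    window of that many seconds around the frame center, preserving the
    wavelet transform's time localization in sliding-frame use.
    """
    if isinstance(maps, CoherencePhaseMap):
        maps = [maps]
    maps = list(maps)
    if not maps:
        raise ConfigError("no coherence maps supplied")
    if picker not in ("maxcoh", "fixed"):
        raise ConfigError(f"unknown picker {picker!r} (use maxcoh|fixed)")
    if picker == "fixed" and fixed_freq is None:
        raise ConfigError("picker 'fixed' requires fixed_freq")
    if mode not in ("frame", "sample"):
        raise ConfigError(f"unknown mode {mode!r} (use frame|sample)")
    times, phases, cohs, freqs = [], [], [], []
    threshold = maps[0].threshold
    for cmap in maps:
        idx = cmap.grid.band_indices(*band)
        if idx.size == 0:
            raise ConfigError(f"no grid pseudo-frequency inside band {band}")
        if center_window_s is not None:
            tmask = np.abs(cmap.times - cmap.center_s) <= center_window_s / 2.0
            if not tmask.any():
                tmask = np.ones(len(cmap.times), dtype=bool)
        else:
            tmask = np.ones(len(cmap.times), dtype=bool)
        band_freqs = cmap.grid.pseudo_freqs[idx]
        if picker == "fixed":
            j = idx[int(np.argmin(np.abs(band_freqs - fixed_freq)))]
        else:
            scores = np.array([_nanmean(cmap.coh2[i][tmask]) for i in idx])
            scores[~np.isfinite(scores)] = -np.inf
            j = idx[int(np.argmax(scores))]
        f = float(cmap.grid.pseudo_freqs[j])
        if mode == "frame":
            times.append(cmap.center_s)
            phases.append(_nanmean(cmap.phase[j][tmask]))
            cohs.append(_nanmean(cmap.coh2[j][tmask]))
            freqs.append(f)
        else:
            times.extend(cmap.times[tmask])
            phases.extend(cmap.phase[j][tmask])
            cohs.extend(cmap.coh2[j][tmask])
            freqs.extend([f] * int(tmask.sum()))
    series = BandSeries(
        times=np.asarray(times, dtype=float),
        phase=np.asarray(phases, dtype=float),
        coh2=np.asarray(cohs, dtype=float),
        freq_used=np.asarray(freqs, dtype=float),
        side=side,
        method="cwt",
        threshold=threshold,
    )
    _warn_wraparound(series.phase)
    return series


def stft_band_series(
    series: StftSeries,
    mayer_freq: float = 0.1,
    threshold: float = 0.6,
    side: str = "",
) -> BandSeries:
    """Mayer-band series from the Welch comparator.

    The coarse Fourier bin grid rarely lands inside the band, so the value
    is reported at the bin nearest the configured Mayer frequency, gated by
    the same coherence threshold as the wavelet method.
    """
    k = int(np.argmin(np.abs(series.k_freqs - mayer_freq)))
    gamma = series.gamma[:, k]
    theta = series.theta[:, k].copy()
    gate = np.isfinite(gamma) & (gamma >= threshold)
    theta[~gate] = np.nan
    out = BandSeries(
        times=series.frame_centers.copy(),
        phase=theta,
        coh2=gamma.copy(),
        freq_used=np.full(len(gamma), series.k_freqs[k]),
        side=side,
        method="stft",
        threshold=threshold,
    )
    _warn_wraparound(out.phase)
    return out


def subrange_scan(
    maps: Iterable[CoherencePhaseMap], band: tuple[float, float] = MAYER_BAND
) -> pd.DataFrame:
    """Per-frequency fraction of gated (coherent) time samples.

    Returns a table with columns ``freq_hz``, ``fraction``, ``selected``;
    the recommended subrange frequency (largest coherent fraction) is
    flagged.  With no gated cell anywhere the selection is undefined and
    no row is flagged.
    """
    maps = list(maps)
    if not maps:
        raise ConfigError("no coherence maps supplied")
    idx = maps[0].grid.band_indices(*band)
    if idx.size == 0:
        raise ConfigError(f"no grid pseudo-frequency inside band {band}")
    freqs = maps[0].grid.pseudo_freqs[idx]
    gated = np.zeros(idx.size, dtype=int)
    total = np.zeros(idx.size, dtype=int)
    for cmap in maps:
        gated += cmap.gate[idx].sum(axis=1)
        total += cmap.gate.shape[1]
    fraction = gated / total
    selected = np.zeros(idx.size, dtype=bool)
    if fraction.max() > 0:
        selected[int(np.argmax(fraction))] = True
    return pd.DataFrame({"freq_hz": freqs, "fraction": fraction, "selected": selected})


@dataclass(frozen=True)
class SensitivityResult:
    """Relative phase-shift excursion during a challenge."""

    eta: float
    theta_ext: float
    theta_bar: float
    episode: str = ""


def sensitivity(
    series: BandSeries,
    episode_window: tuple[float, float],
    baseline_window: tuple[float, float],
    direction: str,
    episode: str = "",
    min_samples: int = 5,
) -> SensitivityResult:
    """Sensitivity eta = |theta_ext - theta_bar| / theta_bar.

    theta_bar is the mean gated phase inside ``baseline_window``;
    theta_ext the extreme gated phase inside ``episode_window``
    (direction "min" for a hypercapnic challenge, which depresses the
    phase shift, "max" for hypocapnic, which raises it).
    """
    if direction not in ("min", "max"):
        raise ConfigError(f"direction must be min|max, got {direction!r}")
    gated = series.gated()

    def _in(window):
        lo, hi = window
        m = gated & (series.times >= lo) & (series.times <= hi)
        return series.phase[m]

    base = _in(baseline_window)
    epis = _in(episode_window)
    if len(base) < min_samples or len(epis) < min_samples:
        raise InsufficientDataError(
            f"need >= {min_samples} gated samples per window, got "
            f"baseline={len(base)}, episode={len(epis)}"
        )
    theta_bar = float(base.mean())
    if theta_bar <= 0:
        raise UndefinedSensitivityError(
            f"baseline mean phase {theta_bar:.4g} rad is not positive; "
            "the relative sensitivity is undefined"
        )
    theta_ext = float(epis.min() if direction == "min" else epis.max())
    eta = abs(theta_ext - theta_bar) / theta_bar
    return SensitivityResult(eta=eta, theta_ext=theta_ext, theta_bar=theta_bar, episode=episode)


@dataclass(frozen=True)
class PhaseStats:
    """Per-side gated phase statistics; ci bounds are mean -/+ k*sd."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_gated: int


@dataclass(frozen=True)
class SubjectSummary:
    left: PhaseStats
    right: PhaseStats
    asymmetry_p: float


def _side_stats(series: BandSeries, k: float) -> PhaseStats:
    ph = series.phase[series.gated()]
    if len(ph) < 2:
        raise InsufficientDataError(
            f"side {series.side!r}: need >= 2 gated samples, got {len(ph)}"
        )
    mean = float(ph.mean())
    sd = float(ph.std(ddof=1))
    return PhaseStats(
        mean=mean, sd=sd, ci_low=mean - k * sd, ci_high=mean + k * sd, n_gated=len(ph)
    )


def summarize_subject(
    left: BandSeries, right: BandSeries, sd_multiplier: float = 3.0
) -> SubjectSummary:
    """Per-side mean/SD/limits and a two-sided pooled t-test between sides.

    The interhemispheric asymmetry p-value uses the classical two-sample
    Student statistic with pooled variance.  Degenerate zero-variance
    inputs are resolved explicitly: identical means give p = 1, distinct
    means with zero spread give p = 0.
    """
    _warn_wraparound(left.phase)
    _warn_wraparound(right.phase)
    ls = _side_stats(left, sd_multiplier)
    rs = _side_stats(right, sd_multiplier)
    a = left.phase[left.gated()]
    b = right.phase[right.gated()]
    if ls.sd == 0.0 and rs.sd == 0.0:
        p = 1.0 if ls.mean == rs.mean else 0.0
    else:
        p = float(scipy.stats.ttest_ind(a, b, equal_var=True).pvalue)
        if ls.mean == rs.mean:
            p = 1.0
    return SubjectSummary(left=ls, right=rs, asymmetry_p=p)
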