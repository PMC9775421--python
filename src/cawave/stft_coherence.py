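"""Welch-averaged short-time Fourier coherence and phase (comparator method).

A frame of ``n_frame`` samples is split into ``L = n_frame / n_shift``
tapered windows of length ``n_win`` hopping by half a window
(``n_shift = n_win / 2``).  Per-window auto and cross spectral densities
are averaged over the frame; magnitude-squared coherence and mean phase
follow from the averaged densities.  With the default parameterization
(16384-sample frame, 1024/512 window/hop) there are 32 windows per frame.

The last window of each frame overruns the frame end by ``n_shift``
samples; the overhang is zero-padded (after centering and tapering the
available samples) so exactly L windows always contribute.

Phase sign convention matches the wavelet module: the phase of
``Sxy = X* Y`` is positive when the y (flow-velocity) oscillation leads
the x (pressure) oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import ConfigError, InsufficientDataError
from .signal_io import Recording, SignalFrame

__all__ = [
    "StftConfig",
    "WindowedSpectra",
    "welch_spectra",
    "msc_and_phase",
    "StftSeries",
    "sliding_frames",
]


@dataclass(frozen=True)
class StftConfig:
    """Window/frame geometry for the Welch coherence estimator."""

    n_win: int = 1024
    window: str = "hann"
    n_frame: int = 16384

    def __post_init__(self):
        if self.n_win < 4 or self.n_win % 2 != 0:
            raise ConfigError(f"n_win must be even and >= 4, got {self.n_win}")
        if self.n_frame % self.n_shift != 0:
            raise ConfigError(
                f"n_frame={self.n_frame} must be divisible by n_shift={self.n_shift}"
            )
        if self.n_windows < 2:
            raise ConfigError(
                f"L={self.n_windows} windows per frame: a single window yields a "
                "degenerate (identically 1) coherence estimate"
            )
        try:
            scipy.signal.get_window(self.window, 8)
        except ValueError as exc:
            raise ConfigError(f"unknown window {self.window!r}") from exc

    @property
    def n_shift(self) -> int:
        """Hop: half the window length."""
        return self.n_win // 2

    @property
    def n_windows(self) -> int:
        """Windows per frame, L = n_frame / n_shift."""
        return self.n_frame // self.n_shift

    @property
    def freqs(self) -> np.ndarray:
        """One-sided frequency axis in Hz per unit dt (multiply by 1/dt)."""
        return np.arange(self.n_win // 2 + 1) / self.n_win

    def freqs_hz(self, dt: float) -> np.ndarray:
        return self.freqs / dt


@dataclass
class WindowedSpectra:
    """Frame-averaged auto/cross spectral densities on a one-sided axis."""

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    k_freqs: np.ndarray
    l_used: int

    def __post_init__(self):
        if self.l_used < 2:
            raise ConfigError("coherence needs at least 2 averaged windows")


def _window_spectra(x, y, taper, n_win):
    """Auto/cross densities of one (possibly truncated) window position.

    Available samples are mean-centered, tapered with the leading part of
    the taper, and zero-padded to the full window length.
    """
    m = len(x)
    xs = x - x.mean()
    ys = y - y.mean()
    if m < n_win:
        xw = np.zeros(n_win)
        yw = np.zeros(n_win)
        xw[:m] = xs * taper[:m]
        yw[:m] = ys * taper[:m]
    else:
        xw = xs * taper
        yw = ys * taper
    X = np.fft.rfft(xw)
    Y = np.fft.rfft(yw)
    sxx = (X * np.conj(X)).real / n_win
    syy = (Y * np.conj(Y)).real / n_win
    sxy = np.conj(X) * Y / n_win
    return sxx, syy, sxy


def welch_spectra(
    frame: SignalFrame, cfg: StftConfig, pad_overhang: bool = True
) -> WindowedSpectra:
    """Average per-window spectral densities over one frame.

    With ``pad_overhang=True`` (default) exactly ``L = n_frame/n_shift``
    windows are used, the last zero-padded past the frame end; with
    ``False`` only fully contained windows are averaged (L-1), which is the
    textbook Welch segmentation and useful for cross-checks.
    """
    if frame.n != cfg.n_frame:
        raise ConfigError(f"frame length {frame.n} != configured n_frame {cfg.n_frame}")
    taper = scipy.signal.get_window(cfg.window, cfg.n_win)
    starts = [l * cfg.n_shift for l in range(cfg.n_windows)]
    if not pad_overhang:
        starts = [s for s in starts if s + cfg.n_win <= frame.n]
    sxx = syy = sxy = None
    for s in starts:
        stop = min(s + cfg.n_win, frame.n)
        a, b, c = _window_spectra(frame.x[s:stop], frame.y[s:stop], taper, cfg.n_win)
        if sxx is None:
            sxx, syy, sxy = a, b, c
        else:
            sxx = sxx + a
            syy = syy + b
            sxy = sxy + c
    L = len(starts)
    return WindowedSpectra(
        sxx=sxx / L,
        syy=syy / L,
        sxy=sxy / L,
        k_freqs=cfg.freqs_hz(frame.dt),
        l_used=L,
    )


def msc_and_phase(spec: WindowedSpectra) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence and phase from averaged densities.

    gamma(k) in [0, 1] (NaN where an auto-spectrum vanishes: undefined,
    never reported as 0); theta(k) in (-pi, pi], positive = y leads x.
    """
    den = spec.sxx * spec.syy
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.abs(spec.sxy) ** 2 / den
    gamma[den <= 0] = np.nan
    gamma[~np.isfinite(gamma)] = np.nan
    np.clip(gamma, 0.0, 1.0, out=gamma)
    theta = np.arctan2(spec.sxy.imag, spec.sxy.real)
    theta[theta == -np.pi] = np.pi
    return gamma, theta


@dataclass
class StftSeries:
    """Sliding-frame coherence/phase, shape (frames, frequency bins)."""

    frame_centers: np.ndarray
    k_freqs: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray


def sliding_frames(
    rec: Recording, cfg: StftConfig, channel_pair: str = "left"
) -> StftSeries:
    """Welch coherence/phase for frames hopping by ``n_shift`` samples.

    Frame m covers samples [m*n_shift, m*n_shift + n_frame).  Per-window
    spectra of fully contained windows are cached and re-summed in window
    order, so the incremental path is bit-identical to recomputing each
    frame from scratch (only the final zero-padded overhang window is
    frame-specific).
    """
    x_all = rec.bp
    y_all = rec.channel(channel_pair)
    n = len(rec)
    if n < cfg.n_frame:
        raise InsufficientDataError(
            f"recording has {n} samples; need at least n_frame={cfg.n_frame}"
        )
    taper = scipy.signal.get_window(cfg.window, cfg.n_win)
    n_frames = (n - cfg.n_frame) // cfg.n_shift + 1
    cache: dict[int, tuple] = {}
    centers = np.empty(n_frames)
    gammas = []
    thetas = []
    for m in range(n_frames):
        f0 = m * cfg.n_shift
        fend = f0 + cfg.n_frame
        sxx = syy = sxy = None
        for l in range(cfg.n_windows):
            s = f0 + l * cfg.n_shift
            if s + cfg.n_win <= fend:
                if s not in cache:
                    cache[s] = _window_spectra(
                        x_all[s : s + cfg.n_win], y_all[s : s + cfg.n_win],
                        taper, cfg.n_win,
                    )
                a, b, c = cache[s]
            else:
                a, b, c = _window_spectra(x_all[s:fend], y_all[s:fend], taper, cfg.n_win)
            if sxx is None:
                sxx, syy, sxy = a, b, c
            else:
                sxx = sxx + a
                syy = syy + b
                sxy = sxy + c
        L = cfg.n_windows
        spec = WindowedSpectra(
            sxx=sxx / L, syy=syy / L, sxy=sxy / L,
            k_freqs=cfg.freqs_hz(rec.dt), l_used=L,
        )
        gamma, theta = msc_and_phase(spec)
        gammas.append(gamma)
        thetas.append(theta)
        centers[m] = (f0 + cfg.n_frame / 2.0) * rec.dt
        cache.pop(f0, None)  # no later frame revisits this window position
    return StftSeries(
        frame_centers=centers,
        k_freqs=cfg.freqs_hz(rec.dt),
        gamma=np.asarray(gammas),
        theta=np.asarray(thetas),
    )
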