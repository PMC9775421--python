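"""Smoothed cross-wavelet spectrum, squared coherence and gated phase.

Squared wavelet coherence is the magnitude of the smoothed cross-wavelet
spectrum normalized by the smoothed auto-powers:

    H2(n, s) = |S(cx* . cy)|^2 / ( S(|cx|^2) . S(|cy|^2) )

where ``S`` smooths in time (multiplication of each scale-row's DFT by the
Gaussian ``exp(-c * s^2 * omega^2)``) and then in scale (forward boxcar over
``Ls`` voices).  Without smoothing the ratio is identically one, so an
identity smoother is rejected as a configuration error rather than computed.

Phase is read off the smoothed cross-spectrum with the two-argument
arctangent and reported only where the coherence gate ``H2 >= threshold``
(default 0.6, the Morlet scale-decorrelation coefficient) holds; elsewhere
it is NaN (missing, never zero).  The sign convention throughout the
package: positive phase means the second channel (flow velocity) leads the
first (pressure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cwt_core import ScaleGrid, WaveletCoeffs, angular_frequencies
from .errors import ConfigError

__all__ = [
    "SmoothingConfig",
    "smooth_time",
    "smooth_scale",
    "cross_spectrum",
    "CoherencePhaseMap",
    "coherence_sq",
    "phase_shift",
    "coherence_map",
]

#: Scale-decorrelation length (octaves) of the Morlet wavelet; also the
#: default coherence gate threshold.
MORLET_DECORRELATION = 0.6


@dataclass(frozen=True)
class SmoothingConfig:
    """Time/scale smoothing parameters.

    time_kernel_coeff is the coefficient ``c`` in the frequency-domain
    Gaussian ``exp(-c * s^2 * omega^2)`` (default 1/4; 1/2 is the common
    alternative in the wavelet-coherence literature and is accepted here).
    ``ls`` is the scale boxcar length in voices; ``None`` derives
    ``round(0.6/dj)`` from the grid (7 at 12 voices).
    """

    time_kernel_coeff: float = 0.25
    ls: Optional[int] = None

    def __post_init__(self):
        if self.time_kernel_coeff <= 0:
            raise ConfigError(
                "time_kernel_coeff must be > 0: with smoothing disabled the "
                "coherence estimator is identically 1 and carries no information"
            )
        if self.ls is not None and self.ls < 1:
            raise ConfigError(f"ls must be >= 1, got {self.ls}")

    def resolve_ls(self, dj: float) -> int:
        if self.ls is not None:
            return self.ls
        return max(1, int(round(MORLET_DECORRELATION / dj)))


def smooth_time(
    mat: np.ndarray, scales: np.ndarray, dt: float, coeff: float = 0.25
) -> np.ndarray:
    """Per-scale time smoothing in the frequency domain.

    Each row's DFT is multiplied by ``exp(-coeff * s^2 * omega_k^2)`` and
    inverse-transformed.  The kernel has unit DC gain, so constant rows are
    preserved exactly.
    """
    mat = np.asarray(mat)
    scales = np.asarray(scales, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != len(scales):
        raise ConfigError(
            f"matrix shape {mat.shape} does not match {len(scales)} scales"
        )
    omegas = angular_frequencies(mat.shape[1], dt)
    kernel = np.exp(-coeff * (scales[:, None] * omegas[None, :]) ** 2)
    return np.fft.ifft(np.fft.fft(mat, axis=1) * kernel, axis=1)


def smooth_scale(mat: np.ndarray, ls: int) -> np.ndarray:
    """Forward boxcar mean over ``ls`` scale rows.

    Row j averages rows j .. j+ls-1; near the deep-scale end only the
    available rows are averaged (renormalized partial mean), so no scale is
    silently dropped.
    """
    mat = np.asarray(mat)
    n = mat.shape[0]
    if not (1 <= ls <= n):
        raise ConfigError(f"ls must be in [1, {n}], got {ls}")
    out = np.empty_like(mat)
    for j in range(n):
        out[j] = mat[j : min(j + ls, n)].mean(axis=0)
    return out


def cross_spectrum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise cross-spectrum ``conj(a) * b``."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ConfigError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.conj(a) * b


@dataclass
class CoherencePhaseMap:
    """Squared coherence and gated phase on the (scale, time) plane."""

    coh2: np.ndarray
    phase: np.ndarray
    gate: np.ndarray
    threshold: float
    grid: ScaleGrid
    times: np.ndarray
    frame_meta: dict = field(default_factory=dict)
    smoothed_cross: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def center_s(self) -> float:
        return float(self.frame_meta.get("center_s", self.times.mean()))


def _values(c) -> np.ndarray:
    return c.values if isinstance(c, WaveletCoeffs) else np.asarray(c)


def coherence_sq(
    cx,
    cy,
    grid: ScaleGrid | None = None,
    cfg: SmoothingConfig | None = None,
    threshold: float = MORLET_DECORRELATION,
    t0: float = 0.0,
    frame_meta: dict | None = None,
) -> CoherencePhaseMap:
    """Squared wavelet coherence of two raw coefficient matrices.

    Accepts :class:`WaveletCoeffs` (grid taken from the first) or bare
    matrices plus an explicit grid.  Returns a map with ``coh2`` and the
    gate filled; phase is NaN until :func:`phase_shift` fills it.  Cells
    where a smoothed auto-power underflows are emitted as NaN (missing).
    """
    if grid is None:
        if not isinstance(cx, WaveletCoeffs):
            raise ConfigError("grid required when passing bare matrices")
        grid = cx.grid
    cfg = cfg or SmoothingConfig()
    if cfg.time_kernel_coeff <= 0:  # defensive: config refuses this already
        raise ConfigError("smoothing must be enabled for a meaningful coherence")
    vx, vy = _values(cx), _values(cy)
    if vx.shape != vy.shape:
        raise ConfigError(f"shape mismatch: {vx.shape} vs {vy.shape}")
    ls = cfg.resolve_ls(grid.dj)

    def S(m):
        return smooth_scale(smooth_time(m, grid.scales, grid.dt, cfg.time_kernel_coeff), ls)

    s_cross = S(cross_spectrum(vx, vy))
    s_px = S(np.abs(vx) ** 2).real
    s_py = S(np.abs(vy) ** 2).real
    den = s_px * s_py
    with np.errstate(divide="ignore", invalid="ignore"):
        coh2 = np.abs(s_cross) ** 2 / den
    coh2[~np.isfinite(coh2)] = np.nan
    coh2[(den <= 0) | ~np.isfinite(den)] = np.nan
    np.clip(coh2, 0.0, 1.0, out=coh2)
    gate = np.zeros(coh2.shape, dtype=bool)
    np.greater_equal(coh2, threshold, out=gate, where=np.isfinite(coh2))
    n = vx.shape[1]
    times = t0 + np.arange(n) * grid.dt
    return CoherencePhaseMap(
        coh2=coh2,
        phase=np.full(coh2.shape, np.nan),
        gate=gate,
        threshold=threshold,
        grid=grid,
        times=times,
        frame_meta=dict(frame_meta or {}),
        smoothed_cross=s_cross,
    )


def phase_shift(cmap: CoherencePhaseMap, cross: np.ndarray | None = None) -> CoherencePhaseMap:
    """Fill the gated phase of a coherence map.

    ``theta = atan2(Im, Re)`` of the smoothed cross-spectrum, in (-pi, pi];
    positive means flow velocity leads pressure.  Cells failing the gate
    carry NaN.
    """
    if cross is None:
        cross = cmap.smoothed_cross
    if cross is None:
        raise ConfigError("no smoothed cross-spectrum available")
    if cross.shape != cmap.coh2.shape:
        raise ConfigError(f"shape mismatch: {cross.shape} vs {cmap.coh2.shape}")
    theta = np.arctan2(cross.imag, cross.real)
    theta[theta == -np.pi] = np.pi
    theta = np.where(cmap.gate, theta, np.nan)
    cmap.phase = theta
    return cmap


def coherence_map(
    cx,
    cy,
    grid: ScaleGrid | None = None,
    cfg: SmoothingConfig | None = None,
    threshold: float = MORLET_DECORRELATION,
    t0: float = 0.0,
    frame_meta: dict | None = None,
) -> CoherencePhaseMap:
    """Convenience: coherence plus gated phase in one call."""
    return phase_shift(coherence_sq(cx, cy, grid, cfg, threshold, t0, frame_meta))
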