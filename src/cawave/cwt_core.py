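"""Morlet continuous wavelet transform on a voice-resolved scale ladder.

The transform is computed in the Fourier domain: the DFT of the centered
signal is multiplied by the conjugated spectrum of the analytic Morlet
wavelet at each scale and inverse-transformed.  This is an exact circular
convolution of the signal with the sampled wavelet, which keeps the
transform linear and time-covariant under circular shifts.

Scales form a geometric ladder ``s_j = s0 * 2**(j*dj)`` with ``dj`` voices
per octave (default 12 voices, ``dj = 1/12``) starting at ``s0 = 2*dt``.
Each scale is assigned a pseudo-frequency through the Fourier factor
``omega0 / (2*pi)`` (0.9549 for the default ``omega0 = 6``), which places
the Mayer band (0.08-0.12 Hz) on a handful of neighbouring scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "angular_frequencies",
    "morlet_hat",
    "ScaleGrid",
    "build_scale_grid",
    "WaveletCoeffs",
    "cwt_forward",
]


def angular_frequencies(n: int, dt: float) -> np.ndarray:
    """DFT angular frequencies ``omega_k`` for an *n*-point transform.

    ``omega_k = 2*pi*k/(n*dt)`` for ``k <= n/2`` and the mirrored negative
    branch for ``k > n/2``; the Nyquist bin (even *n*) is positive.
    """
    if n < 2:
        raise ConfigError(f"need at least 2 samples, got {n}")
    k = np.arange(n)
    w = 2.0 * np.pi * k / (n * dt)
    neg = k > n // 2
    w[neg] = 2.0 * np.pi * (k[neg] - n) / (n * dt)
    return w


def morlet_hat(
    scale: float, omegas: np.ndarray, omega0: float = 6.0, dt: float = 1.0
) -> np.ndarray:
    """Normalized spectrum of the analytic Morlet wavelet at one scale.

    The wavelet is analytic: its spectrum is a Gaussian centered at
    ``omega0/scale`` on the positive half-axis and identically zero at
    ``omega <= 0``.  The per-scale normalization ``sqrt(2*pi*scale/dt)``
    makes transforms comparable across scales.
    """
    if scale <= 0:
        raise ConfigError(f"scale must be positive, got {scale}")
    psi = np.pi ** (-0.25) * np.exp(-0.5 * (scale * omegas - omega0) ** 2)
    psi[omegas <= 0] = 0.0
    return np.sqrt(2.0 * np.pi * scale / dt) * psi


def _is_pow2(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class ScaleGrid:
    """Geometric scale ladder with pseudo-frequencies.

    Attributes
    ----------
    s0 : minimum scale in seconds (``2*dt`` when built with defaults).
    dj : voice spacing (1/voices-per-octave).
    J : maximum decomposition level of the full ladder.
    omega0 : Morlet center-frequency parameter.
    dt : sampling interval in seconds.
    scales : scale values in seconds, strictly increasing.
    pseudo_freqs : ``fourier_factor / scales`` in Hz, strictly decreasing.
    """

    s0: float
    dj: float
    J: int
    omega0: float
    dt: float
    scales: np.ndarray
    pseudo_freqs: np.ndarray

    @property
    def fourier_factor(self) -> float:
        """Scale-to-frequency conversion factor ``omega0 / (2*pi)``."""
        return self.omega0 / (2.0 * np.pi)

    def __len__(self) -> int:
        return len(self.scales)

    def band_indices(self, lo: float, hi: float, edge_decimals: int = 3) -> np.ndarray:
        """Indices of pseudo-frequencies inside the band ``[lo, hi]`` Hz.

        Band edges are treated as printed to ``edge_decimals`` decimals, so a
        grid frequency belongs to the band when it rounds into it.  On the
        default grid this yields nine pseudo-frequencies across 0.078-0.124 Hz.
        """
        tol = 0.5 * 10.0 ** (-edge_decimals)
        f = self.pseudo_freqs
        return np.nonzero((f >= lo - tol) & (f <= hi + tol))[0]

    def nearest_index(self, freq: float) -> int:
        """Index of the pseudo-frequency closest to *freq* (Hz)."""
        return int(np.argmin(np.abs(self.pseudo_freqs - freq)))

    def restrict(self, fmin: float | None = None, fmax: float | None = None) -> "ScaleGrid":
        """Sub-ladder with pseudo-frequencies inside ``[fmin, fmax]``.

        Dropping scales more than the scale-smoothing window below the band
        of interest leaves band-level coherence untouched, so restriction is
        a pure speed/memory knob.
        """
        mask = np.ones(len(self.scales), dtype=bool)
        if fmin is not None:
            mask &= self.pseudo_freqs >= fmin
        if fmax is not None:
            mask &= self.pseudo_freqs <= fmax
        if not mask.any():
            raise ConfigError(f"no scales left in frequency range [{fmin}, {fmax}]")
        return replace(self, scales=self.scales[mask], pseudo_freqs=self.pseudo_freqs[mask])


def build_scale_grid(
    dt: float, n: int, dj: float = 1.0 / 12.0, omega0: float = 6.0
) -> ScaleGrid:
    """Build the default ladder for an *n*-sample frame at interval *dt*.

    ``s0 = 2*dt``; the maximum level is ``J = round(log2(n*dt/s0)/dj)`` so
    the largest scale is about the frame duration.  Adjacent
    pseudo-frequencies differ by the exact factor ``2**dj``.
    """
    if dt <= 0:
        raise ConfigError(f"dt must be positive, got {dt}")
    if not (0 < dj <= 1):
        raise ConfigError(f"dj must lie in (0, 1], got {dj}")
    if not _is_pow2(n):
        raise ConfigError(f"frame length must be a power of two, got {n}")
    s0 = 2.0 * dt
    if n * dt <= s0:
        raise ConfigError(f"frame too short for scale ladder: n*dt={n * dt} <= s0={s0}")
    J = int(round(np.log2(n * dt / s0) / dj))
    j = np.arange(J + 1)
    scales = s0 * 2.0 ** (j * dj)
    ff = omega0 / (2.0 * np.pi)
    return ScaleGrid(
        s0=s0, dj=dj, J=J, omega0=omega0, dt=dt,
        scales=scales, pseudo_freqs=ff / scales,
    )


@dataclass
class WaveletCoeffs:
    """Complex wavelet coefficients of one channel, shape (scales, time).

    ``coi`` holds, per time index, the largest scale (seconds) unaffected by
    edge effects under the sqrt(2)*s e-folding rule.  It is attached as
    metadata; masking by it is the caller's choice.
    """

    values: np.ndarray
    grid: ScaleGrid
    dt: float
    n: int
    coi: np.ndarray

    def __mul__(self, c):
        return replace(self, values=self.values * c)


def cwt_forward(x: np.ndarray, grid: ScaleGrid, pad: bool = False) -> WaveletCoeffs:
    """Morlet CWT of a centered frame via FFT circular convolution.

    For each scale the coefficients are the inverse DFT of the signal DFT
    multiplied by the conjugated, normalized Morlet spectrum.  With
    ``pad=True`` the signal is zero-padded to twice its length before the
    transform to suppress circular wraparound (off by default: the plain
    circular form is the reference definition here).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DataError(f"expected a 1-D frame, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise DataError(f"non-finite sample at index {bad}")
    n = len(x)
    nfft = 2 * n if pad else n
    xin = np.concatenate([x, np.zeros(n)]) if pad else x
    xhat = np.fft.fft(xin)
    omegas = angular_frequencies(nfft, grid.dt)
    arg = grid.scales[:, None] * omegas[None, :]
    psih = np.pi ** (-0.25) * np.exp(-0.5 * (arg - grid.omega0) ** 2)
    psih[:, omegas <= 0] = 0.0
    psih *= np.sqrt(2.0 * np.pi * grid.scales[:, None] / grid.dt)
    values = np.fft.ifft(xhat[None, :] * np.conj(psih), axis=1)[:, :n]
    idx = np.arange(n)
    coi = np.minimum(idx, n - 1 - idx) * grid.dt / np.sqrt(2.0)
    return WaveletCoeffs(values=values, grid=grid, dt=grid.dt, n=n, coi=coi)
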