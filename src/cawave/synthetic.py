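"""Synthetic paired BP/BFV recordings with known Mayer-band coupling.

No clinical recordings ship with this package, so every pipeline stage is
exercised on phenomenological surrogates: a pressure channel carrying the
three canonical oscillations - cardiac (~1 Hz), respiratory (~0.25 Hz) and
Mayer (~0.1 Hz) - plus AR(1)-and-white noise, and flow-velocity channels
carrying the same components with the Mayer component phase-advanced by a
controllable lead (the ground-truth "autoregulation phase shift").
CO2 challenges are emulated purely as episodes that override the Mayer
lead, blended in with a 5 s raised-cosine ramp (an instant phase jump
would inject broadband artifacts no physiology produces).

Default amplitudes put the Mayer component ten times above the white-noise
floor (amplitude 1.0 vs SD 0.1): a clean recording in which a healthy
lead of ~1 rad is recoverable to a few hundredths of a radian.  Healthy
leads are drawn from 0.8-1.4 rad; unilateral impairment halves one side.

All randomness flows from the single config seed; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .errors import ConfigError
from .signal_io import Recording

__all__ = [
    "OscSpec",
    "MayerSpec",
    "NoiseSpec",
    "Episode",
    "DriftSpec",
    "SynthConfig",
    "make_pair",
    "make_cohort",
    "HEALTHY_PS_RANGE",
]

#: Healthy-range Mayer phase shift in radians.
HEALTHY_PS_RANGE = (0.8, 1.4)


@dataclass(frozen=True)
class OscSpec:
    """One sinusoidal component: frequency (Hz) and amplitude."""

    freq: float
    amplitude: float
    gain: float = 1.0  # amplitude ratio carried over to the BFV channels


@dataclass(frozen=True)
class MayerSpec:
    """Mayer component with the BFV-over-BP phase lead (radians)."""

    freq: float = 0.1
    amplitude: float = 1.0
    phase_lead_rad: float = 1.0
    gain: float = 1.0
    phase_lead_right_rad: Optional[float] = None  # None: same as left


@dataclass(frozen=True)
class NoiseSpec:
    """AR(1)-plus-white noise, drawn independently per channel."""

    white_sd: float = 0.1
    ar1_coeff: float = 0.9
    ar1_sd: float = 0.1


@dataclass(frozen=True)
class Episode:
    """A challenge interval overriding the Mayer phase lead."""

    start_s: float
    end_s: float
    phase_lead_rad: float
    label: str = ""


@dataclass(frozen=True)
class DriftSpec:
    """Optional slow sinusoidal amplitude modulation of the Mayer wave."""

    depth: float = 0.0
    freq: float = 0.01


@dataclass(frozen=True)
class SynthConfig:
    duration_s: float = 180.0
    dt: float = 0.01
    cardiac: OscSpec = OscSpec(freq=1.0, amplitude=1.0)
    resp: OscSpec = OscSpec(freq=0.25, amplitude=0.5)
    mayer: MayerSpec = MayerSpec()
    noise: NoiseSpec = NoiseSpec()
    episodes: tuple[Episode, ...] = ()
    seed: int = 0
    ramp_s: float = 5.0
    slow_drift: Optional[DriftSpec] = None

    def validate(self) -> None:
        nyq = 0.5 / self.dt
        for name, f, a in (
            ("cardiac", self.cardiac.freq, self.cardiac.amplitude),
            ("resp", self.resp.freq, self.resp.amplitude),
            ("mayer", self.mayer.freq, self.mayer.amplitude),
        ):
            if not (0 < f < nyq):
                raise ConfigError(f"{name} frequency {f} Hz outside (0, {nyq})")
            if a < 0:
                raise ConfigError(f"{name} amplitude must be >= 0, got {a}")
        if not abs(self.noise.ar1_coeff) < 1:
            raise ConfigError(f"|AR1 coefficient| must be < 1, got {self.noise.ar1_coeff}")
        if self.noise.white_sd < 0 or self.noise.ar1_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.duration_s <= 0 or self.dt <= 0:
            raise ConfigError("duration_s and dt must be positive")
        last_end = -np.inf
        for ep in sorted(self.episodes, key=lambda e: e.start_s):
            if not (0 <= ep.start_s < ep.end_s <= self.duration_s):
                raise ConfigError(f"episode {ep.label!r} outside recording: {ep}")
            if ep.start_s < last_end:
                raise ConfigError(f"episodes overlap at {ep.start_s} s")
            last_end = ep.end_s


def _noise(rng: np.random.Generator, n: int, spec: NoiseSpec) -> np.ndarray:
    out = np.zeros(n)
    if spec.ar1_sd > 0:
        e = rng.normal(0.0, spec.ar1_sd, n)
        out += scipy.signal.lfilter([1.0], [1.0, -spec.ar1_coeff], e)
    if spec.white_sd > 0:
        out += rng.normal(0.0, spec.white_sd, n)
    return out


def _lead_profile(t: np.ndarray, base: float, episodes, ramp: float) -> np.ndarray:
    """Piecewise phase lead with raised-cosine on/off transitions."""
    lead = np.full(len(t), base)
    for ep in episodes:
        up = 0.5 * (1.0 - np.cos(np.pi * np.clip((t - ep.start_s) / ramp, 0.0, 1.0)))
        dn = 0.5 * (1.0 - np.cos(np.pi * np.clip((t - ep.end_s) / ramp, 0.0, 1.0)))
        lead += (up - dn) * (ep.phase_lead_rad - base)
    return lead


def make_pair(cfg: SynthConfig) -> Recording:
    """Generate one paired recording; bit-reproducible from the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s / cfg.dt))
    t = np.arange(n) * cfg.dt
    ph_c, ph_r, ph_m = rng.uniform(0.0, 2.0 * np.pi, 3)

    card = cfg.cardiac.amplitude * np.sin(2 * np.pi * cfg.cardiac.freq * t + ph_c)
    resp = cfg.resp.amplitude * np.sin(2 * np.pi * cfg.resp.freq * t + ph_r)
    m_amp = cfg.mayer.amplitude * np.ones(n)
    if cfg.slow_drift is not None and cfg.slow_drift.depth > 0:
        ph_d = rng.uniform(0.0, 2.0 * np.pi)
        m_amp *= 1.0 + cfg.slow_drift.depth * np.sin(2 * np.pi * cfg.slow_drift.freq * t + ph_d)
    mayer_bp = m_amp * np.sin(2 * np.pi * cfg.mayer.freq * t + ph_m)

    bp = card + resp + mayer_bp + _noise(rng, n, cfg.noise)

    lead_l = _lead_profile(t, cfg.mayer.phase_lead_rad, cfg.episodes, cfg.ramp_s)
    base_r = (
        cfg.mayer.phase_lead_right_rad
        if cfg.mayer.phase_lead_right_rad is not None
        else cfg.mayer.phase_lead_rad
    )
    lead_r = _lead_profile(t, base_r, cfg.episodes, cfg.ramp_s)

    def bfv(lead):
        return (
            cfg.cardiac.gain * card
            + cfg.resp.gain * resp
            + cfg.mayer.gain * m_amp * np.sin(2 * np.pi * cfg.mayer.freq * t + ph_m + lead)
            + _noise(rng, n, cfg.noise)
        )

    bfv_l = bfv(lead_l)
    bfv_r = bfv(lead_r)
    return Recording(
        time=t,
        bp=bp,
        bfv_left=bfv_l,
        bfv_right=bfv_r,
        dt=cfg.dt,
        subject_meta={
            "seed": cfg.seed,
            "ps_left": cfg.mayer.phase_lead_rad,
            "ps_right": base_r,
        },
    )


def make_cohort(
    n_subjects: int,
    healthy_cfg: Optional[SynthConfig] = None,
    impaired_cfg: Optional[SynthConfig] = None,
    seed: int = 0,
    impaired_idx: Sequence[int] = (),
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a cohort with randomized per-subject phase shifts.

    Healthy subjects draw one lead from 0.8-1.4 rad, identical on both
    sides; subjects listed in ``impaired_idx`` use ``impaired_cfg`` (or the
    healthy template) with the lead of one randomly chosen side halved.
    Returns the recordings and a truth table with the per-side leads.
    """
    if n_subjects < 1:
        raise ConfigError(f"n_subjects must be >= 1, got {n_subjects}")
    healthy_cfg = healthy_cfg or SynthConfig()
    impaired_cfg = impaired_cfg or healthy_cfg
    impaired = set(int(i) for i in impaired_idx)
    rng = np.random.default_rng(seed)
    recs, rows = [], []
    for i in range(n_subjects):
        lead = float(rng.uniform(*HEALTHY_PS_RANGE))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if i in impaired:
            side = "left" if rng.random() < 0.5 else "right"
            lead_l = lead / 2.0 if side == "left" else lead
            lead_r = lead / 2.0 if side == "right" else lead
            template, status = impaired_cfg, "impaired"
        else:
            side = ""
            lead_l = lead_r = lead
            template, status = healthy_cfg, "healthy"
        cfg = replace(
            template,
            seed=sub_seed,
            mayer=replace(
                template.mayer, phase_lead_rad=lead_l, phase_lead_right_rad=lead_r
            ),
        )
        recs.append(make_pair(cfg))
        rows.append(
            {
                "subject": i,
                "status": status,
                "impaired_side": side,
                "ps_left": lead_l,
                "ps_right": lead_r,
                "seed": sub_seed,
            }
        )
    return recs, pd.DataFrame(rows)
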