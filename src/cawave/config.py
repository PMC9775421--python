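"""Flat key=value run configuration shared by the CLI and the pipeline.

Config files are plain text, one ``key = value`` per line, '#' comments.
Every key has a default; unknown keys are rejected.  Values accept ints,
floats, simple fractions ("1/12"), booleans and "none".
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

from .errors import ConfigError
from .synthetic import Episode

__all__ = ["RunConfig", "parse_episodes"]

# Defaults double as the type schema; None-defaulted keys list their type
# in _NONE_TYPES.
DEFAULTS: dict = {
    "input": "",
    "out_dir": "results",
    "method": "both",  # cwt|stft|both
    "side": "both",  # left|right|both
    "seed": 0,
    # framing
    "frame.len": 16384,
    "frame.shift": 512,
    "frame.pad": "down",  # down|up
    "frame.detrend": False,
    # Welch comparator
    "stft.win_len": 1024,
    "stft.window": "hann",
    # wavelet transform
    "cwt.omega0": 6.0,
    "cwt.dj": 1.0 / 12.0,
    "cwt.pad": False,
    "cwt.coi_mask": False,
    "cwt.fmin": None,
    "cwt.fmax": None,
    # coherence
    "coh.threshold": 0.6,
    "coh.time_kernel_coeff": 0.25,
    "coh.ls_voices": None,
    # Mayer band
    "mayer.band_low": 0.08,
    "mayer.band_high": 0.12,
    "mayer.picker": "maxcoh",  # maxcoh|fixed
    "mayer.fixed_freq": 0.1,
    "mayer.center_window_s": None,
    "summary.sd_multiplier": 3.0,
    # episodes: "label:start_s:end_s[:lead_rad]" joined by ';'
    "episodes": "",
    "maps.export": "none",  # none|band
    # input column names
    "col.time": "time",
    "col.bp": "bp",
    "col.bfv_left": "bfv_left",
    "col.bfv_right": "bfv_right",
    # synthetic generator (simulate subcommand)
    "synth.duration_s": 480.0,
    "synth.dt": 0.01,
    "synth.cardiac_freq": 1.0,
    "synth.cardiac_amp": 1.0,
    "synth.resp_freq": 0.25,
    "synth.resp_amp": 0.5,
    "synth.mayer_freq": 0.1,
    "synth.mayer_amp": 1.0,
    "synth.mayer_gain": 1.0,
    "synth.phase_lead": 1.0,
    "synth.phase_lead_right": None,
    "synth.white_sd": 0.1,
    "synth.ar1_coeff": 0.9,
    "synth.ar1_sd": 0.1,
    "synth.ramp_s": 5.0,
}

_NONE_TYPES = {
    "cwt.fmin": float,
    "cwt.fmax": float,
    "coh.ls_voices": int,
    "mayer.center_window_s": float,
    "synth.phase_lead_right": float,
}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    default = DEFAULTS[key]
    typ = type(default) if default is not None else _NONE_TYPES.get(key, str)
    if raw.lower() in ("none", ""):
        if default is None or typ is str:
            return None if default is None else raw
        raise ConfigError(f"{key}: 'none' not allowed")
    if typ is bool:
        if raw.lower() in ("true", "1", "yes", "on"):
            return True
        if raw.lower() in ("false", "0", "no", "off"):
            return False
        raise ConfigError(f"{key}: expected boolean, got {raw!r}")
    if typ is int:
        try:
            return int(raw)
        except ValueError as exc:
            raise ConfigError(f"{key}: expected integer, got {raw!r}") from exc
    if typ is float:
        try:
            if "/" in raw:
                num, den = raw.split("/", 1)
                return float(num) / float(den)
            return float(raw)
        except (ValueError, ZeroDivisionError) as exc:
            raise ConfigError(f"{key}: expected number, got {raw!r}") from exc
    return raw


class RunConfig:
    """Resolved flat configuration with typed access."""

    def __init__(self, values: Optional[Mapping] = None):
        self._values = dict(DEFAULTS)
        for k, v in (values or {}).items():
            if k not in DEFAULTS:
                raise ConfigError(f"unknown config key {k!r}")
            self._values[k] = v

    @classmethod
    def load(
        cls, path: Optional[str] = None, overrides: Iterable[str] = ()
    ) -> "RunConfig":
        """Build from an optional config file plus ``key=value`` overrides."""
        cfg = cls()
        if path:
            try:
                with open(path) as fh:
                    lines = fh.readlines()
            except OSError as exc:
                raise ConfigError(f"cannot read config {path}: {exc}") from exc
            for ln, line in enumerate(lines, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{ln}: expected 'key = value'")
                key, raw = (s.strip() for s in line.split("=", 1))
                cfg.set(key, raw)
        for item in overrides:
            if "=" not in item:
                raise ConfigError(f"override {item!r}: expected key=value")
            key, raw = (s.strip() for s in item.split("=", 1))
            cfg.set(key, raw)
        return cfg

    def set(self, key: str, raw: str) -> None:
        if key not in DEFAULTS:
            raise ConfigError(f"unknown config key {key!r}")
        self._values[key] = _parse_value(key, raw)

    def __getitem__(self, key: str):
        try:
            return self._values[key]
        except KeyError:
            raise ConfigError(f"unknown config key {key!r}") from None

    def resolved(self) -> dict:
        """All keys and values, for the run manifest."""
        return dict(self._values)

    @property
    def column_map(self) -> dict:
        return {
            "time": self["col.time"],
            "bp": self["col.bp"],
            "bfv_left": self["col.bfv_left"],
            "bfv_right": self["col.bfv_right"],
        }

    @property
    def sides(self) -> list[str]:
        side = self["side"]
        if side not in ("left", "right", "both"):
            raise ConfigError(f"side must be left|right|both, got {side!r}")
        return ["left", "right"] if side == "both" else [side]

    @property
    def methods(self) -> list[str]:
        m = self["method"]
        if m not in ("cwt", "stft", "both"):
            raise ConfigError(f"method must be cwt|stft|both, got {m!r}")
        return ["cwt", "stft"] if m == "both" else [m]

    @property
    def band(self) -> tuple[float, float]:
        lo, hi = self["mayer.band_low"], self["mayer.band_high"]
        if not (0 < lo < hi):
            raise ConfigError(f"invalid Mayer band [{lo}, {hi}]")
        return (lo, hi)


def parse_episodes(text: str) -> list[Episode]:
    """Parse ``label:start_s:end_s[:lead_rad]`` items joined by ';'."""
    episodes = []
    for item in filter(None, (s.strip() for s in (text or "").split(";"))):
        parts = item.split(":")
        if len(parts) not in (3, 4):
            raise ConfigError(
                f"episode {item!r}: expected label:start_s:end_s[:lead_rad]"
            )
        label = parts[0]
        try:
            start, end = float(parts[1]), float(parts[2])
            lead = float(parts[3]) if len(parts) == 4 else 0.0
        except ValueError as exc:
            raise ConfigError(f"episode {item!r}: bad number") from exc
        episodes.append(Episode(start_s=start, end_s=end, phase_lead_rad=lead, label=label))
    return episodes
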