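"""Reading, validating, centering and framing paired BP/BFV recordings.

Input is delimited text (comma-separated, header row, '.' decimal) with a
time column in seconds and one pressure plus two flow-velocity columns.
The time grid must be uniform; recordings with gaps or non-finite samples
are rejected rather than repaired.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.signal

from .errors import (
    ConfigError,
    DataError,
    FormatError,
    InsufficientDataError,
    SamplingError,
)

__all__ = [
    "Recording",
    "SignalFrame",
    "read_recording",
    "write_recording",
    "make_frames",
    "write_results",
]

DEFAULT_COLUMNS = {
    "time": "time",
    "bp": "bp",
    "bfv_left": "bfv_left",
    "bfv_right": "bfv_right",
}

#: Relative (to dt) tolerance for time-grid uniformity.
UNIFORM_RTOL = 1e-9


@dataclass
class Recording:
    """A paired, uniformly sampled BP/BFV recording.

    bp is systemic arterial pressure (mmHg typical); bfv_left/bfv_right are
    flow velocities in the left/right middle cerebral artery (cm/s typical).
    All channels share one uniform time grid with interval ``dt`` seconds
    (0.01 s in the intended acquisition setting).
    """

    time: np.ndarray
    bp: np.ndarray
    bfv_left: np.ndarray
    bfv_right: np.ndarray
    dt: float
    subject_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.bp = np.asarray(self.bp, dtype=float)
        self.bfv_left = np.asarray(self.bfv_left, dtype=float)
        self.bfv_right = np.asarray(self.bfv_right, dtype=float)
        n = len(self.time)
        for name in ("bp", "bfv_left", "bfv_right"):
            ch = getattr(self, name)
            if len(ch) != n:
                raise FormatError(f"channel {name} has {len(ch)} samples, time has {n}")
            if not np.all(np.isfinite(ch)):
                bad = int(np.flatnonzero(~np.isfinite(ch))[0])
                raise DataError(f"non-finite value in {name} at row {bad}")
        if self.dt <= 0:
            raise SamplingError(f"dt must be positive, got {self.dt}")
        if n >= 2:
            dev = np.abs(np.diff(self.time) - self.dt)
            if dev.max() > UNIFORM_RTOL * self.dt:
                bad = int(np.argmax(dev > UNIFORM_RTOL * self.dt))
                raise SamplingError(
                    f"non-uniform time grid: step at row {bad + 1} deviates by "
                    f"{dev.max():.3g} s from dt={self.dt}"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        return len(self) * self.dt

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"bp": self.bp, "left": self.bfv_left, "right": self.bfv_right}[name]
        except KeyError:
            raise ConfigError(f"unknown channel {name!r} (use bp|left|right)") from None


@dataclass
class SignalFrame:
    """One fixed-length, mean-centered window of a paired recording.

    x is centered pressure, y centered flow velocity; ``n0`` is the start
    index in the parent recording and ``n`` the (power-of-two) frame length.
    """

    x: np.ndarray
    y: np.ndarray
    n0: int
    n: int
    dt: float

    def __post_init__(self):
        if self.n < 256 or (self.n & (self.n - 1)) != 0:
            raise ConfigError(f"frame length must be a power of two >= 256, got {self.n}")
        if len(self.x) != self.n or len(self.y) != self.n:
            raise ConfigError("frame channels must have length n")

    @property
    def center_s(self) -> float:
        return (self.n0 + self.n / 2.0) * self.dt

    @property
    def duration_s(self) -> float:
        return self.n * self.dt


def read_recording(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    expected_dt: Optional[float] = None,
) -> Recording:
    """Read a recording from delimited text and validate its grid.

    ``column_map`` maps the canonical names (time, bp, bfv_left, bfv_right)
    to the file's column names.  ``expected_dt`` cross-checks the interval
    inferred from the time column against the configured one.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    for canon, name in cols.items():
        if name not in df.columns:
            raise FormatError(f"missing column {name!r} (for {canon}) in {path}")
    if len(df) < 2:
        raise FormatError(f"{path} has {len(df)} data rows; need at least 2")
    time = df[cols["time"]].to_numpy(dtype=float)
    dt = float((time[-1] - time[0]) / (len(time) - 1))
    if dt <= 0:
        raise SamplingError(f"time column in {path} is not increasing")
    if expected_dt is not None and abs(dt - expected_dt) > 1e-6 * expected_dt:
        raise SamplingError(
            f"inferred dt={dt:.9g} s disagrees with configured dt={expected_dt:.9g} s"
        )
    return Recording(
        time=time,
        bp=df[cols["bp"]].to_numpy(dtype=float),
        bfv_left=df[cols["bfv_left"]].to_numpy(dtype=float),
        bfv_right=df[cols["bfv_right"]].to_numpy(dtype=float),
        dt=dt,
        subject_meta={"path": str(path)},
    )


def write_recording(rec: Recording, path, float_format: Optional[str] = None) -> None:
    """Write a recording as CSV; default formatting round-trips exactly."""
    df = pd.DataFrame(
        {
            "time": rec.time,
            "bp": rec.bp,
            "bfv_left": rec.bfv_left,
            "bfv_right": rec.bfv_right,
        }
    )
    df.to_csv(path, index=False, float_format=float_format)


def _pow2_floor(n: int) -> int:
    return 1 << (int(n).bit_length() - 1)


def make_frames(
    rec: Recording,
    frame_len: int,
    shift: int,
    channel_pair: str = "left",
    pad: str = "down",
    detrend: bool = False,
) -> list[SignalFrame]:
    """Cut a recording into mean-centered power-of-two frames.

    The requested length N' is rounded DOWN to the nearest power of two
    (tail samples within the frame are dropped); ``pad="up"`` instead keeps
    all N' samples and zero-pads to the next power of two.  Frames start at
    0, shift, 2*shift, ...  ``detrend=True`` removes a linear trend before
    centering (opt-in; the reference procedure removes the mean only).
    """
    if shift < 1:
        raise ConfigError(f"shift must be >= 1, got {shift}")
    if frame_len < 1:
        raise ConfigError(f"frame_len must be >= 1, got {frame_len}")
    if pad not in ("down", "up"):
        raise ConfigError(f"pad must be 'down' or 'up', got {pad!r}")
    if frame_len > len(rec):
        raise InsufficientDataError(
            f"recording has {len(rec)} samples; need at least frame_len={frame_len}"
        )
    n = _pow2_floor(frame_len)
    seg_len = n if pad == "down" else frame_len
    n_out = n if pad == "down" else (n if n == frame_len else _pow2_floor(frame_len) * 2)
    bp = rec.bp
    bfv = rec.channel(channel_pair)
    frames = []
    for n0 in range(0, len(rec) - seg_len + 1, shift):
        sx = bp[n0 : n0 + seg_len]
        sy = bfv[n0 : n0 + seg_len]
        if detrend:
            sx = scipy.signal.detrend(sx, type="linear")
            sy = scipy.signal.detrend(sy, type="linear")
        x = sx - sx.mean()
        y = sy - sy.mean()
        if pad == "up" and seg_len < n_out:
            x = np.concatenate([x, np.zeros(n_out - seg_len)])
            y = np.concatenate([y, np.zeros(n_out - seg_len)])
        frames.append(SignalFrame(x=x, y=y, n0=n0, n=len(x), dt=rec.dt))
    return frames


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    manifest: Optional[Mapping] = None,
    float_format: Optional[str] = None,
) -> list[str]:
    """Write result tables as CSV plus a plain-text run manifest.

    Each table becomes ``<name>.csv``; the manifest records every parameter
    (including the seed) as sorted ``key = value`` lines.  Output is fully
    deterministic: rerunning with identical inputs reproduces identical
    bytes.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.csv")
        try:
            df.to_csv(path, index=False, float_format=float_format)
        except OSError as exc:
            raise DataError(f"cannot write {path}: {exc}") from exc
        written.append(path)
    if manifest is not None:
        path = os.path.join(out_dir, "manifest.txt")
        with open(path, "w") as fh:
            for key in sorted(manifest):
                fh.write(f"{key} = {manifest[key]}\n")
        written.append(path)
    return written
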