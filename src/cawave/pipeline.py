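"""Batch and streaming orchestration of the analysis pipeline.

One frame at a time: center -> Morlet CWT of both channels -> smoothed
cross-wavelet coherence -> gated Mayer-band phase; in parallel (or
instead) the Welch/STFT comparator.  Batch and streaming share the same
per-frame code paths, so replaying a file through the stream interface
reproduces the batch tables bit for bit.
"""

from __future__ import annotations

import logging
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .config import RunConfig, parse_episodes
from .cwt_core import ScaleGrid, build_scale_grid, cwt_forward
from .errors import ConfigError, InsufficientDataError
from .mayer_metrics import (
    BandSeries,
    extract_band,
    sensitivity,
    stft_band_series,
    subrange_scan,
    summarize_subject,
)
from .signal_io import Recording, SignalFrame, make_frames, _pow2_floor
from .stft_coherence import StftConfig, sliding_frames, welch_spectra, msc_and_phase
from .wavelet_coherence import CoherencePhaseMap, SmoothingConfig, coherence_map

logger = logging.getLogger("cawave")

__all__ = ["analyze", "stream_rows", "compare", "process_frame_cwt"]

#: Episode labels mapped to the extremum direction of the phase shift.
EPISODE_DIRECTIONS = {"hypercapnic": "min", "hypocapnic": "max"}


def _smoothing(cfg: RunConfig) -> SmoothingConfig:
    return SmoothingConfig(
        time_kernel_coeff=cfg["coh.time_kernel_coeff"], ls=cfg["coh.ls_voices"]
    )


def _grid(cfg: RunConfig, n: int, dt: float) -> ScaleGrid:
    grid = build_scale_grid(dt, n, dj=cfg["cwt.dj"], omega0=cfg["cwt.omega0"])
    if cfg["cwt.fmin"] is not None or cfg["cwt.fmax"] is not None:
        grid = grid.restrict(cfg["cwt.fmin"], cfg["cwt.fmax"])
    return grid


def _stft_config(cfg: RunConfig) -> StftConfig:
    return StftConfig(
        n_win=cfg["stft.win_len"], window=cfg["stft.window"], n_frame=cfg["frame.len"]
    )


def _center_window(cfg: RunConfig, dt: float) -> Optional[float]:
    """Seconds of frame center used for the per-frame wavelet phase.

    Defaults to the frame shift when frames overlap (each frame then
    reports its newly centered segment, preserving time localization);
    whole frame otherwise.
    """
    cw = cfg["mayer.center_window_s"]
    if cw is not None:
        return cw
    seg = _pow2_floor(cfg["frame.len"]) if cfg["frame.pad"] == "down" else cfg["frame.len"]
    shift = cfg["frame.shift"]
    return shift * dt if shift < seg else None


def process_frame_cwt(
    frame: SignalFrame, grid: ScaleGrid, cfg: RunConfig, frame_index: int = 0
) -> CoherencePhaseMap:
    """Coherence/phase map of one centered frame."""
    cx = cwt_forward(frame.x, grid, pad=cfg["cwt.pad"])
    cy = cwt_forward(frame.y, grid, pad=cfg["cwt.pad"])
    cmap = coherence_map(
        cx,
        cy,
        cfg=_smoothing(cfg),
        threshold=cfg["coh.threshold"],
        t0=frame.n0 * frame.dt,
        frame_meta={"center_s": frame.center_s, "frame_index": frame_index},
    )
    if cfg["cwt.coi_mask"]:
        outside = grid.scales[:, None] > cx.coi[None, :]
        cmap.coh2[outside] = np.nan
        cmap.gate[outside] = False
        cmap.phase[outside] = np.nan
    logger.info(
        "frame %d center=%.2fs gated_fraction=%.3f",
        frame_index,
        cmap.center_s,
        float(cmap.gate.mean()),
    )
    return cmap


def _cwt_side(rec: Recording, cfg: RunConfig, side: str):
    frames = make_frames(
        rec,
        cfg["frame.len"],
        cfg["frame.shift"],
        channel_pair=side,
        pad=cfg["frame.pad"],
        detrend=cfg["frame.detrend"],
    )
    grid = _grid(cfg, frames[0].n, rec.dt)
    maps = [process_frame_cwt(f, grid, cfg, i) for i, f in enumerate(frames)]
    series = extract_band(
        maps,
        band=cfg.band,
        picker=cfg["mayer.picker"],
        fixed_freq=cfg["mayer.fixed_freq"],
        mode="frame",
        center_window_s=_center_window(cfg, rec.dt),
        side=side,
    )
    return maps, series


def _stft_side(rec: Recording, cfg: RunConfig, side: str) -> BandSeries:
    st = sliding_frames(rec, _stft_config(cfg), channel_pair=side)
    return stft_band_series(
        st,
        mayer_freq=cfg["mayer.fixed_freq"],
        threshold=cfg["coh.threshold"],
        side=side,
    )


def _map_table(cmap: CoherencePhaseMap, band) -> pd.DataFrame:
    idx = cmap.grid.band_indices(*band)
    rows = {
        "frame_center_s": np.repeat(cmap.center_s, idx.size * len(cmap.times)),
        "time_s": np.tile(cmap.times, idx.size),
        "pseudo_freq_hz": np.repeat(cmap.grid.pseudo_freqs[idx], len(cmap.times)),
        "coh2": cmap.coh2[idx].ravel(),
        "phase_rad": cmap.phase[idx].ravel(),
        "gated": cmap.gate[idx].ravel(),
    }
    return pd.DataFrame(rows)


def analyze(rec: Recording, cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the configured methods/sides over a recording.

    Returns a dict of result tables: one band series per (method, side),
    a per-frequency subrange table per side (wavelet method), a summary
    table, and optionally long-format in-band coherence maps.
    """
    tables: dict[str, pd.DataFrame] = {}
    series_by: dict[tuple[str, str], BandSeries] = {}
    for side in cfg.sides:
        if "cwt" in cfg.methods:
            maps, series = _cwt_side(rec, cfg, side)
            series_by[("cwt", side)] = series
            tables[f"band_cwt_{side}"] = series.to_frame()
            tables[f"subrange_cwt_{side}"] = subrange_scan(maps, band=cfg.band)
            if cfg["maps.export"] == "band":
                tables[f"maps_cwt_{side}"] = pd.concat(
                    [_map_table(m, cfg.band) for m in maps], ignore_index=True
                )
        if "stft" in cfg.methods:
            series = _stft_side(rec, cfg, side)
            series_by[("stft", side)] = series
            tables[f"band_stft_{side}"] = series.to_frame()
    rows = []
    for method in cfg.methods:
        left = series_by.get((method, "left"))
        right = series_by.get((method, "right"))
        if left is not None and right is not None:
            try:
                s = summarize_subject(left, right, cfg["summary.sd_multiplier"])
            except InsufficientDataError:
                continue
            for side_name, st in (("left", s.left), ("right", s.right)):
                rows.append(
                    {
                        "method": method,
                        "side": side_name,
                        "mean_phase_rad": st.mean,
                        "sd_phase_rad": st.sd,
                        "ci_low_rad": st.ci_low,
                        "ci_high_rad": st.ci_high,
                        "n_gated": st.n_gated,
                        "asymmetry_p": s.asymmetry_p,
                    }
                )
    if rows:
        tables["summary"] = pd.DataFrame(rows)
    return tables


def stream_rows(rec: Recording, cfg: RunConfig) -> Iterator[dict]:
    """Per-frame band-series rows in arrival order (file replay).

    Emits one row per frame advance and per configured method/side; the
    values are identical to the batch tables from :func:`analyze` on the
    same recording.
    """
    n = len(rec)
    seg = _pow2_floor(cfg["frame.len"]) if cfg["frame.pad"] == "down" else cfg["frame.len"]
    shift = cfg["frame.shift"]
    if n < seg:
        raise InsufficientDataError(f"stream shorter than one frame ({n} < {seg})")
    stft_cfg = _stft_config(cfg) if "stft" in cfg.methods else None
    grid = _grid(cfg, seg, rec.dt) if "cwt" in cfg.methods else None
    cw = _center_window(cfg, rec.dt)
    m = 0
    while m * shift + seg <= n:
        n0 = m * shift
        for side in cfg.sides:
            if "cwt" in cfg.methods:
                bp = rec.bp[n0 : n0 + seg]
                bfv = rec.channel(side)[n0 : n0 + seg]
                if cfg["frame.detrend"]:
                    import scipy.signal

                    bp = scipy.signal.detrend(bp, type="linear")
                    bfv = scipy.signal.detrend(bfv, type="linear")
                frame = SignalFrame(
                    x=bp - bp.mean(), y=bfv - bfv.mean(), n0=n0, n=seg, dt=rec.dt
                )
                cmap = process_frame_cwt(frame, grid, cfg, m)
                series = extract_band(
                    cmap,
                    band=cfg.band,
                    picker=cfg["mayer.picker"],
                    fixed_freq=cfg["mayer.fixed_freq"],
                    mode="frame",
                    center_window_s=cw,
                    side=side,
                )
                yield {
                    "method": "cwt",
                    "side": side,
                    "time_s": float(series.times[0]),
                    "phase_rad": float(series.phase[0]),
                    "coh2": float(series.coh2[0]),
                    "freq_hz": float(series.freq_used[0]),
                }
            if stft_cfg is not None:
                # raw segment: the estimator centers each window itself
                frame = SignalFrame(
                    x=rec.bp[n0 : n0 + stft_cfg.n_frame],
                    y=rec.channel(side)[n0 : n0 + stft_cfg.n_frame],
                    n0=n0,
                    n=stft_cfg.n_frame,
                    dt=rec.dt,
                )
                gamma, theta = msc_and_phase(welch_spectra(frame, stft_cfg))
                k = int(np.argmin(np.abs(stft_cfg.freqs_hz(rec.dt) - cfg["mayer.fixed_freq"])))
                g = float(gamma[k])
                gated = np.isfinite(g) and g >= cfg["coh.threshold"]
                yield {
                    "method": "stft",
                    "side": side,
                    "time_s": (n0 + stft_cfg.n_frame / 2.0) * rec.dt,
                    "phase_rad": float(theta[k]) if gated else float("nan"),
                    "coh2": g,
                    "freq_hz": float(stft_cfg.freqs_hz(rec.dt)[k]),
                }
        m += 1


def compare(rec: Recording, cfg: RunConfig) -> pd.DataFrame:
    """Per method/side/episode sensitivity table.

    Episodes come from the ``episodes`` config key; the baseline window is
    the pre-episode stretch ending half a frame before the first episode
    (frames straddling an episode edge are partially contaminated and are
    kept out of the baseline).
    """
    episodes = parse_episodes(cfg["episodes"])
    if not episodes:
        raise ConfigError("compare requires declared episodes (config key 'episodes')")
    for ep in episodes:
        if ep.label not in EPISODE_DIRECTIONS:
            raise ConfigError(
                f"episode label {ep.label!r} must be one of {sorted(EPISODE_DIRECTIONS)}"
            )
    seg = _pow2_floor(cfg["frame.len"]) if cfg["frame.pad"] == "down" else cfg["frame.len"]
    margin = seg * rec.dt / 2.0
    first_start = min(ep.start_s for ep in episodes)
    baseline = (0.0, first_start - margin)
    if baseline[1] <= baseline[0]:
        raise InsufficientDataError(
            "no baseline stretch before the first episode (need at least half a frame)"
        )
    rows = []
    for side in cfg.sides:
        series = {}
        if "cwt" in cfg.methods:
            _, series["cwt"] = _cwt_side(rec, cfg, side)
        if "stft" in cfg.methods:
            series["stft"] = _stft_side(rec, cfg, side)
        for method, s in series.items():
            for ep in episodes:
                res = sensitivity(
                    s,
                    episode_window=(ep.start_s, ep.end_s),
                    baseline_window=baseline,
                    direction=EPISODE_DIRECTIONS[ep.label],
                    episode=ep.label,
                )
                rows.append(
                    {
                        "method": method,
                        "side": side,
                        "episode": ep.label,
                        "theta_bar_rad": res.theta_bar,
                        "theta_ext_rad": res.theta_ext,
                        "eta": res.eta,
                        "rel_change": (res.theta_ext - res.theta_bar) / res.theta_bar,
                    }
                )
    return pd.DataFrame(rows)
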