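import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cawave.config import RunConfig
from cawave.pipeline import _grid, process_frame_cwt
from cawave.signal_io import make_frames
from cawave.synthetic import MayerSpec, NoiseSpec, OscSpec, SynthConfig, make_pair

#: Scale-ladder restriction covering the Mayer band plus the scale-smoothing
#: margin; band-row output is identical to the full ladder (see the ladder
#: restriction test) but ~60x faster.
NARROW = {"cwt.fmin": 0.055, "cwt.fmax": 0.13}


@pytest.fixture(scope="session")
def narrow_cfg():
    return RunConfig(dict(NARROW))


@pytest.fixture(scope="session")
def mk_pair():
    """Factory for coupled BP/BFV pairs at given Mayer lead and seed."""

    def make(phase_lead=1.0, seed=7, duration_s=163.84, white_sd=0.1, **mayer_kw):
        cfg = SynthConfig(
            duration_s=duration_s,
            mayer=MayerSpec(phase_lead_rad=phase_lead, **mayer_kw),
            noise=NoiseSpec(white_sd=white_sd),
            seed=seed,
        )
        return make_pair(cfg)

    return make


@pytest.fixture(scope="session")
def mk_map(narrow_cfg):
    """Factory: single-frame coherence/phase map of a recording's left pair."""

    def make(rec, frame_len=16384, cfg=None):
        cfg = cfg or narrow_cfg
        frame = make_frames(rec, frame_len, frame_len)[0]
        grid = _grid(cfg, frame.n, rec.dt)
        return process_frame_cwt(frame, grid, cfg), grid

    return make


@pytest.fixture(scope="session")
def coupled_map(mk_pair, mk_map):
    """One standard coupled map (lead 1.0 rad, SNR 10) shared across tests."""
    rec = mk_pair(phase_lead=1.0, seed=7)
    cmap, grid = mk_map(rec)
    return cmap
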