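import numpy as np
import pytest

import sealrange as sr
from sealrange import hull_behaviour as hb
from sealrange import movement_hmm as mh
from sealrange import tlocoh_core as tl
from sealrange import track_io as tio
from sealrange.synth_forager import SimConfig, default_patches, simulate_track

COLONY = sr.synth_forager.DEFAULT_COLONY


@pytest.fixture(scope="session")
def sim_track():
    """A 6-week clean simulated female track: projected, filtered, annotated."""
    cfg = SimConfig(seed=11, start="2014-06-01", end="2014-07-15")
    cfg.patches = default_patches("female", np.random.default_rng(5))
    track = simulate_track(cfg, animal_id="F0", sex="female")
    track = sr.project(track, cfg.colony)
    track, _ = sr.filter_fixes(track)
    track = tio.annotate_track(track, cfg.colony)
    track.meta["sim_config"] = cfg
    return track


@pytest.fixture(scope="session")
def sim_hulls(sim_track):
    """k-method hulls on the simulated track with enclosed points and visits."""
    cfg = tl.TLoCoHConfig(s=0.05, k=15)
    hulls = tl.build_hulls(sim_track, cfg)
    hb.compute_enclosed_points(hulls, sim_track)
    hb.compute_visits(hulls, sim_track)
    return hulls


@pytest.fixture(scope="session")
def hmm_fit_and_series(sim_track):
    series = mh.compute_speeds(sim_track)
    fit = mh.fit_hmm2(series)
    return fit, series
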