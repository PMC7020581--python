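"""Build T-LoCoH hulls, the 95 % home range and the 30 % core area.

One convex hull is seeded at every GPS fix from its time-scaled nearest
neighbours (adaptive a-method, budget derived from k = 15).  Sorting
hulls by point density and merging until 95 % of fixes are enclosed gives
the home range; sorting by visit frequency (nsv, separate visits split by
a > 12 h absence) and merging to 30 % gives the core area.
"""

import numpy as np

import sealrange as sr
from sealrange import hull_behaviour as hb
from sealrange import tlocoh_core as tl
from sealrange import track_io as tio
from sealrange.synth_forager import SimConfig, default_patches, simulate_track

cfg = SimConfig(seed=11, start="2014-06-01", end="2014-07-31")
cfg.patches = default_patches("female", np.random.default_rng(5))
track = simulate_track(cfg, "F00", "female")
track = sr.project(track, cfg.colony)
track, _ = sr.filter_fixes(track)
track = tio.annotate_track(track, cfg.colony)

config = tl.TLoCoHConfig(s=0.05, k=15, method="a")
hulls = tl.build_hulls(track, config)
hb.compute_enclosed_points(hulls, track)
hb.compute_visits(hulls, track, ivg_h=12.0)

home = tl.build_isopleths(hulls, len(track.fixes), "point_density", (0.95,)).at(0.95)
core = tl.build_isopleths(hulls, len(track.fixes), "visit_frequency", (0.30,)).at(0.30)

print(f"fixes:                {len(track.fixes)}")
print(f"hulls:                {len(hulls)} ({sum(h.degenerate for h in hulls)} degenerate)")
print(f"95% home range:       {home.area_km2:.0f} km^2 "
      f"({home.achieved_fraction:.1%} of fixes, {home.n_hulls} hulls)")
print(f"30% core area:        {core.area_km2:.0f} km^2 "
      f"({core.achieved_fraction:.1%} of fixes, {core.n_hulls} hulls)")
nsv = [h.nsv for h in hulls if not h.degenerate]
print(f"median visits per hull: {np.median(nsv):.0f} (values > 1 are return visits)")
# The core should be a small, intensively revisited subset of the home
# range, concentrated at the simulated foraging patches.
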