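"""Independent multi-line tracking on a branched (triple-cannulated) vessel.

Three arms meet at a junction; each gets its own segment track line at a
standoff from the junction, so each trace follows only its own arm.
Here one arm dilates while the other two stay constant.
"""

import numpy as np

import myotrack as mt
from myotrack.phantom import branched_track_lines

n = 20
tracks = np.vstack(
    [
        np.linspace(100.0, 135.0, n),  # arm 0 dilates
        np.full(n, 100.0),             # arm 1 constant
        np.full(n, 80.0),              # arm 2 constant
    ]
)
spec = mt.PhantomSpec(
    geometry="branched3",
    frame_size=(500, 500),
    od_track=tracks,
    calibration=mt.Calibration(scale=1.0),
    noise_sd=3.0,
    seed=5,
)
stack, truth = mt.make_branched_stack(spec)
lines = branched_track_lines(spec, standoff_px=130.0)
table = mt.track_stack(stack, lines)

for ln in lines:
    _, d, status = table.trace(ln.id)
    err = np.nanmax(np.abs(d - truth[ln.id]))
    print(
        f"arm {ln.id}: OD {d[0]:6.1f} -> {d[-1]:6.1f} um, "
        f"max |error| {err:.2f} um, {np.sum(status == 'tracked')}/{n} tracked"
    )
# Only arm 0's trace should change over time; the per-arm error shows each
# segment line measures its own arm, unaffected by the others.
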