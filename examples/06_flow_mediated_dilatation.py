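"""Offline flow-mediated dilatation (FMD) analysis in ultrasound mode.

Emulates a brachial-artery FMD recording: a ~4 mm vessel imaged in
B-mode (echogenic walls on a dark lumen), a cuff-release dilatation of a
few percent, and the standard FMD summary — peak diameter change
relative to the pre-release baseline.
"""

import numpy as np

import myotrack as mt

cal = mt.Calibration(scale=40.0, label="ultrasound, 40 um/px")  # ~4 cm field

# baseline 60 s, release at t=60, dilatation to +7.5% peaking with tau 25 s
od_track = mt.simulate_dynamics(
    "drug_step",
    dict(
        baseline_um=4000.0,
        n_frames=180,
        frame_interval_s=1.0,
        events=[(60.0, 4300.0, 25.0)],
    ),
)
spec = mt.PhantomSpec(
    geometry="straight",
    frame_size=(256, 64),
    od_track=od_track,
    calibration=cal,
    intensities=(8.0, 200.0, 15.0),  # dark background, echogenic walls
    noise_sd=6.0,
    seed=11,
)
stack, _ = mt.make_stack(spec)
line = mt.TrackLine(
    id=0, kind="roi_horizontal", geometry=(2, 14, 252, 36), mode="ultrasound"
)
table = mt.track_stack(stack, [line])
t, d, status = table.trace(0)

base = d[t < 60].mean()
fmd = mt.summarize_reactivity(t, d, (0.0, 60.0), (60.0, 180.0))
print(f"baseline diameter : {base/1000:.3f} mm")
print(f"peak diameter     : {d[t >= 60].max()/1000:.3f} mm")
print(f"FMD               : {fmd:.2f} % (simulated stimulus +7.5%)")
# FMD is the percent increase of the post-release peak over the mean
# baseline diameter - the standard endothelial-function readout.
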