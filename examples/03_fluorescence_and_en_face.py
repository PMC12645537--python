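"""Diameter tracking beyond brightfield: bright-walled vessels and strips.

Fluorescence-labelled vessels and B-mode ultrasound show walls as two
bright bands on a dark lumen/background, so edges are found on the
flanks of those bands.  An en-face (flat-mounted) artery has only two
strip edges: inner-diameter detection is disabled and the measured strip
width can be re-expressed as the equivalent diameter of a pressurized
vessel.
"""

import numpy as np

import myotrack as mt

cal = mt.Calibration(scale=0.5)

# fluorescence: bright walls (220) on dark background (5) and lumen (10)
spec_fl = mt.PhantomSpec(
    geometry="straight",
    frame_size=(512, 96),
    od_track=np.full(1, 180.0),
    calibration=cal,
    intensities=(5.0, 220.0, 10.0),
    seed=1,
)
frame, truth = mt.render_frame(spec_fl, 0)
line_fl = mt.TrackLine(
    id=0, kind="roi_horizontal", geometry=(2, 18, 508, 60), mode="fluorescence"
)
rec = mt.measure_line(frame, line_fl, cal)
print(
    f"fluorescence: OD {rec.outer_um:.2f} um, ID {rec.inner_um:.2f} um "
    f"(truth {truth['od_um']:.0f} / {truth['id_um']:.0f})"
)

# en-face strip: only outer edges exist
spec_ef = mt.PhantomSpec(
    geometry="strip",
    frame_size=(512, 96),
    od_track=np.full(1, 160.0),
    calibration=cal,
    seed=2,
)
frame, truth = mt.render_frame(spec_ef, 0)
line_ef = mt.TrackLine(
    id=1, kind="roi_horizontal", geometry=(2, 18, 508, 60), mode="en_face"
)
rec = mt.measure_line(frame, line_ef, cal)
print(f"en-face strip width: {rec.outer_um:.2f} um (inner edges: {rec.inner_um})")
print(
    "equivalent diameter (width convention):        "
    f"{mt.equivalent_diameter(rec.outer_um, 'width'):.2f} um"
)
print(
    "equivalent diameter (circumference convention):"
    f" {mt.equivalent_diameter(rec.outer_um, 'circumference'):.2f} um"
)
# The circumference convention reads the strip width as the opened-out
# vessel circumference, i.e. diameter = width / pi.
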