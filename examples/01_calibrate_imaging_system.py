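"""Pixel-to-micron calibration for common myography imaging setups.

The image-plane sampling is the camera pixel pitch divided by the total
magnification; every diameter the tracker reports is a pixel distance
multiplied by this factor.
"""

import myotrack as mt

setups = [
    ("4x objective, 3.45 um CMOS", 3.45, 4),
    ("10x objective, 3.45 um CMOS", 3.45, 10),
    ("20x objective, 3.45 um CMOS", 3.45, 20),
    ("20x objective, 13 um EMCCD", 13.0, 20),
]

for label, pixel_um, mag in setups:
    cal = mt.make_calibration(pixel_um, mag, label=label)
    print(f"{label:32s} -> {cal.scale:.4f} um/pixel")

cal = mt.make_calibration(3.45, 10)
print()
print(f"A vessel spanning 580 px at 10x is {mt.px_to_um(cal, 580):.1f} um across.")
# Each line prints the physical sampling of one camera/objective pair; the
# last line converts a measured pixel span into microns with that factor.
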