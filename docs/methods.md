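# Methods

This note documents the measurement model, the tunable parameters, the
synthetic phantoms used for validation, and the numerical choices made
where the design was genuinely open.

## Coordinate and sampling conventions

Indices are 0-based; `x` is the column, `y` the row, and positions refer
to pixel centres, so sub-pixel positions are continuous coordinates in
that frame. Profiles are sampled at unit (1-pixel) spacing along a track
line by bilinear interpolation; a line of length `L` px yields
`floor(L) + 1` samples. Bilinear interpolation was chosen over bicubic:
it is exact on the axis-aligned lines used by ROI scanlines (where it
reduces to direct indexing) and the accuracy of the final diameter is
limited by edge localization, not by the interpolant.

ROI track lines sample `n_scanlines` (default 10) evenly spaced
rows/columns across the rectangle. Segment lines average is not applied
across offsets; instead each integer perpendicular offset in
`[-half_width, +half_width]` (default half_width 2, i.e. 5 parallel
scanlines) is measured as its own profile and enters the robust
aggregation below. This treats ROI and segment lines uniformly.

## Edge model

An edge is defined as the extremum of the spatial derivative `dF/dx` of
the intensity profile — the steepest point of the wall transition — not
a half-maximum crossing. The pipeline per profile is:

1. centred moving-average smoothing, window 5 samples (odd; ends padded
   by edge replication). Window 5 suppresses single-pixel noise while
   preserving the sign pattern of edge slopes; configurable.
2. differentiation by central differences (one-sided at the two ends),
   exact for quadratics.
3. peak detection on `+dF/dx` and `−dF/dx` separately. A peak is a
   strict local maximum (plateau maxima report the leftmost sample);
   peaks closer than `min_separation` (default 5 px) are greedily
   suppressed, taller first, leftmost on ties. These tie rules are fixed
   so results are deterministic.

**Qualifying edges.** A derivative peak qualifies when its topographic
prominence is at least `k` × robust SD of `dF/dx` (k default 3; robust
SD = 1.4826 × MAD) *and* its height is at least
`max(k × robust SD, 0.2 × max|dF/dx|)`. The height floor exists because
prominence alone over-credits noise: a +3 SD wiggle beside a −3 SD dip
has ~6 SD prominence, and with the outermost-qualifying-edge pairing
rule a single such wiggle in the background would displace an outer
edge. Both thresholds are relative to the profile, so detection is
invariant to positive intensity scaling and to uniform offsets, and the
same defaults serve 8- and 16-bit data. On noise-free profiles the MAD
is zero and the relative floor alone applies.

**Pairing (brightfield).** Walls are dark on bright background. The
outer-left edge is the *leftmost* qualifying negative-going transition,
the outer-right the *rightmost* positive-going one — the outermost
qualifying pair, which stays correct when the lumen is brighter than the
walls but darker than the background. Inner edges are the strongest
opposite-sign transitions strictly between the outer pair, one in each
half; they are omitted (not zeroed) when no candidate qualifies. En-face
strips reuse this detector with the inner search disabled, since a flat
strip has no lumen edges.

**Bright-band modalities.** Fluorescence-labelled vessels and B-mode
ultrasound show walls as two bright bands on a dark lumen/background.
Band apexes are detected on the smoothed intensity itself (prominence ≥
25 % of the profile's dynamic range, configurable); at least two bands
are required, and the leftmost/rightmost are taken as the walls. Each
outer edge is the steepest point on the band's outward flank, each inner
edge the steepest point on the lumen-facing flank. An `invert` flag
negates the profile before dispatch for reversed-contrast material.

**Sub-pixel localization.** The apex of the relevant derivative signal
is refined by the vertex of a parabola through the peak sample and its
two neighbours, clamped to ±0.5 samples; a zero-curvature triple or a
boundary index returns the integer position. One special case: on
noise-free symmetric step transitions the sampled derivative is exactly
flat over several samples (a plateau of width `window − 1`), and
parabolic refinement of the leftmost plateau sample would bias the edge
by up to half the plateau width. The localizer therefore returns the
plateau *midpoint* whenever the apex value repeats, which is the exact
answer for a symmetric step; blurred or noisy data never produce exact
plateaus and always take the parabolic path.

## Robust aggregation and temporal filtering

Per line and frame, every scanline profile is measured independently;
profiles whose OD deviates from the per-line median by more than 3 × MAD
are discarded (side branches, adherent tissue crossing one scanline),
and survivors are aggregated by median. The record is `tracked` only
when at least half the scanlines survive, otherwise `failed`. Wall
thickness is the median over surviving profiles of the mean of the left
and right per-side widths; per-side widths are symmetric for the
phantoms, and for symmetric aggregation `wall = (OD − ID)/2` holds to
1e-6.

Across frames, a tracked value deviating from the rolling median of the
previous 5 accepted values by more than 25 % of that median — or an
outright failure — is replaced by the last accepted record with
`status = held`; the first frame is accepted if tracked. Held records
are exported so downstream analysis can exclude them. The window and
jump fraction are declared defaults, configurable in the session config.

## Calibration

`scale (µm/px) = camera_pixel_µm / magnification`, stored with its
provenance; e.g. 3.45 µm pixels give 0.8625, 0.345 and 0.1725 µm/px at
4×, 10× and 20×, and a 13 µm EMCCD pixel gives 0.65 µm/px at 20×. All
diameters are pixel spans multiplied by this factor. Named calibrations
live in the plain-text session config so users can switch between
imaging setups.

## Phantoms and what they do (not) show

Phantoms render a tube (or strip, or three-armed junction) from the
per-pixel distance to the vessel axis: background outside `OD/2`, wall
between `ID/2` and `OD/2`, lumen inside, with a one-pixel anti-aliased
(distance-smoothed) boundary, followed by Gaussian optical blur
(`psf_sigma`, default 0.8 px) and additive Gaussian noise. The
anti-aliased boundary puts the intensity mid-transition exactly at the
analytic radius, so the derivative extremum of the blurred profile falls
at the true edge and sub-pixel accuracy claims are testable: noise-free
recovery is better than 0.25 px across OD 50–400 px in all modalities,
and rotating tube and line together by 30° changes the measured OD by
less than 0.1 px. Per-frame noise is seeded `seed + frame_index`, so
stacks are bit-reproducible frame-wise.

What the phantoms do *not* emulate: ultrasound speckle, out-of-focus
structure, illumination gradients, wall-intensity asymmetry and motion
within a frame. Passing the phantom suite therefore demonstrates the
correctness and precision of the measurement chain, not performance on
every real-world artefact; the robust aggregation and temporal filter
are the mechanisms intended to absorb such artefacts, and they are
exercised by corrupted-scanline and failure-frame tests.

The dynamics generators are *fixtures, not physiology claims*: drug
responses are piecewise-exponential relaxations toward a target with
time constant τ (evaluated analytically segment-by-segment, so sampled
values are exact), and the pressure–diameter model is
`OD_p(P) = D0 (1 − a e^(−P/Pc))` for the passive curve (defaults D0 =
180 µm, a = 0.65, Pc = 30 mmHg, giving a realistic saturating passive
curve for a resistance artery) minus a tone term for the active curve.
Tone is `T_max · s((P − P_th)/w)` with a smoothstep `s`, `T_max` = 55 µm,
threshold `P_th` = 60 mmHg, width `w` = 60 mmHg: exactly zero at or below
threshold and smoothly rising above it, emulating sustained myogenic
constriction of resistance arteries at pressures above ~60 mmHg.

## Simulated pressure servo and protocols

A protocol is a staircase `start → stop` in `step` mmHg increments, stop
always included (a non-dividing step produces a flagged partial final
level), each level held for `hold` seconds (default 120 s, a typical
myogenic equilibration time; the value is configurable). The servo is a
first-order system updated with the exact exponential step
`p ← sp + (p − sp) e^(−dt/τ)` (default τ = 2 s), sampled at the frame
interval *before* each update so the trace equals the closed form at
sample times. Optional sinusoidal oscillation (amplitude, rate ≤ 400
cycles/min, the murine heart rate) rides on the setpoint; on a 5-minute
trace its dominant FFT frequency equals rate/60 Hz within one bin.
`run_protocol` closes the loop: servo pressure → pressure–diameter model
→ phantom frame → tracker, logging a "pressure set" event at every level
transition and annotating each record with the pressure reading.
Physical pump hardware is out of scope; the servo contract is the
extension point for real drivers.

## Detection-limit benchmark

The benchmark renders a 60 µm vessel at 0.345 µm/px before and after a
known diameter step, with independent noise at 5 % of the
background-to-wall range, and calls the step detected when the measured
change has the right sign and at least half the true magnitude. Under
these conditions single-frame measurement SD is ~0.05 µm (0.14 px) and
steps of 0.5 µm are detected in ≥ 95 % of 100 trials — comfortably below
the 1–2 µm scale that optical resolution makes practically meaningful.
The problem sizes (256 × 48 px frames, 100 trials per candidate step)
keep the full simulation under a minute.

## I/O conventions

TIFF stacks are read via tifffile; RGB pages (common for ultrasound
video exports) are converted by Rec. 601 luminance
(0.299 R + 0.587 G + 0.114 B). Results are exported as two RFC-4180
CSVs — `<base>_results.csv` (one row per frame × line) and
`<base>_table.csv` (the event log) — with '.' decimal separator, UTF-8,
and absent quantities as empty fields, never zeros; numeric fields round-
trip to better than 1e-6. Overlay stacks copy the raw pixels and draw
each track line plus tick marks at the edge positions (outer and inner
at distinct gray levels), reconstructed symmetrically about the line
midpoint from the recorded diameters.

## Known limitations

* Edge pairing assumes the profile spans the whole vessel with
  background visible on both sides; profiles ending inside a wall fail
  rather than extrapolate.
* The en-face "equivalent diameter" has no canonical formula; both the
  identity (default, conservative) and width/π (circumference reading)
  conventions are exposed.
* The temporal filter trades responsiveness for robustness: a genuine
  diameter change larger than 25 % within one frame would be held until
  the rolling median catches up.
* Wall thickness is meaningful only when both inner edges are found;
  fluorescence bands thinner than ~4 px blur into single-peak bands and
  are rejected rather than measured.
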