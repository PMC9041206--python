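# Methods

This note documents the models behind the simulated rig, the numerical
choices in the analysis code, and what the desk-scale tests do and do not
demonstrate about real hardware.

## Coordinate conventions

Stage coordinates are millimetres: X rightward, Y away from the door, Z up,
origin at the boot pose (the stage powers up at X0 Y0 Z0; there are no
homing switches). The camera maps a world point (u, v) µm to pixel
((u − x·1000)·s + W/2, (v − y·1000)·s + H/2) with s the pixel scale in
px/µm — so driving the stage in +X shifts specimen content left in the
image. `G92Z0` redefines the firmware Z origin without motion; the
simulator therefore tracks the firmware frame (what G-code targets mean)
separately from the true physical position (what the camera sees).

## Virtual stage

Realized motion per axis is `commanded × firmware_steps_per_mm /
true_steps_per_mm`: the firmware converts millimetres to motor steps with
its configured setting, the physical axis converts steps back with the true
pitch. Additive Gaussian positioning noise (default σ = 2 µm per commanded
axis per move, seedable) represents backlash-like repeatability limits at
the magnitude hardware of this class exhibits. The simulated clock advances
by distance / max_speed (default 130 mm/s).

**Vibration.** Moving the gantry rings the structure; the model is an
amplitude A(t) = A₀·exp(−t/τ) with A₀ = 10 µm and τ = settle_time/3, so the
residual is below 5% of A₀ once the configured settle time (defaults 0.6 s
X, 1.0 s Y) has elapsed. The camera converts amplitude to isotropic
Gaussian blur via `vibration_blur_gain` (default 0.5 px/µm). The decay
model and the gain are the simulator's defining calibration: they are set
so that the observable — the sharpness-versus-delay curve reaching 95% of
its plateau — crosses at the configured settle times on the default cell
specimen, which is exactly the behaviour the rest-time analysis is designed
to recover. All four parameters are configurable.

## Virtual camera and specimens

Rendering is: ideal pattern sampled at pixel centres → Gaussian defocus
blur (σ = 25 px per mm of |z − focal_plane|; combined in quadrature with
vibration blur) → optional left-to-right 0.7→1.0 illumination gradient
(mimicking oblique single-LED illumination) → additive Gaussian sensor
noise (default σ = 2/255), seeded deterministically from the camera seed
and the pose so identical captures are byte-identical. Output is 8-bit
single-channel; files are written as 24-bit BMP (channel-replicated) or
JPEG quality 95.

Specimens live in world coordinates and are procedural except for `cells`:
N non-overlapping Gaussian blobs (σ 3–8 µm, i.e. nucleus-scale bright
features of unstained monolayer cells under oblique illumination) placed by
seeded rejection sampling in a stated window. `graticule` (parallel lines
at known spacing), `usaf_bars` (a three-bar triplet at a stated lp/mm),
`slant_edge` (a half-plane with a 1-px anti-aliasing ramp) and `uniform`
cover the metrology workflows.

What the simulator does **not** model: physically correct PSFs,
fluorescence photophysics, photobleaching, stage backlash or acceleration
profiles, condensation or thermal drift of the incubator environment.
Passing tests therefore demonstrate the correctness of the *algorithms and
their closed-loop behaviour* under the stated noise models, not the
performance of any physical instrument.

## Plate calibration

The well diameter is measured twice (vertical and horizontal landmark
pairs); the two estimates must agree within 5% — the same tolerance ethos
as the motion rule — and D is their mean. Well "segments" (sub-well start
anchors) are a 3×3 grid over the well's bounding square, row-major from the
top-left corner; the default sweep anchor is the minimum-X/Y corner so a
scan enters the well from outside. The config-facing "five-array" export is
(label, default X, default Y, row offset, col offset) per well.

## Optics calibration

Graticule pixel scale: the image is collapsed to a line profile per axis
and the dominant period is the global maximum of the autocorrelation after
the zero-lag lobe decays below 0.5; a peak below 0.25 means no graticule.
Quantization limits accuracy to about half a pixel per period, ample for
scan-step planning. The published pixel-area figure and the published FOV
for the 10X build are mutually inconsistent, so both are carried as
independent config inputs and never derived from one another.

Slant-edge MTF: edge crossings are located per row by the centroid of the
row gradient, a line is fitted, all pixels are projected onto the edge
normal and binned at 1/4 px (4× oversampling); the ESF is differentiated,
a Hann window centred on the LSF peak suppresses far-field noise, and the
FFT magnitude is normalized at DC. On a σ = 2 px Gaussian-blurred edge the
curve matches exp(−2π²σ²f²) to well within 3% up to half-Nyquist.

## Autofocus

Sharpness is the variance of the 3×3 discrete Laplacian response after a
Gaussian prefilter; "radius" is the Gaussian σ in pixels with the kernel
truncated at 3σ, radius 0 disables the prefilter. Variance was chosen as
the aggregation statistic (standard, scale-stable); it is a stand-in for
proprietary focus plugins, so its absolute values are not comparable across
implementations. Ties break toward the lowest slice index. The default
sweep step is 0.2 mm; a best slice on the sweep boundary raises a warning.

## Motion validation

Default protocol: 10 distances (0.1–1.0 mm) × 2 axes × 2 directions × 10
repeats = 400 trials, 800 images. After each trial the stage retraces the
move so the tracked texture stays in the field of view for the whole
protocol; the retrace is subject to the same miscalibration (and so returns
exactly) plus noise (a bounded random walk, ~60 µm over 800 moves).

Motion validation uses a low-magnification *survey* camera configuration
(840×600 px at 0.3 px/µm, a 2.8×2 mm field): with the high-magnification
profile a 1.3 mm realized move would leave no overlap between the image
pair, whereas the survey field keeps even the worst miscalibrated move
(1.0 mm × 1.3) well inside one frame — the same reason one validates motion
on a low-power objective at the bench.

Translation is estimated by phase correlation with 10× upsampled peak
refinement. Confidence is the normalized cross-power peak height (1 for a
pure cyclic shift); the rejection threshold adapts to image area as
10/√N — about twice the peak two unrelated noise images produce, which
scales as ~4.5/√N. Medians pool directions and repeats per (axis,
distance); the correction ratio is the median across distances of
observed/commanded. Observed motion is the absolute shift component along
the commanded axis.

Stationary stability regresses per-axis deviation (from the first sample)
on time with OLS; a two-sided slope p-value above 0.05 is reported as "no
persistent drift". With two axes tested at α = 0.05, about 10% of perfectly
still runs will flag one axis by chance — the per-axis false-positive rate,
not the any-axis rate, is the calibrated quantity.

Rest time: after a 1 mm move, frames at 0.1 s intervals over 2 s; the
plateau is the median of the last five scores and the result is the first
delay reaching 95% of it. On the default rig this recovers the configured
settle times to within one sampling interval.

## Scan planning and scheduling

Wells are visited row-major (A1, A2, … B1, …), skipping exclusions;
within a well the grid is row-major with X varying fastest (matching
row-by-row stitching conventions; serpentine is deliberately not used, so
tile order maps trivially to grid indices). Consecutive positions differ by
exactly one step increment, giving 20% overlap between adjacent fields at
the default 0.8 overlap factor.

Schedule semantics are start-to-start: if the requested interval is at
least the estimated sweep duration, starts are exact multiples of the
interval; otherwise scans run back to back and the schedule carries an
explicit flag (rather than silently slipping). The duration estimate is
positions × a per-image cost (5.125 s BMP, 1.125 s JPEG — set so the
reference 24-well, 4×4-per-well sweep reproduces the 32.8/7.2-minute
figures of the hardware the simulator stands in for); it is a planning
aid, not a measured quantity.

The simulated clock drives the scheduler, so multi-hour time-lapses run in
seconds and re-running a config with the same seeds reproduces every BMP
byte for byte.

## Problem sizes in the test suite

Tests run the same algorithms at reduced scale: survey-camera frames
(840×600) for motion work, 320×240 frames for the 50-stack autofocus
experiment, 160×120 frames for the 800-image protocol count, and 3 repeats
instead of 10 for closed-loop calibration checks. These sizes were chosen
as the smallest at which the estimators' noise floors are comfortably below
the documented tolerances; nothing in the algorithms depends on frame size.

## Known limitations

- The autocorrelation pixel-scale estimator returns integer-pixel periods;
  sub-pixel refinement would matter only below ~1% scale accuracy.
- Phase correlation assumes rigid translation; rotation or scale change
  (plate re-seating) is outside its model and will surface as low
  confidence.
- The steps/mm correction assumes the error is a pure scale factor;
  distance-dependent errors (backlash, belt tooth defects) would need the
  per-distance table inspected directly.
- JPEG file sizes are content-dependent and are not treated as reference
  quantities; only the uncompressed BMP dialect has an exact size.
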