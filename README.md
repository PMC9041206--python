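# incuscan

Automation stack for an in-incubator well-plate scanning microscope, built
on the motion system of an entry-level cartesian 3D printer: plate
calibration from user-captured well landmarks, objective calibration and
resolution metrics, GRBL-dialect G-code stage control, Laplacian autofocus,
motion-fidelity validation with steps-per-mm correction, and time-lapse
scan planning and execution.

Everything runs against a **fully simulated rig** — a virtual stage with
configurable steps-per-mm miscalibration, positioning noise and post-move
vibration, and a virtual camera that renders a world-coordinate specimen
with defocus blur, vibration blur, illumination gradients and sensor noise.
That makes the entire control and analysis pipeline testable at desk scale,
with no hardware, while keeping every interface the same shape it would
have against a real stage.

It is aimed at labs building or commissioning low-cost scanning
microscopes: the calibration and validation workflows are exactly what you
run against hardware, and the simulator is the test double that lets you
develop and regression-test them without one.

## The methods at the core

**Plate geometry.** Six landmarks of well A1 and its neighbours (the top-,
bottom-, left- and right-most points of A1, the left-most point of A2, the
top-most point of B1) give the well diameter *D* (mean of the vertical and
horizontal extents, which must agree within 5%), the well pitches
ΔX = A2ₗ − A1ₗ and ΔY = B1ₜ − A1ₜ, and the A1 centre. Every well centre is
then `a1_center + ((col−1)·ΔX, (row−1)·ΔY)`.

**Optics.** The pixel scale (px/µm) is measured from a graticule image by
autocorrelation of its line profile; FOV = sensor / scale, and the scan
step increments are FOV × 0.8, leaving 20% tile overlap for stitching.
Resolution is quantified by the USAF-1951 line density
`2^(group + (element−1)/6)` lp/mm and by a slant-edge MTF (oversampled
edge-spread function → line-spread function → windowed FFT).

**Motion fidelity.** Moves of 0.1–1.0 mm on X and Y, both directions, ten
repeats, imaged before and after (800 images). Each pair's displacement is
measured by sub-pixel phase correlation. Per (axis, distance), the median
observed motion must be within 5% of commanded (≤ 1 mm) or within ±13 µm
(> 1 mm); a failing axis gets a corrected firmware steps-per-mm of
`current × commanded / observed`, which removes a pure steps-per-mm
miscalibration in one cycle.

**Autofocus.** Sharpness = variance of the 3×3 Laplacian after a Gaussian
prefilter of radius (σ) 1 px; a Z sweep at 0.2 mm steps picks the sharpest
slice and re-zeros the axis there with `G92Z0`.

## Worked example

Calibrate a 6-well plate from landmarks, derive a 10X objective profile,
then run a short motion-validation protocol on a deliberately mis-set rig
(firmware believes 80 steps/mm, the true axes need 100 — the stage
under-moves by 20%):

```python
from incuscan import *
from incuscan.camera import CameraConfig, build_specimen
from incuscan.motion import StageConfig, VirtualStage

lm = WellLandmarks(a1_top=(30, 10), a1_bottom=(30, 46), a1_left=(12, 28),
                   a1_right=(48, 28), a2_left=(51, 28), b1_top=(30, 49))
plate = calibrate_plate_from_landmarks(lm, format=6)
profile = derive_profile(1.292, (1680, 1200), 0.8, label="10X")

camera = CameraConfig(resolution=(840, 600), pixels_per_um=0.3, seed=1)
specimen = build_specimen("cells", n=120, window_mm=(4.0, 4.0), seed=5)
rig = StageConfig(firmware_steps_per_mm=(80, 80, 400),
                  true_steps_per_mm=(100, 100, 400), seed=2)

trials = build_motion_protocol(distances=[0.2, 0.6, 1.0], repeats=3)
m = measure_motion(VirtualStage(rig), camera, specimen, trials)
summary = summarize_motion_fidelity(m, camera.pixels_per_um,
                                    {"x": 80.0, "y": 80.0})
print(summary.to_text())
```

Output:

```
D = 36.0 mm, pitch = (39, 39) mm, A1 centre = (30.0, 28.0)
FOV (um): (1300.3, 928.8)
step increments (um): (1040.2, 743.0)
Motion fidelity summary
=======================
X  0.200 mm ->  0.1595 mm (-20.25%)  FAIL
X  0.600 mm ->  0.4808 mm (-19.86%)  FAIL
X  1.000 mm ->  0.7988 mm (-20.12%)  FAIL
Y  0.200 mm ->  0.1597 mm (-20.17%)  FAIL
Y  0.600 mm ->  0.4797 mm (-20.06%)  FAIL
Y  1.000 mm ->  0.8012 mm (-19.88%)  FAIL
X steps/mm: current 80.000, adjust to 100.146
Y steps/mm: current 80.000, adjust to 100.069
```

Every distance fails the 5% rule at −20%, and the recommended settings
(≈100 steps/mm, within 0.15% of the true value) fix the rig in one cycle:
`apply_steps_correction(rig, summary)` returns a config whose realized
motion is within 1% of commanded.

The same workflows are available from the shell:

```
incuscan usaf 7 6                      # -> 228.1 lp/mm
incuscan calibrate-plate landmarks.yaml --plate-format 6
incuscan validate-motion --config run.yaml --seed 1 --folder runs/motion
incuscan autofocus --config run.yaml --seed 1
incuscan scan --config run.yaml --folder runs/plate --format jpeg
```

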