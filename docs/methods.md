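# Methods

## Eye model

**Model.** A patch of 37 ommatidia stands in for the region of a mosquito
compound eye looking at a target; whole anopheline eyes carry ~200–300
ommatidia, but only the patch whose receptive fields the target can cover
matters for detection, and the patch is centered on the gaze, which points
at the target center. Axes are laid out as a central axis plus concentric
rings k = 1, 2, 3 of 6k axes at eccentricity k × 8° (the interommatidial
angle), evenly spaced in azimuth — a stylized hexagonal arrangement in which
every ring sits at an exact multiple of the interommatidial angle. Each
receptive field is a circular angular disk of 40° full width; at 8° spacing
neighboring fields overlap heavily, which is what a dark-adapted
superposition-style eye with a ~40° resolution angle looks like to a
geometric model.

**Projection.** All overlap computations happen on a 2D "angular screen":
the azimuthal-equidistant projection about the gaze direction, which
preserves angular distance from the gaze axis exactly and distorts azimuthal
extent only at second order (few-percent area error at 40–50° eccentricity,
far smaller near the axis where detection is decided). A vertical disk
centered on the gaze maps to a circle of angular radius arctan(radius /
distance). A floor-lying disk seen from flight height h is projected point
by point: each rim point's direction from the eye is converted to (angle
from gaze, azimuth about gaze). Both outlines are polygons with
`polygon_resolution` (default 360) vertices; receptive fields are polygons
of the same resolution, and coverage is computed with shapely polygon
clipping. A 360-gon under-estimates a disk's area by ~5 × 10⁻⁵
relative — far below the 0.5-percentage-point tolerance the geometry tests
enforce against the analytic circle-circle lens formula and a Monte-Carlo
point-sampling oracle.

**Detection rule.** Ommatidia whose coverage s_i reaches the individual
threshold θ = 20 % contribute; the eye's total is the summed excess
Σ (s_i − θ), and the target is detected when the total reaches 100 %.
Thresholds are inclusive with 10⁻⁹ slack so results are stable under
floating point. The alternative reading — summing the full s_i of
supra-threshold ommatidia — is implemented as
`EyeParameters(summation="supra_sum")`; with the default geometry it places
every detection boundary exactly where the central 7 ommatidia cross θ
simultaneously (95 cm for the 30 cm vertical disk) and was rejected as the
default because the excess rule reproduces the detection-distance
relationships this model family is known for (vertical ≈ 2× horizontal for
equal diameter, and exact size-scaling for vertical targets: the 30 cm disk
at 74 cm, the 15 cm disk at 37 cm). For vertical targets the rule is
scale-invariant — doubling the diameter exactly doubles the detection
distance — because the image depends only on D/d.

**Sweep.** Distances run from `scan_step_cm` (1 cm) to `scan_max_cm`
(500 cm); horizontal targets start past the disk edge, since an eye directly
over the disk has no defined gaze-at-center geometry (it is rejected as a
geometry error rather than special-cased). The sweep reports the *largest*
detected distance: for vertical targets stimulation is monotone in distance
(the tests assert it), but a foreshortened floor target's total need not be,
so no early exit is taken.

**Parameters that matter.** `interommatidial_angle_deg` (8°) and
`receptive_field_deg` (40°) are the published dark-adapted anopheline
optics; detection distance scales inversely with the tangent of the
critical angular radius they imply, so species with finer optics can be
modeled by lowering them. `individual_threshold_pct` = 20 and
`total_threshold_pct` = 100 define the (dimensionless) sensitivity;
`altitude_cm` = 15 is the flight height above a floor target. The 40° value
is a full width — its half, 20°, is the receptive-field radius; treating 40°
as a radius would roughly halve every detection distance.

## Track analysis

**Cleaning.** The acquisition system drops frames and occasionally emits
impossible points. Cleaning (in order): (1) remove points outside the
120 × 200 × 120 cm arena; (2) remove isolated spikes — points whose implied
speed to *both* neighbors exceeds 400 cm/s (~17× the 24 cm/s mean flight
speed), iterated to a fixed point so the filter is idempotent; (3) fill
gaps of up to 5 missing frames by per-axis linear interpolation, flagging
filled points `interpolated`, and split tracks at longer gaps; (4) smooth
each axis with a cubic smoothing spline (scipy `UnivariateSpline`) whose
total residual budget is `smoothing_parameter` (default 0.04 cm², i.e.
~2 mm RMS) per point — 0 reproduces the input, and straight constant-speed
tracks are invariant under any budget because a linear fit has zero
roughness penalty. Observed points are never invented or reordered; only
flags distinguish interpolated points.

**Visits and metrics.** A target's region of interest is its footprint
grown 10 cm per side in X and Y, from the floor to 30 cm (floor targets) or
60 cm (vertical targets). Membership is half-open ([min, max) per axis) so
adjacent regions never double-count a boundary point. A visit is a maximal
run of ≥ 2 consecutive in-cuboid points; single-point crossings (20 ms at
50 fps) are noise, not behavior. Per visit: duration = (frame span)/rate;
path = summed 3D steps; tortuosity = path / entry-to-exit chord, reported
as missing when the chord is under 0.1 cm (an out-and-back loop has no
meaningful straightness); mean speed = path/duration. Vertical-target
visits are labeled upwind/downwind by mean y against the target plane.
Landing counts are an external per-assay input (the tracker stops following
landed animals); landing density is 100 × landings / target area in cm².
Per-assay totals and per-visit means are both emitted, since either may be
wanted downstream.

## Synthetic tracks

The simulator generates what the pipeline consumes, with ground truth known
by construction. Flight is a correlated random walk: each frame the heading
is a persistence-weighted blend (default 0.9) of the previous heading and
an isotropic random direction; speeds are truncated-normal about 24 cm/s
(SD 6 cm/s); walls reflect by folding the position and flipping the heading
component, which preserves the speed distribution. Only the mean speed and
arena size are anchored to measurements; spread, persistence and the
corruption rates (1 %/frame gap starts of 1–8 frames, 0.5 %/frame 50 cm
spikes) are conventions chosen to resemble wind-tunnel acquisitions.
Corruption never touches track endpoints, keeps gaps non-adjacent and
spikes isolated, and records every altered frame, so the cleaning rules can
be checked defect by defect.

Planned-visit scenarios construct a track that enters each requested cuboid
exactly n times for exactly the requested dwell: the track stages on a
"porch" 3 cm outside the entry face, holds there for 12 frames (longer than
any interpolatable gap, so corruption can never merge adjacent visits),
hops across the face in one frame into a closed dwell loop that starts and
ends 4 cm inside, and hops back out. Short hops mean a dropped-frame gap at
a transition is bridged by an equally short chord, so recovered durations
and path lengths stay within the 2 % the recovery tests demand. Ground
truth is computed from the clean constructed track.

**What passing tests do and do not show.** The simulator has no odor plume,
no anemotaxis, no casting/surging, and its dwell loops are far more regular
than real exploratory flight; recovery results demonstrate that the
cleaning rules are unbiased for the defect classes they target, not that
real mosquito metrics survive arbitrary sensor failure. Likewise the eye
model is purely geometric: no contrast sensitivity, light adaptation,
wavelength dependence or motion vision, and circular targets only — its
outputs are theoretical upper bounds on visual detection, not measured
behavior.

## Numerical choices and degenerate inputs

- Thresholds and detection comparisons are inclusive with 1e-9 slack.
- Zero-area angular images stimulate 0 % (never an error); targets with
  vanishing diameter are rejected at construction, and a sweep that never
  detects returns an absent maximum plus the full trace.
- Test problem sizes: detection sweeps in tests stop at 120–150 cm (all
  default-parameter detections lie below 100 cm); the oracle grid is 20
  circle pairs with a 10⁵-sample Monte-Carlo check; pipeline-recovery runs
  50 seeded scenario tracks of 2 visits each (5–7 s dwell). The acceptance
  script sweeps the full default 500 cm range.
- Tracks shorter than 4 points cannot carry a cubic spline and are returned
  unsmoothed with a warning; duplicate frames in input tables are dropped
  (first kept) with a warning; malformed rows fail loudly with line numbers.
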