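# Methods

This note records the models, conventions and design choices behind
`loopalign`, and what the simulator does and does not emulate.

## Geometry and motion model

Lab frame: `x` along the ω rotation axis, `y` vertical (up), `z` along the
beam at ω = 0; the beam crosses the rotation axis at the origin.  The
centering translations ride on the rotation stage, so a material point `p`
of the sample sits at `lab = R_x(ω) · (p + m)` with `m = (x, y, z)` the
motor vector.  Centering the loop tip therefore means driving `tip + m → 0`,
which simultaneously puts the tip on the rotation axis and at the beam —
that is why aligning the tip to the beam marker at two orthogonal ω values
solves the problem exactly: the first orientation fixes the in-plane pair,
the second fixes the former depth axis.

Images use the 0-based top-left origin with y growing downward; moving the
sample +1 mm in lab y moves its silhouette up by `px_per_mm` pixels.  The
microscope (narrow field, 200 px/mm, 480×360 by default) looks along the
beam and images lab (x, y); the top camera (wide field, 50 px/mm, 640×480)
looks down and images lab (x, z).  Both beam markers default to the image
center.  The magnification ratio between the cameras is configuration, not a
claim about any particular instrument; the only structural requirement is
that the top field of view is wide enough to capture mount errors that the
microscope cannot see.

Projection is orthographic.  Depth of field is not modeled; the prelocation
step's real-world purpose of bringing the sample into the microscope focus
band is represented by its geometric effect (bounding the depth offset).
The algorithms consume silhouettes, not blur, so this loses nothing they
depend on.

## The sample model

A scene is a pin (cylinder along the rotation axis) carrying a planar
elliptical loop with semi-axes `a ≥ b` and a thickness `t < 2b` normal to
the loop plane, the tip at the far end of the loop; an optional crystal sits
at loop-plane coordinates (u, v) inside the ellipse, and a Gaussian
"ice-jitter" displacement of configurable σ can be applied once between
optical and diffraction centering to emulate sample settling.

The loop solid is an **oblate ellipsoid** with semi-axes (a, b, t/2) rather
than an extruded flat plate.  This is deliberate: the projected area of an
ellipsoid, `π·a·√(b²cos²α + (t/2)²sin²α)` with α the angle off the flat
face, is exactly 180°-periodic and exactly maximal at the flat face, and
its edge-on projected height is exactly `t`.  An extruded plate's projected
area is `π·a·b·|cos α| + 2·a·t·|sin α|`, whose maximum is *biased off* the
flat face by `atan(2t/πb)` (several degrees for realistic loops) — it would
make the ground truth itself ambiguous.  The ellipsoid keeps every recovery
test well-posed while preserving the two facts the procedures rely on.

Rendering evaluates the ellipsoid and pin analytically per pixel over the
primitives' bounding rectangle, with 2×2 sub-pixel sampling for graded
edges, onto a uniform light background (level 230) with a dark sample
(level 30).  Rendering is a pure function of (scene, motor state, camera):
bit-identical frames for identical inputs.

Default scene parameters (a = 0.40 mm, b = 0.25 mm, t = 0.20 mm, pin radius
0.05 mm; randomized scenes draw a ∈ [0.30, 0.45], b ∈ [0.18, 0.28],
t ∈ [0.6, 0.9]·b) correspond to ordinary nylon loops holding 50–200 µm
crystals.  The thickness-to-width ratio matters: the five-point sinusoid fit
of the near-`|cos|` area curve carries an intrinsic bias that shrinks as the
loop gets thicker relative to its width; at t/(2b) ≈ 0.3–0.45 the worst-case
bias is below 1.3°, comfortably inside the 2° recovery budget.

## Spot-count model

Expected spots at a motor target are
`background + peak · exp(−d² / 2σ²)` with `d` the **3D** distance from the
beam position to the crystal center; observed counts are Poisson.  Defaults:
peak 100, background 2, σ = 0.05 mm.  Using the 3D distance means a crystal
displaced along the viewing axis also diffracts less — which is what makes
the 90°-away line scan genuinely informative in the simulation, at the cost
that a strongly depth-displaced crystal can fall below the default threshold
at the 2D orientation (see the line-scan benchmark below).

## Centering procedures

* `calibrate_top_cam` mounts a small reference loop, centers it on the
  microscope beam marker (the trusted reference), and reads the tip pixel on
  the top camera — that pixel *is* the beam position there, so the procedure
  recovers arbitrary top-camera mount drift to a pixel.
* `prelocate` / `center_on_tip` iterate measure-and-move at ω and ω + 90°,
  up to 3 rounds (default tolerance: 3 px top, 2 px microscope).  One
  round normally suffices in the noiseless simulator; the extra rounds guard
  against pixel quantization.  Entry ω is restored on exit.
* `center_to_flat` runs tip centering, sweeps ω over entry + {0, 40, 80,
  120, 160}° measuring the loop-ROI projected area (180° is omitted as
  redundant with 0° under the period), least-squares fits
  `c₀ + c₁cos 2ω + c₂sin 2ω`, measures the vertical extent at ω* + 90°,
  re-centers the tip, and takes the bounding box at ω*.  The 2ω model is
  physically forced: a planar loop's silhouette repeats every half turn.
* Degenerate fits (modulation amplitude below 2% of the mean area — e.g. a
  spherical drop) fall back to the entry ω with the result still usable and
  flagged; a loop that never segments yields status `not_found`, which the
  orchestrator treats as a failed centering step.
* The "loop region of interest" is the foreground within 1.2× the expected
  loop diameter of the detected tip, so the pin and gripper do not inflate
  area or bounding-box measurements.  Pin exclusion is our assumption; the
  tip-tie-break (median perpendicular coordinate of the tied set) is chosen
  for stability and symmetry.

`grid_from_result` converts the bounding box into motor targets at the
flat-face ω: `ceil(extent/beam)` boxes per axis at exactly one beam-size
spacing, centered on the box, visited in serpentine order from the top-left.
Pixel-to-motor conversion is `Δmotor = R_x(ω)ᵀ · Δlab` with
`Δlab = Δpixel / px_per_mm` under the sign conventions above.

## Grid-scan decisions

Four threshold modes with per-box minimum spot counts — default 10,
strong 40, weak 3, always-collect 0 (configurable; the ordering
strong ≥ default ≥ weak is enforced).  These numeric defaults are
placeholders standing in for instrument-specific tuning; the structure is
what the tests exercise.  Selection takes the maximum count; ties break by
distance to the grid centroid, then row-major.  The line scan reuses the 2D
policy and spans the full ROI height; the vertical grid is *never*
restricted to the measured loop thickness.  No sub-box centroid refinement
is performed: the decision selects a box, and spot count is the only
criterion (a known limitation — multiple lattices or cracks can mislead it).

A sample is skipped when all 2D boxes are below threshold (the line scan is
then never run), or when the line scan itself has no box above threshold.

## Orchestration

The execution stacks per method:

| method            | stack                                                |
|-------------------|------------------------------------------------------|
| standard          | safety_check, mount, optical_center, diff_center, daq |
| multi_orientation | safety_check, mount, optical_center, diff_center, daq |
| serial            | safety_check, mount, optical_center, daq             |
| robot_test        | safety_check, mount                                  |
| alc_test          | safety_check, mount, optical_center                  |

Every transition (unknown → in_progress → success/skipped/failed) is
appended to a JSON-lines journal and fsynced, so replaying the journal
reconstructs the execution records exactly.  Any step failure stops the
whole run; a grid-scan skip only marks that sample's daq as skipped and the
run continues.  Samples flagged `no_centering` skip diffraction centering
and collect at the current position (the serial-chip style of operation).

Per-step randomness derives from `(run_seed, row_index, step_index)`, so a
resumed step reproduces the original outcome bit-for-bit: resume replays the
already-successful steps of the failing row for their side effects under the
original seeds, then continues normally.  Record equivalence between a
resumed and an uninterrupted run is defined over timestamp-free record
signatures — wall-clock times legitimately differ.  Pause requests are
honored at step boundaries only.  Operator notifications are structured
journal events with a pluggable sink rather than any messaging integration.

The real three-party recovery design (acquisition service, GUI, replicated
database) collapses here to the single append-only journal: the same
recovery contract with no services, which is what makes the resume property
testable at every step boundary.

## Validation studies (`loopalign.evaluation`)

Problem sizes: 50 randomized scenes for optical-centering recovery
(noiseless, and with 1% multiplicative area noise), 1000 sinusoid triples
against a 0.1° grid-search oracle, 200 random grid geometries, 100 seeded
crystal scenes for best-spot recovery (crystal σ equal to the 0.05 mm beam),
100 decisions on a crystal-free scene, 100 seeds for the line-scan study,
all 25 interruption points of a 5-sample run, and 200 random spreadsheets.
These sizes keep the full suite around a minute and a half on one CPU while
leaving the binomial pass criteria well separated from their thresholds.

The line-scan study uses a thin loop (t = 0.06 mm, b = 0.25 mm), settling
σ = 1.5·t, a 0.02 mm beam, a 0.1 mm crystal and the weak threshold mode.
The thin loop and weak mode are the conditions under which the question is
meaningful: settling displaces the crystal in depth, which under the
3D-distance count model also depresses the 2D counts (the weakly-diffracting
scenario the mode exists for).  Under these conditions the full-ROI vertical
scan brackets the crystal in ≈99% of seeds while a thickness-restricted scan
succeeds in under half — the quantitative version of the argument for
scanning the whole ROI.

## What the simulator does not emulate

Photorealism (shadows, refraction, depth of field), real detector images
and on-image spot finding, motor backlash and vibration, real robot and
detector integrations, message brokers and databases, and ML-based
centering.  Passing tests therefore demonstrate the correctness of the
geometry, decision logic and state machine — not robustness to real-world
imaging artifacts such as frost, fibers, non-uniform illumination or
translucent loops, which is exactly the gap a deployment against real
cameras would need to close.
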