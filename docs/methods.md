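# Methods

This note documents the models, numerical choices and limitations behind
`insituplan`, in the order the workflow runs.

## Coordinate conventions

Right-handed frames, z up, millimetres everywhere; angles in radians inside
the library, degrees in user-facing settings and G-code words. Mesh face
indices are 0-based. Two named frames matter: the *planning* frame (the
pre-operative model, sphere centre of the synthetic phantom at the origin)
and the *robot* frame (arm base at the origin).

## Substrate meshes and vertical probing

Planning needs a single geometric query: the outermost upward-facing surface
under a vertical line. `surface_probe` answers it with a uniform 2D grid over
face bounding boxes and a barycentric point-in-triangle test in the xy
projection; among upward-facing hits the one with the largest z wins, because
deposition happens on the exposed outer (or, inside the defect, dural)
surface. Faces that are vertical in projection (signed xy area below 1e-12)
can never be hits and are excluded from the index — this is what makes the
recess wall of the phantom invisible to probes, as it should be.

Normals are per-face by default. Vertex-interpolated (area-weighted) normals
are available behind a flag and are markedly more accurate on smooth
surfaces: a chordal mesh's face normal deviates from the true surface normal
by O(edge/R) (several milliradians at print-relevant resolutions), while
interpolated normals cancel that error to O(edge²/R²) away from sharp
features. Near the recess wall the vertex stars are asymmetric and
interpolated normals degrade; accuracy assertions in the test-suite therefore
sample at least 1–2 mm inside the defect rim.

Mesh cleaning on load merges vertices within 1e-6 mm and drops faces below
1e-9 mm² — three orders of magnitude below any feature the 0.8 mm needle can
produce.

## Conformal (2.5D) slicing

The defect is assumed to have constant thickness, so the curved base layer is
simply repeated in height: layer *i* places each planned 2D point at
`z_surface(x, y) + i * layer_thickness`. The vertical (+z) offset was chosen
over an offset along the surface normal: normal offsets self-intersect on
concave regions, and the vertical-extruder deposition mode stacks material
vertically anyway. The consequence — bead spacing compresses by cos(slope) on
steep walls — is accepted and documented.

Per layer the pattern is `n_perimeters` inward offsets of the footprint
boundary (perimeter *k* at depth (k+½)·extrusion width, round joins) followed
by rectilinear infill: parallel lines at `infill_angle + (i−1)·alternate_angle`
(defaults 45° and 90°, giving the orthogonal fibre alternation that creates
interconnected porosity), placed at offsets `ymin + spacing/2 + k·spacing` in
the rotated frame so output is deterministic, clipped to the footprint, and
serpentine-connected whenever the join gap is at most twice the line spacing
(longer gaps become travel moves). Line spacing is
`extrusion_width / infill_density` — the standard rectilinear identity, which
also explains the practice of doubling the extruder width in a slicer that
cannot set top-layer density directly: a 1.6 mm width over a 0.8 mm needle at
3.2 mm spacing yields 50 % coverage. Infill is clipped to the full footprint
(not to the region inside the perimeters), keeping the covered-area fraction
equal to the nominal density; the slight overlap with the single perimeter is
accepted.

Polylines are resampled to ≤1 mm pose spacing (≈0.33 s of travel at the
3 mm/s print speed; far below the ~80 mm curvature radius of a skull). The
infill clipping region is pulled 0.01 mm inside the footprint so that line
endpoints never sit exactly on the chordal boundary of the probed patch —
negligible against the bead width, but it removes a probe-miss ambiguity that
is purely an artefact of triangulation.

The 45° slope rule (`assign_orientation`) is a hard switch: above the
threshold the tool axis is the outward surface normal (deposition
perpendicular to the surface), at or below it the axis is vertical. The
switch is exactly a step function of the *probed* slope, which is what the
tests assert.

## Registration

`estimate_rigid` is the closed-form least-squares (Kabsch/SVD) solution with
the determinant correction, so the result is a proper rotation even for
coplanar fiducials whose unconstrained optimum would be a reflection.
Correspondence is strictly by label; no automatic matching is attempted
(markers are identified manually in both frames in practice). Three
non-collinear fiducials are the mathematical minimum; the collinearity check
requires the second singular value of the centred coordinates to exceed
1e-6 mm (rank ≥ 2 — coplanar sets are explicitly allowed, only collinear ones
are degenerate). The CLI warns below five markers, since redundancy is cheap
insurance against markers lost during the intervention.

FRE is reported simultaneously as mean, RMS and max of the post-fit
residuals, because a single "least-squares error" figure is ambiguous between
the first two; downstream consumers must name the statistic they quote.

## Kinematics

The arm model is five revolute joints in series; each joint contributes a
rotation about a fixed axis in its parent frame followed by a fixed link
transform. The packaged chain (`data/imagobot.toml`) has MOVEO-like
proportions — base yaw about z at 231.5 mm, two 221 mm pitch links, a 60 mm
wrist pitch, a wrist roll, and a 90 mm tool drop (~730 mm reach) — and is an
editable convention, not a measurement of any physical arm.

Forward kinematics composes Rodrigues rotations; a vectorised batch version
handles encoder logs. Inverse kinematics solves the 5-dimensional task (tip
position + tool-axis direction) by damped least squares on a finite-difference
Jacobian with Levenberg-Marquardt-style adaptive damping (initial μ = 0.01,
×8 on a rejected step, ×0.5 on an accepted one), warm-started from the seed
state, joint limits enforced by clamping. Position and axis errors are
combined with a 100 mm weighting length, so 1 mrad of axis error counts like
0.1 mm of position error. Convergence requires 1e-4 mm / 1e-5 rad — an order
tighter than the 1e-3 contract. Because this chain's geometry decouples (the
tool axis azimuth is tied to the arm plane), closed-form yaw/elbow candidates
are tried after the warm start, then up to five random restarts drawn from a
seeded generator; non-convergence raises an error carrying the best residual,
never a silent bad pose. Spin about the tool axis is never constrained —
that is precisely the missing sixth degree of freedom.

One consequence of the yaw + planar-arm layout: a tool axis tilted out of the
arm's vertical plane is unreachable. A noisy registration tilts the mapped
frame by a few milliradians, so executed programs re-assert the vertical tool
axis in the robot frame (`with_vertical_axes`), exactly as a vertical-mode
controller would.

## G-code and encoder logs

Only the G0/G1 subset is interpreted (mm mode, absolute coordinates, modal
words); `G92 E0` resets the extrusion reference, unknown commands are skipped
with a warning. Extrusion is pneumatic (pressure-driven syringe), hence
on/off semantics: the writer brackets extruding runs with an M-code pair
(M8/M9 by default) instead of emitting filament lengths, and the parser
treats that pair as a modal extrusion flag. All numbers are written with
fixed 3 decimals (6 for joint words), making files bit-reproducible and
bounding the write→parse position error by 5e-4 mm per coordinate.

The top-layer filter segments a file into layers at travel-move z jumps and
discards layers whose extrude moves span ≤1e-3 mm in z — automating the
manual deletion of planar-perimeter paths from slicer output. The 1e-3 mm
planarity tolerance sits 600× below the layer step, so false merges are not
possible at these settings.

## Evaluation

The executed trajectory is one forward-kinematics tip point per encoder
record. Pairing is `by_line` by default (the controller records one sample
per G-code line, so index pairing is exact); `nearest` (KD-tree) is provided
for logs without line correspondence and is never larger by construction.
Travel moves are excluded from the statistic by default — only deposited
material matters — with a flag to include them. The reported spread is the
population standard deviation (divide by n).

## The synthetic phantom

The phantom is an analytic spherical cap rather than a segmented skull so
that every geometric claim has a closed form: sphere radius 80 mm, cap height
55 mm, a circular defect footprint of 70 mm diameter centred 30° from the
apex (planar area ≈ 38.5 cm², curved area larger), floor recessed vertically
by the 6 mm constant skull thickness, six fiducial markers on the outer
sphere ringed around the defect (nominal 45 mm geodesic radius, pushed at
least 2 mm clear of the footprint where the rim reaches further). With a
70 mm defect centred 30° off-apex, a 50 mm cap would clip the footprint rim
by under a millimetre, so the default cap height is 55 mm; all other defaults
follow the case-study magnitudes. Construction is fully deterministic.

The triangulation is curvature-adaptive: ring spacing follows
`sqrt(8·tol·R·cos³θ)` (the radial second derivative of the sphere height is
1/(R cos³θ)) and the azimuth count follows the tangential curvature at the
steepest rim point, with a vertical chordal tolerance of 3e-4 mm. Linear
interpolation over the mesh then reproduces the analytic height to well under
1e-3 mm everywhere in the defect — including the ~70° slopes at the far rim —
at a cost of ~350 k faces. Tests that do not assert sub-millimetre geometry
use a relaxed tolerance (5e-3 mm) for speed.

Noise models are i.i.d. Gaussian and seeded: isotropic position noise on the
probed fiducials, per-joint angle noise on the encoder records. What the
phantom deliberately does **not** model: bone fragments and fracture lines,
scanner voids, arm compliance/backlash (no data to calibrate them),
deposition physics and bead geometry, or biology. Passing the synthetic
end-to-end loop therefore demonstrates that the geometry, frames and
conventions compose correctly and how errors propagate — not that a physical
print will achieve these numbers.

## Problem sizes in the shipped checks

The acceptance script and test-suite run the default conditions end to end:
the full 10-layer, ~16,600-pose toolpath for slicing, registration and IK;
200 random transforms (exact recovery) and 2,000 noisy replicates
(Monte-Carlo FRE) for registration; 500 random joint states for the IK
round-trip rate; 10 seeded replicates per encoder-noise level
(σ ∈ {0, 1e-4, 1e-3, 1e-2} rad) for the error-monotonicity check. These sizes
keep a full run under a minute while leaving the Monte-Carlo standard errors
far below the asserted tolerances.

## Known limitations

- Constant-thickness (2.5D) reconstruction only; hybrid planar/non-planar
  slicing of variable-thickness defects is out of scope.
- Vertical projection, not arc-length-preserving surface mapping: fibre
  spacing compresses on steep slopes.
- The kinematic fixture is a plausible stand-in; no fidelity is claimed to
  any physical arm's dimensions or controller.
- Probe misses raise errors; hole-filling of real scan voids is upstream.
- Rheology metadata (e.g. Herschel-Bulkley parameters) is carried as inert
  configuration and never computed upon.
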