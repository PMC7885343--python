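# Methods

This note documents the models, numerical choices and limitations behind
`hemomap`, in the order the pipeline runs.

## Data model and units

All volumes live on regular axis-aligned grids with `world = origin +
index * spacing` in millimetres; oblique acquisitions are assumed resampled
upstream. Velocity is stored in cm/s (the VENC convention) and converted to
SI only inside the WSS and vorticity kernels, so outputs are in Pa and 1/s
without unit juggling at call sites. A `VelocityField4D` is a
`(nx, ny, nz, nt, 3)` array; vector maps restricted to the lumen carry an
explicit boolean support grid rather than sentinel values.

## Preprocessing

**Background phase correction.** Velocity offsets from eddy currents vary
approximately linearly in space. For each component a first-order
polynomial `a + bx + cy + dz` is least-squares fitted to the *time-averaged*
component over stationary-tissue voxels and subtracted from all frames.
Fitting to the time average (rather than per frame) is the default because
the offset is static by construction; a per-frame mode and a second-order
fit exist behind flags. When no stationary mask is supplied, one is derived
as the voxels whose temporal speed standard deviation is below the 20th
percentile (intersected with a magnitude floor at the 25th percentile when
a magnitude image is available). Correction is skipped, with a warning and
absent coefficients, below 100 static voxels — a plane fitted to fewer is
dominated by noise.

**PC-MRA** is the cycle-average of magnitude × speed. **Peak systole** is
the frame with the highest segmentation-averaged speed, ties broken toward
the earliest frame (ties only arise in degenerate synthetic inputs). All
downstream analysis uses this single frame.

## Wall geometry

The wall mesh is the 0.5-level marching-cubes isosurface of the binary
mask, lightly Gaussian pre-smoothed (σ = 0.5 voxel) to suppress the
staircase area bias of binary isosurfaces — with it, a digitized 20 mm
sphere at 1 mm spacing meshes to within ~5% of 4πr². The mask is padded
before meshing so surfaces touching the grid edge still close; non-watertight
results are rejected rather than repaired. Laplacian smoothing is the
uniform-weight 1-ring update `v ← v + λ(mean(neighbors) − v)`, default
λ = 0.5 for 10 iterations (the classical mild setting; both configurable);
smoothing shrinks convex shapes by construction, measured at < 10% volume
on the sphere phantom. The smoothed mesh is used throughout (flag to
disable).

Per-vertex area is one third of the incident face areas, so vertex areas
sum exactly to the mesh area. Inward normals are area-weighted vertex
normals, globally oriented by a majority probe into the mask. The **local
lumen radius** at a vertex is half the chord length marched along the
inward normal (step = spacing/4) until the ray exits the lumen; where the
ray leaves the grid first, the Euclidean distance transform at the nearest
interior voxel is used, and where both fail the vertex is excluded from
WSS. The march is capped at a few inscribed diameters to bound memory on
fine grids.

## Wall shear stress

At each vertex, velocity is trilinearly sampled at `r/2` and `r` along the
inward normal, both samples are projected onto the tangent plane (WSS is
tangential by definition), and the wall gradient is taken from the unique
quadratic through `(0, 0)`, `(r/2, v1)`, `(r, v2)`:

    WSS = mu * (4 v1_t - v2_t) / r

With three points and a pinned zero at the wall, a natural cubic and the
quadratic agree in their wall derivative, so the quadratic is the canonical
form of this spline estimator. Applying the formula to the projected
*vectors* makes the result independent of any tangent-basis choice. The
estimator is exact on profiles quadratic along the normal — in particular
Poiseuille flow, where samples at r/2 and r make the wall gradient
independent of radius estimation error. μ defaults to 3.2 cP. Samples
falling outside the velocity grid mark the vertex absent; samples outside
the lumen but inside the grid interpolate against zero-filled voxels and
bias low — accepted and documented rather than masked, since near-wall
voxels are exactly where data exist. On the voxelized Poiseuille tube the
mean |WSS| error is ~8% at 2.5 mm, ~2% at 1.25 mm, ~0.4% at 0.625 mm
(lateral wall, end caps excluded; caps have no analytic counterpart).

## Vorticity and LNH

Vorticity is curl V with the fourth-order central stencil
`(-f(+2h) + 8f(+h) - 8f(-h) + f(-2h)) / 12h` — algebraically the
Richardson extrapolation of central differences — wherever all four
neighbours lie in the support, degrading to second-order central where only
±1 exist, and flagged invalid otherwise. The flags let callers (and tests)
restrict to full-stencil voxels; measured convergence order on smooth
fields is ~4. LNH is the cosine of the angle between V and ω, clamped to
[−1, 1]; it is undefined below 1e−6 × VENC speed or 1e−6 1/s vorticity.
Regional summaries are the volume of |LNH| > 0.6 and the mean |ω| per
region (a volume-integral variant exists behind a flag; the mean keeps 1/s
units). LNH/vorticity are computed at peak systole, consistent with the
rest of the pipeline.

## Atlas construction and mapping

Registration of binary lumen masks is intensity-based on their signed
Euclidean distance maps (SimpleITK, correlation metric, 3-level
multi-resolution, dense sampling, regular-step gradient descent). Two
choices matter. *Correlation, not mean squares*: under a scaling transform
the distance-map values scale with the object, so a mean-squares optimum is
biased away from true alignment, while correlation is invariant to linear
intensity scaling — on a 1.2× scaled phantom it recovers det = 1.728
essentially exactly. *Dense sampling*: no random metric sampling, so
registration is deterministic. A Dice sanity check rejects results that
degrade overlap, falling back to the identity with a warning.

The **shared geometry** takes the cohort member with median lumen volume as
reference, rigidly co-registers the rest, and keeps the largest connected
component of the voxels covered by a majority of members (more than half;
for N = 2 this means both — so cohorts that cannot be aligned are rejected
rather than degenerating to a single subject's mask).

Each subject is then affinely registered to the shared geometry. Vector
fields are transported by the **rotation part only** — locations move with
the full affine, vectors are rotated but never scaled, so speeds and WSS
magnitudes are preserved (checked to 1e−9). The rotation is extracted from
the linear part L by polar decomposition (default), which is a true
rotation for any positive-determinant L; a `paper_literal` mode divides L
by the isotropic scale s = det(L)^(1/3), exact for similarities and
non-orthogonal in the presence of shear (an affine registration between
same-modality anatomies is near-similarity, so the two modes agree in
practice). Reflections (det ≤ 0) are rejected.

Atlas values are nearest-neighbour interpolated — deliberately not
trilinear, to avoid blending across the thin lumen — and averaged
componentwise with a per-location contributor count; locations with no
contributor are excluded downstream. Mapping the atlas onto a subject
reverses the machinery (affine shared→subject, rotation-only transport,
nearest-neighbour), with a warning below 80% lumen coverage.

## Deviation maps and quantification

θ = arccos of the clamped normalized dot product; undefined where either
vector is below 1e−6 × VENC. Categories use half-open intervals [0°, 60°),
[60°, 120°), [120°, 180°] so the partition is total and testable; undefined
locations are excluded from numerator and denominator alike. Regions are
cut by user-supplied landmark planes (point + distally-oriented normal):
ascending aorta between the sinotubular-junction and brachiocephalic
planes, split into inner/outer halves by a configured axis through the
ascending centroid; proximal descending aorta between the left-subclavian
and pulmonary-artery planes. Landmarks are explicit configuration, not
auto-detected — reproducibility over anatomy detection. Quantification is
count × voxel volume (cm³) for voxels and summed vertex areas (cm²) for
the wall; the ascending total is the exact sum of its halves. Ensemble
incidence is 100 × flagged/n per location and category, computed separately
for the yellow and red categories.

## The phantom: what it does and does not emulate

The generator provides ground truth the real study cannot: a U-shaped
lumen (half-torus arch of radius `arch_radius` joined to a straight
descending limb) at 2.5 mm isotropic spacing with 24 cardiac frames —
matching the acquisition geometry the pipeline expects — carrying
axial Poiseuille flow v_peak(1 − r²/R²) (default v_peak = 100 cm/s, a
normal aortic peak systolic velocity), optional solid-body azimuthal swirl,
optional reversed-flow patches of closed-form volume πR² × extent, a
raised-cosine systolic waveform peaking uniquely at frame 7, and i.i.d.
Gaussian velocity noise per component (the simplest model consistent with
velocity-encoded phase noise). Because the tube ends are defined by
perpendicular-distance clamping, the lumen volume has the exact closed form
πR²(πR_arch + L). The axisymmetric axial field is divergence-free in the
continuum (on the arch as well as the limb), so the discrete divergence in
the tube core converges to zero with spacing.

Cohorts are produced by drawing similarity transforms (bounded rotation,
isotropic scale, translation) and evaluating the analytic field through the
inverse map, rotating vectors only — no resampling error, and the true
affines are returned for recovery tests. Default landmark planes sit at 25°
and 55° along the arch and 15–55 mm down the limb; the 30° ascending window
keeps the single-plane inner/outer split close to the exact
torus-center-distance rule (a wider window bows away from any single
plane, and the voxel centroid of a torus segment sits ~R²/4R_arch outside
the centerline, both of which erode the agreement).

What the phantom does **not** emulate: valve jets, turbulence,
CFD-realistic secondary flows, branch vessels, intensity/magnitude imaging
artifacts, or non-affine inter-subject shape variation. Passing tests
therefore demonstrate that the *machinery* (meshing, estimators,
registration, transport, quantification) is correct on fields with known
answers — not that clinical effect sizes are reproduced.

## Problem sizes and determinism

Tests and the acceptance script run the phantom at its native 2.5 mm
spacing (≈4,000 lumen voxels, ≈2,700 wall vertices), with refinement
studies at 1.25 and 0.625 mm on single-frame fields; these sizes resolve
every effect the oracles measure while keeping the whole suite fast. All
randomness flows from explicit integer seeds (`numpy.random.default_rng`);
registration uses dense sampling and is deterministic, so repeated runs
byte-reproduce all CSV/JSON outputs.

## Known limitations

- Time-resolved WSS and oscillatory shear index are out of scope: only the
  peak-systolic frame is analyzed.
- The WSS estimator's near-wall interpolation against zero-filled exterior
  voxels biases magnitudes low at coarse spacing (quantified above).
- `paper_literal` rotation extraction is not a rotation under shear; polar
  decomposition is the default for that reason.
- Nearest-neighbour atlas interpolation leaves single-voxel speckle at the
  lumen boundary when cohort geometry varies strongly; the majority-overlap
  shared mask bounds but does not eliminate this.
- No phase unwrapping: velocities beyond VENC alias upstream of this
  package.
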