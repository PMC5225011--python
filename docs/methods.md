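# Methods

`lumenwall` measures bowel wall thickness in contrast-enhanced MR
colonography volumes, where ingested contrast leaves the lumen dark and the
enhancing wall bright. The pipeline has three stages — stochastic lumen
tracking, centreline extraction, and cross-sectional wall labelling — plus a
synthetic phantom generator that supplies analytic ground truth for testing.
This note records the models, their assumptions, the parameters that matter,
and the numerical choices made where the design was open.

## 1. Particle-filter lumen tracking

The colon is treated as topologically cylindrical with a smoothly varying
elliptical cross-section. The tracker state is 15-dimensional: centre
`c` (mm), a 3x3 reference frame `R = [r s t]` with tangent `t`, and ellipse
parameters `(a, b, phi)` (semi-axes in mm, in-plane orientation). A cloud of
`Ns` such states evolves by sequential importance resampling:

- **Prediction.** `c' = c + t + eps_c`, `eps_c ~ N(0, sigma_c^2 I)`; ellipse
  parameters receive independent Gaussian noise and are clamped to
  `a >= b >= min_axis`. The frame is perturbed by drawing a direction about
  the pole — azimuth uniform on (0, 2pi), off-pole angle `N(0, sigma_psi^2)`
  — and rotating `R` by the single double-reflection rotation-minimising
  step that carries (0,0,1) onto that direction. This keeps the frame
  orthonormal by construction and adds no spurious twist.
- **Measurement.** `H` rays leave the centre through equally spaced ellipse
  boundary points. Each ray is marched at a quarter of the smallest voxel;
  the first sample whose intensity exceeds the current wall threshold `k`
  is that ray's wall detection. The cost of a state is the mean squared
  radial distance `F` between detections and the predicted ellipse over
  detected rays, scaled so that missing rays (fraction `1 - Omega`) and
  detections inside the `eta`-scaled inner ellipse (fraction `Upsilon`,
  evidence the ellipse has crossed the wall) strictly increase it:
  `d = F (1 + lambda_Y * Upsilon) / max(Omega, eps)`. The literal printed
  product form `F (1 - Upsilon) Omega` decreases with missing detections,
  contradicting its role as a cost; it is kept behind
  `TrackerConfig.literal_cost` for comparison.
- **Weighting.** `q_i ∝ q_i^prev exp(-W d_i)`, renormalised. With `W=None`
  (default) the sharpness is auto-calibrated on the first iteration so that
  the median cost maps to unit exponent; the value used is recorded in the
  run report.
- **Termination and resampling.** The effective sample size
  `ESS = 1 / sum q_i^2` is evaluated on the pre-resampling weights; the
  track stops when `ESS < ess_frac * Ns` (default 1%), which in practice
  fires at local collapse, bright intraluminal matter, or contrast loss.
  Otherwise systematic resampling (low-variance, multiplicities within
  floor/ceil of `Ns q_i`) resets the ensemble each iteration. An optional
  end point stops the track once the weighted mean centre comes within
  `end_tol_mm` of it.

**Dynamic threshold.** After each iteration, intensities are sampled 3 mm
outward (wall) and 3 mm inward (lumen) from every detected wall point of
every particle, along the centre-to-detection ray; 3 mm approximates a
bowel wall's depth. The threshold `k` maximises
`tau * #{wall > k} + (1 - tau) * #{lumen < k}` by linear search over the
sorted unique sampled intensities (an explicit candidate grid can be
supplied); ties resolve to the smallest candidate. The initial `k` comes
from the seed cross-section, taking the seed ellipse's own boundary points
as wall positions — the seed ellipse is fitted to the inner wall, so this
is consistent. Pooling detections across all particles (rather than one
reference contour) weights the estimate by detection multiplicity.

Defaults: `Ns=500`, `H=32`, `sigma_c=0.5 mm`, `sigma_e=(0.25, 0.25, 0.05)`,
`sigma_psi=0.15 rad`, `eta=0.5`, `tau=0.5`, `max_radius=25 mm`,
`step=1 mm`, `T_max=500`. The tests and the acceptance script use
`Ns=150` and phantoms of 40–80 mm so a full run takes seconds; tracking
accuracy on those phantoms is well under a voxel, so the reduced ensemble
loses nothing at desk scale.

## 2. Centreline extraction

Averaging particle centres per iteration fails where the ensemble splits
around folds, so the centreline is a geodesic instead. A speed field
`G(y) = sum_i q_i exp(-||y - x_i||^2 / h^2)` is accumulated over all
particle centres of all iterations (bandwidth `h = 3 mm`), evaluated
exactly at voxels within `4h` of any particle; farther voxels receive a
floor of 1e-12, which keeps the Eikonal problem defined everywhere while
making low-density regions effectively impassable. The exponent sign is
negative — a weighted Gaussian sum — and the truncation keeps the stated
1e-3 relative accuracy because discarded kernel terms are below 1e-6 of
each particle's weight.

Arrival times solve `G |grad T| = 1` by fast marching with second-order
one-sided upwind differences (first-order differences leave up to ~7%
diagonal metrication error on a 64-cube, violating the 5% accuracy target;
second order brings the maximum below 3.5%). The point-source singularity
is removed by seeding exact arrival times inside a three-voxel ball around
the start — standard source factoring. The centreline is the steepest
descent of trilinearly interpolated `T` from the end point, in quarter-voxel
steps, terminating within one grid-cell travel time of the start; when the
sub-voxel line search stalls on a knife-edge ridge of `T` (possible next to
near-zero speed), the trace falls back to the best neighbouring grid node,
which preserves strict monotone descent. The path is resampled at uniform
arc length (default one voxel) and framed by the double-reflection
rotation-minimising sweep, so that the angular index of cross-sectional
sites is comparable between neighbouring frames.

Segments separated by a collapse are handled as separate runs with their
own seeds; there is no automatic re-seeding.

## 3. Wall localisation as MRF labelling

At 1 mm intervals along the centreline, the image is resampled on a radial
lattice: `n_angles=64` angles, radial labels `f` from 1 to 20 mm in
0.25 mm steps (distances from the frame centre). One site per
(frame, angle) takes a radial label; sites are connected to their angular
neighbours (wrapping) and to the same angle on adjacent frames.

**Inner wall node potentials.** `V = H1 * H2` where `H1` is the gradient
magnitude when the gradient direction lies within pi/4 of the outward ray
(the enhancing wall brightens outward at the luminal surface), otherwise
attenuated by `((dot + 1)/2)^2`; and `H2 = beta^c` with `c` the number of
supra-threshold ray samples closer to the centre than the label, not
counting the first contiguous bright run. `H2` is 1 for an unobstructed
ray and decays geometrically past extraneous bright structures (vessels,
an adjacent bowel loop), so labels beyond the true wall are suppressed
while labels within the wall's own bright run are not. A literal
cumulative form (`beta * c`) *rewards* labels beyond bright obstacles —
the opposite of its stated purpose — and is available behind
`WallConfig.literal_h2` only for comparison. The pi/4 window, not a bare
sign test, governs `H1` for the same reason: a bare positive dot product
admits gradients up to 90 degrees off-ray.

**Edge potentials.** `exp(-gamma |f_i - f_j|) * exp(-lam (1 - min/max)^2)`
over the two sites' distances and sampled intensities: maximal (=1) at
equal distance and equal intensity, symmetric, strictly decreasing in
distance difference (rate `gamma = 1 /mm`) and in relative intensity
dissimilarity (`lam = 4`). Two zero intensities count as perfectly similar.

**Inference.** Max-product belief propagation in the log domain: parallel
message updates, messages normalised to max zero, damping 0.5 for loopy
stability, up to 50 iterations or a 1e-8 message-change tolerance; each
site takes the label of maximum belief, ties resolving to the smallest
distance. BP is exact on acyclic graphs (verified against exhaustive
enumeration) and empirically attains the exhaustive maximum on these
ring-structured graphs whenever it converges. All potentials are floored
at 1e-12 so messages stay finite; a site whose node potentials are
entirely zero is an error (named in the exception) unless explicitly
flagged as resolvable through its edges.

**Outer wall.** The inner MAP contour per frame seeds outward rays along
its smoothed outward normals (angle-wise central differences over the
closed contour, averaged over three sites, oriented away from the centre).
Labels are distances from the inner point, 0.5–10 mm in 0.25 mm steps.
`H1` mirrors the inner term with the sign flipped — full weight when the
gradient points back toward the lumen, i.e. intensity decreasing outward
at the serosal surface. `H2 = kappa * F`, where `F` counts positions from
the first local minimum of gradient magnitude along the ray (0 before it,
1 at it, incrementing outward): candidate outer positions must lie beyond
the inner surface's own gradient peak. `kappa` only scales the potential
and cannot change any argmax; it is fixed at 1. Rays with no local
minimum carry zero potential and are flagged; their sites are resolved by
the edge terms. Edge potentials and inference are identical to the inner
stage. Thickness is the inner-to-outer distance per (frame, angle), which
equals the outer label.

Because `F` increases outward while the gradient profile around the outer
surface is nearly symmetric, the recovered thickness carries a small
outward bias of about one label step (+0.25 mm on noiseless phantoms).
This is a property of the potential form itself, is well inside the
half-millimetre recovery target, and is left uncorrected.

**ROI protocol.** An observer ROI point selects the measurement whose
inner-wall point is nearest; if none lies within 5 mm the algorithm is
recorded as having failed that ROI. Agreement is summarised by the mean
difference, the sample standard deviation (n-1), and 95% limits of
agreement `mean ± 1.96 SD` (the Bland–Altman convention).

## 4. Phantom generator

The generator voxelises a tube around a straight, torus-segment (constant
curvature) or helical axis: dark lumen inside a bright wall inside an
intermediate background (defaults 10 / 100 / 40 on an arbitrary scanner
scale), with the wall occupying `[r_in(s), r_in(s) + t(s)]` around the
axis. Both surfaces get one-voxel linear coverage ramps as an analytic
stand-in for partial-volume averaging, which is what makes sub-voxel
thickness recovery measurable on 1–2 mm grids. Degradations are applied
in order: haustral indentation (a sinusoidal narrowing of the lumen with
the wall following, so the thickness profile is preserved), collapse
(the lumen radius drops to zero over an interval, with a half-voxel taper;
a lumen narrower than a voxel fades out entirely), multiplicative linear
or quadratic bias, additive Gaussian noise (seeded). Ground truth — axis,
tangents, effective inner radius, thickness — is the construction input
and therefore exact.

Default spacing is 1 mm isotropic; the clinical 2 mm protocol is a
stress-test preset. What the phantom does *not* emulate: MR physics
(k-space sampling, coil profiles, Rician noise), faecal-matter texture,
adjacent organs, or genuinely elliptical/irregular cross-sections beyond
the haustral model. Passing phantom tests therefore demonstrates the
geometric and inferential machinery, not clinical performance; the
headline patient-level agreement statistics require real scans and
observers and are out of scope here.

## 5. Numerical choices and degenerate inputs

- World coordinates are mm, right-handed; voxel indices 0-based; the
  volume's direction matrix is honoured throughout. Trilinear sampling
  reproduces affine fields exactly; gradients come from central
  differences of a Gaussian-smoothed grid (default sigma half the
  smallest voxel) rotated into world axes. Out-of-bounds samples return
  NaN; the tracker reads that as "no wall detected", the MRF as zero
  potential.
- Ellipse fitting is the direct constrained least-squares conic method;
  degenerate (collinear) inputs raise. Fitted axes are ordered `a >= b`
  with `phi` wrapped to [0, pi).
- Duplicate consecutive centreline points are an error naming the index;
  `end == start` is rejected as degenerate before tracing.
- Parameters the source material leaves unspecified (`beta`, `gamma`,
  `lam`, `W`, `eta`, the noise sigmas, BP iteration count) carry the
  defaults above, chosen once on geometric grounds (`eta=0.5` places the
  inner ellipse halfway to the wall; `gamma=1/mm` lets the contour move
  one label step per site at cost e^-0.25; `beta=0.5` halves belief per
  obstructing voxel) and exposed in the configs.
- Reproducibility: one seeded `numpy` Generator threads through all
  stochastic steps; the seed, configuration and package versions are
  written next to every run's outputs, and measurement CSVs are
  byte-identical across reruns of the same configuration.

## 6. Known limitations

- Single-branch tracking only; collapses require manual re-seeding.
- The inter-frame MRF edges pair sites with equal angular index, relying
  on the rotation-minimising sweep to keep angular parametrisations of
  neighbouring frames aligned; strong torsion between frames would weaken
  that correspondence.
- The outer-wall run counter is unbounded outward, so in very low
  contrast the product with noise gradients can in principle favour
  distant labels; the continuity edges suppress this in the tested noise
  regime (sigma at 10% of wall contrast plus 20% bias).
- No per-measurement confidence estimate is produced.
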