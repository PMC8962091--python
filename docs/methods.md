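# Methods

## Physical model

Blood in the total cavopulmonary connection (TCPC) is treated as an
incompressible Newtonian fluid in laminar flow. Two energetic quantities are
computed from the measured velocity field **v**(x, t) within the vessel mask:

- kinetic energy, KE(t) = Σ_voxels ½ ρ |v|² V_voxel (reported in mJ), the
  energy of blood motion at each reconstructed cardiac phase;
- viscous energy loss rate, EL(t) = Σ_voxels μ Φ_v V_voxel (reported in mW),
  the rate at which kinetic energy is converted to heat by friction, with the
  Navier–Stokes dissipation function
  Φ_v = ½ Σ_ij (∂v_i/∂x_j + ∂v_j/∂x_i)² − ⅔ (∇·v)².

The cycle average is the unweighted mean over phases: retrospective ECG
gating reconstructs phases of equal duration. Cycle-averaged values are
normalized by total venous inflow (caval + conduit, L/min) for the complete
connection, and by segment-specific inflow × included centerline length (cm)
for branch segments, so that partially imaged segments remain comparable;
the central confluence has no meaningful length and is normalized by flow
only.

Material constants default to ρ = 1060 kg/m³ and μ = 3.2 mPa·s, standard
values for adult whole blood; both are configurable (`EnergeticsConfig`).
The −⅔(∇·v)² compressibility correction is included by default because
measured phase-contrast fields are never exactly divergence-free; it is
identically zero on the analytic phantoms. Any negative per-voxel Φ_v it
produces (possible only through that term) is clipped to zero and counted.

## Numerics

Velocity gradients use central differences where both axis-neighbors lie in
the mask and one-sided differences at mask boundaries (`boundary_scheme =
"one_sided"`; `"interior_only"` is available as the conservative bracket).
Dropping boundary voxels systematically misses wall-shear-dominated
dissipation, which is why one-sided differences are the default; on the
0.5 mm Poiseuille reference phantom the two schemes bracket the closed form
and the one-sided result is within 3 %. Central differences are exact for
the parabolic profile, so the residual error is boundary discretization;
it decreases monotonically over 2 → 1 → 0.5 mm grids.

Voxels with no in-mask neighbor along an axis contribute zero gradient along
that axis and are counted in the log.

## Anti-aliasing (VENC unwrapping)

Velocities beyond ±VENC wrap by multiples of 2·VENC. Each component/phase
volume is mapped to a phase image (±VENC ↔ ±π) and unwrapped with the 3D
Herraez algorithm, anchored so that the majority of voxels (static
background) keep their values; every applied shift is an exact multiple of
2·VENC, so noise is untouched. A purely local neighborhood-median detector
cannot flag contiguous wrapped cores — every neighbor of a wrapped voxel in
the core is wrapped too — which is why a global unwrap is the primary step.
A verification pass with the 6-neighborhood-median test then repeats until
nothing is flagged, making the operation idempotent. On phantoms wrapped at
1.2·VENC the corrected field equals the generator's pre-wrap field to
machine precision.

## Segmentation and geometry

The lumen is segmented on the magnitude-weighted, phase-averaged speed image
by threshold + seeded 26-connected components, followed by a 1-voxel
morphological closing and hole filling. The default threshold is 10 % of the
99th-percentile speed. Anatomical extent and artefact exclusion are
expressed as oriented cut planes in world mm.

Centerlines are medial geodesics: shortest paths through the lumen voxel
graph whose edge costs are the physical step length divided by
(local distance-to-wall + ½)², so paths run along the distance-transform
ridge. (3D thinning was rejected: the available implementation deletes
entire objects whose medial axis falls between voxel centers.) The junction
is the geodesic 1-median of the seed geodesics; branches run junction →
seed, are smoothed with a short moving average, and are extended to the seed
position to recover end erosion. On a straight tube the recovered length is
exact to within 2 voxels and every node lies within 1 voxel of the analytic
axis.

Segments follow the five-segment convention (Fontan tunnel, SVC, LPA, RPA,
central confluence). Every mask voxel takes the branch of its nearest
centerline point; voxels whose nearest point lies within the confluence
margin of the junction form the confluence. The margin defaults to the local
mean vessel radius around the junction — the anatomy does not define a sharp
boundary, and a radius-scaled margin is reproducible across patient sizes.
Segments with less than 1.5 cm of included centerline are flagged excluded
(too few voxels for stable energetics).

Cross-sectional areas are sampled every 1 mm along each branch on planes
perpendicular to the local tangent, by nearest-neighbor resampling of the
mask at 0.25 mm in-plane resolution; the CSA is the in-plane connected
component containing the centerline point, reported in cm² and per m² of
body surface area (Haycock: 0.024265 · weight^0.5378 · height^0.3964).
Through-plane flow integrates v·n̂ over in-plane points inside the mask with
mask-weighted (normalized) linear interpolation, which removes the
partial-volume bias of interpolating across the wall; flow planes sit 5 mm
outside the confluence margin, normal to the centerline, signed positive
toward the junction for inflow branches.

## Synthetic phantoms

Phantoms provide analytic ground truth: parabolic (Poiseuille) profiles in
straight, tilted and disjoint tubes and in a four-branch cavopulmonary
junction, scaled per phase by a nonnegative waveform with mean 1 (default: a
raised cosine with peak/mean 2, emulating venous pulsatility; a single phase
gives steady flow). Per straight branch the closed forms are
KE = ⅔ ρQ²L/(πR²) and EL = 8μLQ²/(πR⁴); both were verified independently by
radial quadrature of the defining integrals (see `tests/test_synthetic.py`).
The junction interior is blended by distance-weighted interpolation of the
branch profiles and is explicitly non-physical (no Navier–Stokes solve):
closed-form comparisons are restricted to straight-branch regions, while
mass conservation at planes outside the junction holds by construction.

Defaults describe the imaging regime the package targets: VENC 80 cm/s, 24
phases per cycle, 1 mm isotropic spacing, total venous inflow 3 L/min split
70/30 between conduit and SVC and 45/55 between LPA and RPA, branch radii
9/7/6/7 mm (tunnel/SVC/LPA/RPA). Noise (additive Gaussian, all components)
and VENC wrapping are opt-in corruptions applied after the analytic field is
frozen — corruption order is fixed (field → noise → wrap) and the
pre-corruption fields are returned as oracles. What the phantoms do **not**
emulate: MR signal formation (k-space, eddy currents, background phase
offsets), secondary/vortical junction flow, respiratory modulation, and
wall motion. Passing phantom tests therefore demonstrates correctness of
the discrete operators and pipeline plumbing, not robustness to every
in-vivo artefact.

The synthetic cohort is multivariate normal over seven per-patient
variables (normalized KE and EL, liver cT1, peak VO₂ absolute and
% predicted, cardiac index, ejection fraction) with published summary means,
SDs and pairwise correlations; the cells not published (KE–EL, cT1–VO₂,
VO₂–%predicted, CI–EF) are fixed plausible constructions chosen once to
keep the matrix positive definite, and are documented in
`synthetic.COHORT_CORRELATION`. Gaussianity is an idealization — real
cohort variables are bounded and skewed; values are deliberately not
truncated, and the generator is a calibration target for the statistics
layer, not a patient simulator.

## Statistics

Presentation (mean ± SD vs median/IQR) follows Shapiro–Wilk at α = 0.05.
Correlation defaults to automatic selection: Pearson when both variables
pass Shapiro–Wilk, Spearman otherwise, with explicit override; strength
bands are weak 0.3–0.5, moderate 0.5–0.7 (0.5 itself is moderate), strong
0.7–0.9, excellent > 0.9. Spearman p is exact (full rank-permutation
enumeration) for n ≤ 9. Segment comparison uses Kruskal–Wallis with tie
correction — Monte-Carlo permutation of H (10 000 seeded resamples) when any
group has n ≤ 5, the χ² asymptotic otherwise — and pairwise two-sided
Mann–Whitney U with Bonferroni adjustment (p × number of pairs, capped at
1). Mann–Whitney was chosen over Dunn's test as the most common reading of
"Kruskal–Wallis adjusted by Bonferroni". Two-group differences select
Welch's t or Mann–Whitney by per-group normality. All tests are two-sided
at α = 0.05; every report carries its n.

## Problem sizes and reproducibility

Validation uses 0.5 mm grids (~160 k lumen voxels) for the Poiseuille
energetics oracles and 1 mm grids for geometry, junction and pulsatility
checks; statistical calibration uses 2 000 replicates at n = 28 and cohort
recovery n = 100 000 — sizes at which every oracle tolerance is resolved
comfortably. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); pipeline CSV outputs use fixed number
formatting and are byte-reproducible for a given config + seed, with the
config SHA-256 echoed into the run directory.

## Known limitations

- Spatial resolution bounds the recoverable dissipation: EL is a lower bound
  that sharpens with grid refinement (the convergence test quantifies this).
- No background phase-offset or eddy-current correction is implemented;
  fields are assumed preconditioned apart from VENC aliasing.
- The junction blend is not a flow solution; junction-region energetics on
  phantoms are plumbing checks only.
- The cohort generator reproduces first and second moments, not the joint
  distribution of a real population.
- Segment labeling near the confluence boundary is margin-dependent;
  agreement with generator labels is ≥ 96 % at default settings but the
  margin is a convention, not an anatomical fact.
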