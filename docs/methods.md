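# Methods

`mitolens` reimplements, as a tested pipeline on synthetic geometry, the
computational demonstration that the tightly packed mitochondria of cone
photoreceptor inner segments (IS) act as a microlens: they concentrate
incident light onto the outer-segment region (OSR) and give light delivery a
Stiles-Crawford-like angular dependence.  The pipeline is: synthetic
cone/mitochondria geometry → dielectric-grid conversion → FDTD light
propagation → concentration/focal/OSR metrics → directionality (ρ) fitting →
skeleton alignment morphometry → cohort bootstrap statistics.

## Synthetic geometry

The original study ran on manually segmented electron-microscopy
reconstructions of ground-squirrel cones, which are not publicly deposited.
Everything here therefore runs on generated geometry whose *statistical*
properties emulate those reconstructions; conclusions are checked as
orderings and calibrated properties, not as numeric reproduction of the
reconstruction-specific values.

**Envelope.** The IS envelope is a solid of revolution: an ellipse-arc
generatrix, cylindrical below the widest point ("bulge") and tapering to an
apex at the distal tip.  The reference 3D cone is 8 µm long and 4.0 µm in
maximum diameter with the bulge at half height — deliberately slim, because
in real cones the mitochondrial bundle fills the ellipsoid nearly
wall-to-wall and only a thin cytoplasmic sheath separates it from the plasma
membrane.  (During design we found this matters optically: with a thick
sheath the envelope contributes a large collecting aperture of its own and
the mitochondria-only condition is artificially weak.)  The 2D reference
cone is full scale (10 µm × 7 µm, distal tip at z = 25 µm as in the standard
simulation layout) with a rounder taper (widest point a quarter of the way
up) and a single planar row of thin chains, so its central XZ slice — the 2D
simulation plane — cuts through every mitochondrion.

**Mitochondria.** Each mitochondrion is a watertight tube mesh swept along a
segmented polyline ("chain").  Chains stand on a hexagonal lattice of lateral
sites confined to the distal 70% of the envelope (the ellipsoid region);
interior sites carry the full tube radius, edge sites shrink to fit, and tube
radii taper where the envelope tapers, as real mitochondria conform to the
wall.  Each segment's polar angle is an independent von Mises–Fisher (vMF)
draw about the cone axis, so the *branch-angle law of the skeletons is
exactly vMF*; only the azimuths are steered, keeping each chain inside a
small wobble band (±0.02 µm) around its site.  A final common radius rescale
hits the target bundle volume to <1%.  We chose this construction over
independently placed capsules after finding that rejection-sampled capsule
packings saturate far below volume-matched bundle densities; random
sequential packing cannot reach dense, aligned configurations.

vMF concentrations are calibrated analytically: κ = ln 4 / (1 − cos 15°) ≈
40.7 puts 75% of branch draws within 15° of the axis (active-like bundle),
and κ ≈ 10.5 puts 30% within 15° (hibernating-like).  The hibernating preset
also scales total bundle volume by 0.70 and uses shorter segments in a 5x
wider wobble band (0.10 µm) — the distortion is bundle-scale, not just
segment-scale.
Volume-matched alternatives: near-spherical bodies on an HCP lattice
(adaptively shrunk at the wall) and a single "megamitochondrion" (a radially
shrunk copy of the envelope profile).  `n_mito` is exact for spheres/mega
and acts as a cap for chain bundles, where the lattice decides how many fit.
All bodies keep ≥20 nm clearance from each other and the envelope wall.

Defaults treated as modeling assumptions, not ground truth: bundle = 26% of
the reference envelope volume (≈47% of the ellipsoid zone — the packing
ceiling of clearance-respecting tubes; real bundles are denser still),
segment length 0.8 µm (0.5 µm disordered), chain radius ≈ 0.3–0.5 µm.

**Cohorts.** Two-group OSR-concentration cohorts mirror the imaging
experiment's structure: 4 animals per condition, 15 cones per animal, group
means 4.44 vs 3.65, an animal-level random effect (SD 0.25) plus cone-level
noise (SD 1.2, chosen so the total spread matches the reported ≈1.0–1.25
group SDs; the between/within split is not identifiable from the published
summary and is our assumption).

## Dielectric conversion

Meshes are voxelized by slab-decomposed point-in-polygon parity counting at
**double** the simulation resolution (matching the half-step Yee offsets);
2×2×2 fine-point blocks give per-voxel volumetric fill fractions.  Bulk
voxels take ε_r = n² exactly, from the index table n = 1.34 (extracellular),
1.36 (cytoplasm), 1.40 (mitochondrion), 1.46 (membrane).  Voxels straddling
a surface become interface records (normal, fill fraction, membrane
fraction); the 10-nm membranes — far thinner than any voxel — enter purely
through these records.  The effective permittivity tensor of an interface
voxel is the fill-weighted harmonic mean along the surface normal and the
arithmetic mean tangentially (the standard effective-medium rule behind
subpixel smoothing); the Yee update uses its diagonal projection, dropping
the off-diagonal coupling (exact for axis-aligned interfaces, a small
controlled error otherwise).  Interface normals come from the smoothed
fine-grid occupancy gradient rather than per-triangle lookups — exact for
axis-aligned faces and accurate to a few degrees on curved surfaces, which
is all the averaging needs.

Optional cristae substitute the uniform mitochondrial interior with three
compartments from a random isotropic cosine-sum field f: matrix (f > 0),
intramembrane space (f < 0), internal membrane (|f|/‖∇f‖ < 5 nm).  Where
‖∇f‖ = 0 inside the band the sign of f decides (a measure-zero set).

Ablations re-skin material labels from the stored fills without
re-voxelizing: `no_mitochondria` turns mitochondrial voxels into cytoplasm
(membranes dropped); `mitochondria_only` strips the envelope, leaving
mitochondria + membranes in extracellular medium.  `extend_base` tiles the
proximal-most occupied layer down to z = 0 so the model continues
homogeneously below, and the source plane sits inside that repeated base.

## FDTD engine

Maxwell's curl equations are leapfrogged on a Yee lattice in natural units
(length unit 1 µm, time unit 1 µm/c₀, ε₀ = µ₀ = 1); 50 time units correspond
to 166.78 fs.  Light is a soft additive current source on a full-width
plane, CW at 450 nm with a 3-cycle smooth turn-on, Ex-polarized in 3D;
the 2D XZ mode propagates the out-of-plane E component (cylindrical-lens-like
focusing — used for fast oracles and sweeps, with 3D for headline
properties).  Boundaries are polynomial-graded convolutional PML, 1 µm
thick (measured pulse reflection < 10⁻⁴ in power); the 2D mode can be
periodic in x, which reduces exactly to 1D for layered media (used for the
Fresnel oracle).  Courant factor 0.5.  The exported energy density
u = (ε|E|² + |H|²)/2 is averaged over the final optical cycles, with the
window extended to the whole-time-step-aligned multiple of the period (up to
four cycles): a window misaligned by a fractional step — e.g. 22.5 steps per
period — leaves a ~2% standing ripple in the average.  The averaging window
at export is our choice; an instantaneous export would carry a ripple at 2ω.  Runs are fixed-duration (no convergence
detection) and bit-deterministic.

Problem sizes: the 3D reference condition is a 6.5 × 6.5 × 20 µm lattice at
16 voxels/µm (tip at z = 11 µm, source at 2 µm, duration 34 time units);
2D studies use the full-scale layout (10 × 35 µm at 25 voxels/µm, tip at
25 µm, source at 9 µm — or 5 µm for the far-source variant — duration 60).
These sizes were fixed at design time so a complete study runs on one CPU
core in minutes; the conversion resolution (50 voxels/µm, 20-nm spacing)
remains the default for pure-conversion work, and the Fresnel/lens oracles
run at 10–20 nm.

## Focusing metrics

The analysis treats any co-registered (structure, intensity) volume pair the
same way, whether simulated (ε_r + energy density) or acquired
(mitochondrial marker + transmitted light).  Rings are per-slice thresholded
cross-sections of the structural channel (threshold midway between the
brightest material and the background median, so only the marker-bright
bundle rings in); the anatomical axis is the principal direction of
area-weighted ring centers.  The optical axis runs from the proximal
intensity "halo" centroid to the global intensity peak.  The concentration
factor at each depth is the mean intensity within 0.75 µm of the optical
axis divided by the background level (the paired empty-run mean for
simulations; an annotated empty region for imported stacks).  Depths are
referenced to the distal IS tip; in pipeline comparisons the tip and OSR
anchor at the placed model's exact tip to remove annotation variance.  The
focal length is the depth of the profile's global maximum distal to the halo
center (ties break proximally; a boundary peak is flagged truncated, and a
`min_depth=0` option clamps foci that retreat inside the bundle at high
mitochondrial index).  A 3-point parabolic refinement is reported alongside
the raw-voxel peak.  The OSR factor is the mean background-normalized
intensity over a 6 µm × 1.5 µm cylinder anchored at the distal tip along the
chosen axis.

## Directionality

Tilt series rotate the model about Y (0/5/10°), re-convert, and re-measure;
tilt angles enter the fit as *measured* from the annotated data (anatomical
vs optical axis in 3D), not as the nominal rotation.  The relative intensity
at a tilt is the OSR concentration along the tilted anatomical axis divided
by the aligned (zero-tilt) value.  ρ comes from least squares on
log₁₀(relative intensity) = −ρ d², with d = angle / (2.5°/mm) — the
classical Stiles-Crawford parameterization with the intercept fixed at 1;
the source names ρ and the human range (0.05–0.09 mm⁻²) without printing
the formula, so the functional form is an interpretive choice documented
here.  The fit pools all angles of a series; per-cone fits are available.

## Alignment morphometry

Skeletons (node/edge centerlines per mitochondrion plus a primary-axis
skeleton tracing the cone center vs z) are read and written in the KNOSSOS
XML dialect.  The z axis is discretized into 0.5-µm layers; each layer
collects the angle between the local primary-axis segment and every branch
(edge) whose z-extent intersects the layer — one contribution per crossing
branch, whole-edge direction, sign-folded into [0°, 90°], 5° bins.
Per-layer histograms are normalized and aggregated as mean ± SD across
layers.  `fraction_below(15°)` summarizes order.  Note the aggregate
(layer-mean, crossing-weighted) fraction runs slightly above the per-branch
fraction for disordered bundles; the generator calibration targets the
per-branch statistic (75% active, 30% hibernating), which is the number the
source reports per branch.

## Cohort statistics

The between-group difference in mean OSR concentration gets a hierarchical
bootstrap: each of 10,000 replicates resamples animals with replacement
within group, then cones with replacement within each drawn animal (each
animal's own pool size); the 99% CI is the 0.5/99.5 percentile range of the
replicate differences.  A flat cone-level scheme is available behind a flag
for sensitivity analysis.  Percentile (not BCa) intervals match the stated
percentile rule.  Simulation contrasts use classical pooled-variance
two-sample, two-tailed t tests (zero-variance ties return p = 1, flagged).
Measured coverage of the nominal 99% CI over 500 synthetic cohorts is ~0.99
(the animal-level resampling slightly over-covers, as expected with 4
clusters).

## What the synthetic studies do and do not show

Passing tests demonstrate that the *pipeline* reproduces the mechanism and
its signatures on geometry with the right statistics: dense aligned bundles
focus light into the OSR; removing mitochondria (but not removing the cell
body around them) destroys most of that concentration; focal length shortens
as the mitochondrial index rises and as bundles densify; shorter focal
length means stronger SCE-like directionality.  They do not reproduce the
reconstruction-specific numbers of the original cones (those depend on exact
segmented shapes), and the generator omits: curved/branching mitochondrial
topology beyond wobbling tubes, cristae geometry beyond an isotropic random
field, refractive-index heterogeneity within compartments, absorption, and
dispersion.  2D runs understate absolute concentration factors
(cylindrical vs spherical focusing) but preserve orderings.

## Numerical choices and degenerate inputs

Float32 fields with float64 accumulation for the cycle average; CPML with
cubic grading, σ_max = 0.8(m+1)/Δx, α = 0.05; PEC behind the PML on all
outer walls.  The Courant bound is validated per dimensionality.  Voxel
centers sit at (i + ½)Δx with a half-open spatial extent; the voxelizer
jitters the lattice by ~10⁻⁶ Δx so mesh edges cannot coincide with test
rays.  Non-watertight meshes are refused everywhere; inward-wound meshes are
flagged by signed volume.  Flat concentration profiles (factor ≈ 1
everywhere) return a no-focus flag rather than a spurious peak.  Packing is
deterministic given a seed; infeasible targets raise a `PackingError` with
the measured capacity rather than silently under-filling.
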