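# Methods

This note records the models, conventions and numerical choices behind
`istomo`, in the order the pipeline runs.

## Optical model and reconstruction

**Forward model.** The sample is described by the scattering potential
V(**r**) = (2π/λ)² (n(**r**)² − n_m²) with λ = 532 nm and medium index
n_m = 1.337 (cell-culture medium; configurable — instruments rarely state
it).  Under the first-order (Rytov) weak-scattering approximation, valid
for RI contrast ≲ 0.05, each illumination direction samples the 3D
spectrum of V on an Ewald cap: for a field indexed by lateral frequency
**q** relative to the illumination, the axial frequency is
k_z = √((n_m/λ)² − |**q** + **k**_ill,lat|²) − k_ill,z and the cap value
relates to the 2D Rytov-phase spectrum by V̂ = 4π ν_z ψ̂ / i (frequencies
in cycles/nm).  Under this convention a thin slab of thickness d delays
the transmitted phase by 2π Δn d/λ, which the tests verify.  The phantom
generator's `forward_scatter` evaluates the z-transform onto the
(generally off-grid) cap frequency exactly, so forward model and
inversion are consistent up to the gridding step.  Multiple scattering is
explicitly out of scope.

**Illumination scan.** One normal beam plus an azimuthally uniform fan on
a cone at the illumination NA (49 beams by default), matching a
DMD-scanned ODT acquisition.

**Hologram demodulation.** Off-axis holograms are demodulated by cropping
a circular window (default radius = half the carrier magnitude, the
largest window that cannot touch the autocorrelation term) around the
+carrier side band and re-centering.  The recovered phase is unwrapped
with a reliability-sorted 2D unwrapper (deterministic raster tie-break).

**Spectrum gridding.** Lateral frequencies land on the grid exactly; the
axial frequency is off-grid.  The default deposits each sample linearly
onto the two neighbouring k_z voxels of a 2× k_z-oversampled grid
(object zero-padded in z), with occupancy-weight averaging where caps
overlap.  Nearest-voxel deposition without oversampling is available
(`z_spread="nearest"`, `z_oversample=1`); on the 64³ sphere benchmark the
linear/oversampled default reduces the support RMSE of the round trip
from 0.34·Δn to 0.28·Δn.  Samples that are evanescent, beyond the
detection NA, or beyond the axial Nyquist frequency are discarded and
counted.

**Missing-cone regularization.** Gerchberg–Papoulis alternating
projections: each iteration replaces measured Fourier voxels by their
measured values, then clamps the object to non-negative RI contrast and
to the known z-support (the oversampling pad is empty space).  The loop
ends on the object-space projection, so the returned contrast is
non-negative by construction.  Defaults: 100 iterations, relative-change
tolerance 1e-6 (no reference values exist for either; both configurable).
`iterations=0` returns the plain inversion.

**Resolution bounds.** Lateral Nyquist period λ/(2(NA_ill + NA_det));
axial period λ/(2[(n_m − √(n_m² − NA_ill²)) + (n_m − √(n_m² − NA_det²))])
(`two_cone`), with a detection-only `single_cone` variant.  The printed
literature pair "125 nm lateral / 471 nm axial" is not derivable from
λ = 532 nm and any single stated NA with these standard formulas (the
effective NA of a DMD scan is rarely published), so the module documents
both variants and asserts only their closed forms and monotonicity.

**Densitometry.** c = (n − n_m)/α with α = dRI/dc = 0.185 mL/g by
default; 1 g/mL = 1000 fg/μm³, so Δn = 0.0185 ↦ 100 fg/μm³.  Negative
contrasts clamp to zero with a logged count.

## Annotation and consensus

`annotate_cells` smooths with a Gaussian (σ), thresholds RI, applies a
binary **closing** with a Euclidean ball (the merging step — closing
rather than bare dilation so cell volume is not inflated; the choice of
operator on the ambiguous step is deliberate and configurable), then
floods a marker-based watershed over the distance-to-nearest-seed map
restricted to the foreground.  Labels are keyed by seed identity, making
the output invariant to seed-list order up to naming.  For two equal
touching spheres the recovered interface is the plane of equidistance to
within one voxel for ≥ 95% of interface voxels.

Binary STAPLE is implemented directly (E-step posterior from current
per-rater sensitivity/specificity and a fixed prior equal to the mean
foreground fraction; M-step re-estimation; tolerance 1e-6, ≤ 100
iterations) because the per-iteration log-likelihood trace and unclipped
p/q estimates are part of the module's contract; the SimpleITK
implementation serves as an independent cross-check in the tests, never
as the implementation.  Voxels with identical rater patterns are
collapsed before EM (exact, and bounds the E-step at 2^raters patterns).

## Signed-distance regression

**Target.** y(v) = +EDT(v) inside the effector, −EDT(v) inside the
target, exactly 0 on background, with EDT the Euclidean distance to the
nearest background voxel in voxel units.  Regressing in voxel units keeps
training resolution-independent; conversion to nm multiplies by the
pitch, under which the default mask threshold 54.5 nm equals a quarter
voxel at 218.5 nm pitch.

**Loss.** Boundary-weighted L1: w(v) = 1 + w_b·exp(−d_b(v)²/(2σ_b²)),
where d_b is the distance to the nearest cell-boundary voxel (including
the cell-cell interface).  The weighting emphasises exactly the region
where voxel-wise classification fails.  The functional form and constants
are not fixed by any reference; defaults w_b = 9, σ_b = 2 voxels put a
tenfold weight on the boundary and decay to uniform L1 within a few
voxels.

**Architecture.** U-shaped encoder/decoder.  Encoder level ℓ is a
residual block (conv3–LReLU–conv3 plus identity); each skip connection
passes a large-kernel "global convolution" module factorized as
separable k×1×1 / 1×k×1 / 1×1×k convolutions (internal width equal to the
skip width — unspecified in the literature, chosen for parameter
economy); transitions are average-pool + channel-expanding conv down,
nearest-upsample + channel-reducing conv up; the head is a linear 1×1×1
conv.  The full-scale configuration (5 levels, 32–512 filters, GCN
kernels 13, 13, 9, 7, 5) validates and instantiates; the desk-scale
default (3 levels, 6/12/24 filters, kernels 5/5/3, 32³ patches,
~73k parameters) trains on one CPU in minutes.  The tensor engine is
NumPy: convolutions as `tensordot` over sliding-window views with
explicit backward passes, verified against finite differences.

**Optimization.** Adam with learning rate 1e-3, β₁ = 0.5, β₂ = 0.99,
learning-rate halving every 50 epochs, and early stopping when the
validation loss has not improved for 5 consecutive epochs — these are the
`TrainConfig` defaults.  The toy benchmark overrides the schedule to
match its scale (an "epoch" of 12 single-sample updates is two orders of
magnitude smaller than a full-dataset epoch): 72 epochs, batch 1,
lr 1.5e-3 halved every 30 epochs, patience 20.  One seed governs split,
initialization and augmentation; runs are bit-reproducible on one
machine.

**Augmentation.** Right-angle rotations about z, lateral reflections
(never axial — the coverslip breaks z-symmetry), random crops, and an
optional elastic warp.  After elastic warping the distance target is
recomputed from the warped masks rather than interpolated, because
warping does not preserve the Euclidean-distance property.

**Inference.** Whole volumes are padded by reflection to the required
divisibility; larger volumes are tiled with a discarded margin
(overlap/2) on interior tile faces, which is seam-free once the margin
covers the receptive field.

## Post-processing

Masks: effector = {y·pitch > +54.5 nm}, target = {y·pitch < −54.5 nm},
each reduced to its largest 26-connected component (fragmentation cleanup
matters for toy models; flag to disable, removed voxels logged).  The
literal 54.5 nm is retained as the default even though it is closer to a
quarter than to half of the 218.5 nm pitch.  Synapse: overlap of the two
masks dilated by a digital Euclidean ball of r = 2 voxels (437 nm,
comparable to the axial resolution).  Surface/interior: one-voxel
6-connected erosion; the two partition the mask exactly.  Structuring
elements (ball for dilation, cross for erosion) are recorded choices —
sizes, not elements, are fixed by the procedure definitions.

## Quantification conventions

**Projection axis.** "En face" is along the unit vector between the two
density-weighted cell centroids (no reference defines the direction; the
centroid axis is well-defined frame by frame).

**Areas.** Two conventions ship.  `synapse_area` projects a mask along
the grid axis nearest to the en-face axis and counts occupied pixels —
simple and thickness-robust, the convention used for mask areas and
density normalization.  `contact_area` sums the signed flux of
effector→target voxel faces through the plane normal to the axis; by the
discrete divergence theorem this is the exact projected area of the
interface, free of the ~2πr·t rim inflation that dilation-overlap masks
carry, and is therefore what the kinetics fits use.

**Surficial density** is mass-per-projected-area (Σc·voxel volume ÷
projected shell area); the max-projection map is produced for
visualization only.  **Total synapse protein** is Σc·voxel volume over
the IS mask.  **Center of mass** is the density-weighted mean voxel
position in nm.

**Hyperbola fits.** y = y_max·t/(t + τ½) by `least_squares` with
multistart τ½ ∈ {t_med/3, t_med, 3·t_med}, y_max₀ = max(y); best SSE
wins, ties to the smallest τ½; ρ is the Pearson correlation between
fitted and observed series (the natural reading of the reported fit
quality).  Noiseless generate-and-refit is exact to 1e-6 relative.

**Rate windows.** rate = [d(t₀+10 s) − d(t₀)]/10 s with linear
interpolation at the edges, at t₀ = 0 and 100 s by default.

**Wilcoxon tests.** Paired signed-rank and unpaired rank-sum, two-tailed;
exact enumeration (via SciPy's exact methods) for n ≤ 25 without ties,
normal approximation with tie/continuity correction otherwise.

## Evaluation metrics

Mask Pearson correlation is computed over the full common grid (×100);
full-grid is deterministic and shift-insensitive within a fixed field of
view.  BDE extracts one-voxel boundary shells (mask minus 6-connected
erosion) and averages the two directional mean nearest-neighbour
distances (symmetric by construction; one-directional variants exposed).
With anisotropic pitch the nm value is computed in physical space.

## The phantom generator: what it emulates and what it does not

A conjugate is two quasi-spherical cells: the effector with higher-RI
cytoplasm (1.360) and high-RI granules (1.380, 6–8 of radius
0.3–0.45 μm), the target with lower-RI cytoplasm (1.350) and a
nucleus-like concentric core (1.344); medium 1.337.  The RI separation
between the two cytoplasms stands in for the real morphological and
textural cues that distinguish effector from target in measurements — a
deliberate simplification, so passing the toy benchmark demonstrates that
the pipeline machinery (distance targets, loss, optimization,
post-processing) works, not that the network would distinguish real cell
types.  Granules are placed in the distal hemisphere (a 60° cone away
from the contact axis) so they never straddle the interface as the cells
interpenetrate; real lytic granules polarize toward the synapse — the
phantom trades this realism for an unambiguous ground truth.  Membranes
are sub-resolution and not modelled; noise is additive Gaussian on RI
only.

**Contact kinetics.** A(t) and Δd(t) follow y_max·t/(t + τ½) with
defaults equal to the reference fitted values (A_max = 106.16 μm²,
τ½ = 39.63 s; Δd_max = 7.48/1.74 μm, τ½ = 37.84/14.56 s for
effector/target).  The contact is realized by interpenetrating spheres:
the center distance D(t) solves π(r₁² − d₁²) = A(t) for the lens disc,
voxels in the lens go to the nearer center (effector wins ties), so the
true interface is the radical plane.  Displacements are prescribed on the
*realized density-weighted centroids*: the growing truncation shifts each
cell's centroid away from the interface, so sphere centers are corrected
by a 3-step fixed-point loop (re-rasterize, measure, adjust) until the
realized centroid lands on the prescribed trajectory (residual
≲ 0.04 voxel).  The target moves along the initial contact axis; the
effector's direction is solved in the contact plane so that displacement
magnitude and center distance hold simultaneously (a triangle
construction; infeasible parameter combinations raise a geometry error).
Default grid: 14 × 19 × 28 μm at 218.5 nm pitch, cells of radius 6.2 μm —
the smallest cells that can carry the saturated 106 μm² disc.

**Known discretization limit.** Where two sphere surfaces approach at a
grazing angle, voxel adjacency registers contact for sub-voxel gaps,
inflating small contact areas by an additive bias that is linear in the
pitch (~3 μm² at 218.5 nm near t = 0, decaying as the rim steepens).
This biases the fitted τ½ by about −7% at 218.5 nm and −3.5% at
109.25 nm; the displacement fits are unaffected (< 0.1%).  The kinetics
recovery benchmark therefore runs at 109.25 nm pitch, where the bias is
subdominant to its 5% tolerance; `default_timelapse_spec(pitch_nm=...)`
exposes the refinement and the error halves with the pitch, consistent
with convergence to the generating hyperbola as pitch → 0.

## Problem sizes used by the test suite

Chosen so the whole suite runs on one CPU: tomographic round trip at 64³
with 49 illuminations; watershed accuracy over 20 seeded conjugates at
32×32×64; STAPLE with 5 raters on 20³; network benchmark with 12 training
and 4 held-out conjugates (32×32×64 at 218.5 nm), 72 epochs; kinetics
recovery on 51 frames at 109.25 nm pitch.  The full-scale network
configuration is provided but deliberately not trained by the tests.

## Limitations

- Single-scattering forward model and inversion; thick or high-contrast
  samples violate the Rytov assumption.
- The phantom's effector/target distinction is an RI offset, not
  morphology; trained toy models do not transfer to measured tomograms.
- No aberration correction, no temporal-consistency smoothing, no
  active-contour refinement of the regressed boundaries.
- Segmentation-accuracy figures from correlative-fluorescence ground
  truth (and group comparisons between receptor constructs) require the
  original measured cells and are out of scope; the metrics themselves
  are the deliverable.
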