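# Methods

This note records the models and numerical choices behind `footarch`, what
the synthetic scenes do and do not emulate, and the known limitations.

## Measurement model

The instrument being modelled is a depth + color camera looking up at a
transparent footplate roughly 300 mm above it. A pixel (u, v) with depth z
(mm) deprojects through the pinhole model to
x = (u − cx)·z/fx, y = (v − cy)·z/fy in the depth-camera frame (x right,
y down, z along the optical axis; 0-based indices, u = column). Color is
mapped onto the depth raster by nearest-neighbour sampling through the
depth→color extrinsics; depth value 0 marks an invalid pixel. The camera is
not assumed parallel to the plate — the plate pose is estimated from the
data itself.

### Footplate estimation and contact points

Per-pixel normals are cross products of the left/right and up/down neighbour
differences, oriented toward the camera (n_z < 0) and averaged once over the
valid 3×3 neighbourhood. Normals are voted into a 20×20×20 voxel grid over
[−1, 1]³ (cell size 0.1; +1.0 clamps into the last cell). Every non-empty
cell seeds a cluster; clusters whose cells are 26-neighbours merge,
closest-mean pair first, while their mean normals differ by less than the
cell size. The plate plane is the least-squares fit (centroid + smallest
right singular vector of the centered coordinate matrix) to the points of
the largest cluster.

Absolute point–plane distances are histogrammed in 1 mm bins over [0, 20] mm
(bin width and range are package choices; only a histogram is prescribed by
the method). The contact points are all foot points with |d| ≤ the upper
edge of the modal bin (d*). Absolute rather than signed distances are
binned because noise places genuine contact points on both sides of the
fitted plane.

**Plane refinement.** Normals from single-pixel baselines are very noisy at
realistic sensor noise, and the cluster-selected point set can yield a plane
tilted by 1–3°. A tilt of that size moves one end of the foot out of the
modal bin, which both truncates the contact set and (worse) lets true
contact pixels be drawn as non-contact training samples downstream. The
plane is therefore refit three times on the gated contact points themselves,
re-gating after each fit. On noise-free input the refit is a fixed point and
changes nothing; under noise it brings the plane within ~0.2–0.9° of truth
in our scenes.

### MRF contact-region segmentation

Labels are {contact, non-contact, background} on the full pixel grid;
pixels without a valid 3D point are clamped to background. The energy is

    E(c) = Σᵢ w_ψ ψ(cᵢ,xᵢ) + w_λ λ(cᵢ,dᵢ) + w_ρ ρ(cᵢ,θᵢ)
         + Σ_(i,j)∈edges 1(cᵢ≠cⱼ) exp(−β‖xᵢ−xⱼ‖²)

with θᵢ the angle between the pixel normal and the plate normal. Per class,
ψ is the negative log density of a 3-component full-covariance RGB GMM (EM,
k-means init, tol 1e-4, ≤200 iterations, covariance regularizer 1e-3); λ and
ρ are negative log densities of scalar Gaussians from the sample mean/std
(std floored at 1e-3). Densities are floored at 1e-12 before the log.
Defaults: weights (w_ψ, w_λ, w_ρ) = (2.9, 9.3, 1.8);
β = 1/(2⟨‖xᵢ−xⱼ‖²⟩) over the grid edges (standard contrast normalization),
overridable.

Training samples (500 per class by default) come from the frame itself:
contact samples uniformly from the sparse contact points; non-contact
samples from foot points outside the contact mask dilated by a disk of
radius 5 px (so the sparsity of contact detection does not leak contact
pixels into the non-contact class); background samples are the fixed
archetype (color [0,0,0], distance 0, angle 180°) with small Gaussian
perturbations (σ = 2 intensity / 0.1 mm / 1°). If every foot point is a
contact point (a fully flat foot), there is no evidence for a non-contact
class; it is then trained on the background archetype and stays inert
rather than splitting the contact region arbitrarily.

Inference is alpha-expansion: for each label in the fixed order (contact,
non-contact, background) a binary keep-vs-switch subproblem is solved
exactly by s–t min-cut (the Potts pairwise table is submodular for every
expansion move). Capacities are scaled to int64 at 1e8 per energy unit, so
cuts are exact to ~1e-8; every move is additionally accepted only if it
lowers the exact floating-point energy, which guarantees a monotone descent
from the per-pixel unary argmin initialization. Sweeps repeat until no move
helps. A checkerboard ICM backend (exact coordinate descent on the
4-connected grid) is available as an alternative.

A practical caveat recorded here because it is easy to trip over: with the
color weight at exactly zero, the background archetype (distance 0) competes
with the contact class for on-plate pixels whenever the contact distance
spread collapses (noise-free data) or a residual plane tilt shifts the
distances; the color term is what keeps the background class confined to
non-foot pixels. All recommended weight sets have w_ψ > 0.

### Arch parameters

The contact region (largest connected component of the contact label) is
PCA-aligned; the half with the greater maximum width perpendicular to the
principal axis is the toe side. On the heel half, distances from the
region centroid to the traced boundary (Moore neighbour tracing, closed
8-connected contour) are smoothed with a circular 1D Gaussian (σ = 5
samples), and salient points are the strict local maxima of the smoothed
profile with at least 0.5 px prominence over a 2σ window — the prominence
gate exists because rasterizing a smooth boundary leaves sub-pixel ripples
that would otherwise count as maxima. The heel center K is the salient
point farthest from the centroid (fallback: the farthest boundary point).
The axis runs from K through the operator-supplied second-toe pixel.

Toes are removed in a raster rotated so the axis is vertical: within the
anterior third of the foot's axial extent, each column keeps its strongest
vertical 3×3 Sobel response with magnitude strictly above 50 (per-column
non-maximal suppression); edge positions are averaged over a 5-column
window, missing columns interpolated; pixels anterior to the edge curve are
dropped. On a uniform image no edge fires and the mask is returned whole.

AI: with L the foot of the axis at the most anterior main-body contact
pixel (ties averaged), the L–K segment is cut at 1/3 and 2/3; thirds use
half-open intervals of the clamped normalized axial coordinate so no pixel
is double-counted, and anterior + middle + posterior = total exactly.
AI = 100·middle/total.

MBL: the convex hull of the traced contact boundary is computed; hull
vertices deviating less than 1.5 px from their neighbours' chord are merged
first, because the projected (genuinely straight) medial border quantizes
into a pixel staircase whose sub-pixel convex corners would split the hull
edge and displace its midpoint. For each remaining hull edge the depth is
the maximum perpendicular distance from the edge to the boundary arc it
spans; the deepest edge is the MBL (a convex region returns the longest
edge with depth ≈ 0 and a warning). AW is measured by marching an in-plane
ray from the MBL midpoint, perpendicular to the MBL toward the region
interior, to the first contact pixel (0.5 px steps, sub-pixel boundary
refinement), reading the length from the 3D points involved. AH is the
distance from the MBL midpoint to the foot point nearest the line through
it along the plate normal; the midpoint is first projected into the fitted
plane, since the MBL is by definition a footprint (in-plane) line and depth
noise on its endpoint pixels would otherwise offset the height origin by a
couple of millimetres. All metric outputs come from 3D points, never from a
global mm-per-pixel factor, which makes AW/AH invariant (≲0.5 mm) under
rigid tilts of the whole scene.

## Weight fitting

With residuals fᵢ(w) = Gᵢ − Eᵢ(w) over m scenes (ground truth minus
pipeline estimate) and cost F = ½‖f‖², Levenberg–Marquardt iterates
(JᵀJ + μI)h = −Jᵀf with μ₀ = 1e-3 and factor ν = 10 (classic Marquardt
schedule; only the adaptivity, not the schedule, is prescribed). Steps are
accepted only if they strictly lower F; weights are projected to ≥ 0 after
acceptance. The Jacobian is central-difference with a large relative step
(default 1e-2, 0.25 recommended for the pipeline problem) because the
pipeline is piecewise-flat in w; all pipeline randomness is frozen by seed
so the residual is a deterministic function of w. Each arch parameter is
fitted as a separate problem (the residual units differ), giving one weight
triple per parameter.

## Evaluation statistics

Accuracy is the average signed error (AE) against ground truth;
repeatability the sample standard deviation (ddof = 1; the population
variant is exposed via `ddof`) of repeats, and a coefficient of variation.
The published CV definition is ambiguous (its printed values are consistent
with std/mean although the text reads mean ÷ std), so both formulas are
exposed and std/mean is the default; no published CV value is asserted.
Spearman's ρ uses average ranks for ties and the classical
1 − 6Σd²/(n(n²−1)) formula; `spearman_from_ranks` accepts externally
supplied ranks, which is how the shipped 11-subject rank tables reproduce
their published coefficients (the AW table's printed ranks are internally
inconsistent — two distinct values share rank 7.5 — and are stored
verbatim, not re-ranked). Quartiles for the arch-type classifier use linear
interpolation between order statistics (numpy's default); AI below Q1 is a
high arch, above Q3 a low arch.

## Synthetic scenes

The generator renders the measurement geometry analytically: rays through
each pixel intersect the (optionally tilted) plate plane; a parametric foot
template in plate coordinates decides silhouette, surface height and color;
depth is the z-component of the surface point plus i.i.d. Gaussian noise
(default σ = 1.65 mm ≈ 0.55 % of the 300 mm working distance, the relative
error class of consumer depth cameras at this range).

Template choices, each made for realism of the emulated measurement:

- the lateral border tapers linearly from heel to forefoot width and the
  body front is flat against the toe-gap band — real footprints have a
  nearly straight lateral border, and this guarantees the only deep
  boundary concavity is the medial arch indentation;
- the medial border is straight (the hull line), recessed over the midfoot
  by up to `arch_width`, with the dome above it rising to `arch_height`;
  by construction AW_true = arch_width and AH_true = arch_height;
- the axial arch profile has smooth flanks and a central plateau (the
  deepest section of a real arch is broad), so the construction truth is
  insensitive to small axial errors in locating the MBL midpoint, and the
  dome rises as √t from the contact edge so that "contact" is sharp with
  respect to the detection threshold;
- contact-region skin is blanched by a subtle chroma shift under per-pixel
  color noise (σ = 10) and a deterministic ±15–20 % illumination gradient.
  The gradient matters: with spatially uniform lighting the color cue would
  be more informative than the distance cue, inverting the cue ordering of
  the real instrument (where distance dominates and stable lighting needs
  dedicated hardware);
- toes are five ellipses separated from the body by a dark gap band lifted
  3 mm off the plate (0 in the flat-foot preset, where the entire foot is
  in contact).

Ground-truth AI is obtained by counting rendered contact pixels in the
axial thirds; an independent continuum integral of the template widths
agrees within 0.5 points at the canonical raster. Canonical scenes are
rendered at 400×300 (focal length scaled accordingly from the 640×480
default); this is the package's standard problem size for tests and the
acceptance script, chosen so the full pipeline runs in well under a second
per frame. Weight-optimization examples use 200×150 scenes for the same
reason.

What the scenes do **not** emulate: real skin texture and specularity,
depth shadowing/occlusion at steep surfaces, correlated (non-i.i.d.) sensor
noise, partial foot placement, and anatomical variation beyond the
template's parameters. Passing tests therefore demonstrate correctness of
the algorithms under the stated geometry and noise model, not clinical
accuracy on human feet.

## Known limitations

- Alpha-expansion is an approximate minimizer for three labels; exhaustive
  checks on small instances find it at the global optimum, but no global
  guarantee exists for full frames (the energy-descent guarantee does).
- The MBL definition assumes a medial arch indentation exists; on a
  completely flat foot the convex contact region has no meaningful MBL and
  AW degrades to a warning path with depth ≈ 0.
- The second-toe center is an operator input by design; automatic detection
  is out of scope.
- AH under sensor noise inherits the noise of the single nearest surface
  point (no local surface averaging), contributing most of its ~0.5–0.9 mm
  repeat spread.
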