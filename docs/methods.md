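# Methods

`vimloc` analyses how different definitions of the ventro-intermediate
(Vim) thalamic nucleus relate to each other: a directly delineated Vim
outline, the indirect quadrilatere-of-Guiot stereotactic target, the
motor-nuclei (VLV) cluster from diffusion-based thalamic parcellation, and
a multi-atlas segmentation driven by SWI-like intensities. Because real
7T SWI with expert Vim outlines is scarce, every stage runs on synthetic
phantoms with known ground truth. This note describes the models, the
parameters that matter, and the choices made where the design was open.

## Coordinate frame and volumes

All geometry lives in world millimetres on axis-aligned voxel grids: the
anterior commissure (AC) at the origin, `x+` subject-right, `y+` anterior,
`z+` superior. Every predicate operates on voxel *centers*. Rotated or
sheared grids are rejected at I/O time; inter-contrast and inter-subject
registration is assumed to have happened upstream, so a cohort shares one
rigid AC-PC frame. The default grid is 96³ voxels at 0.4 mm isotropic
(0.5 mm grids are supported through `VoxelGrid`), spanning roughly
x ∈ [−19, 19], y ∈ [−34.6, 3.4], z ∈ [−14, 24] mm — enough to hold both
thalami with the AC and the posterior commissure (PC) in frame.

## Synthetic thalamic anatomy

Each phantom hemisphere is built from ellipsoids clipped to their parent
structure:

* **Thalamus** — an ovoid (aspect semi-axes 9.2 × 16.5 × 11.6 mm in
  x/y/z) centred near (±9.8, −17.5, 2.5) mm, clipped to its own
  half-space so left and right never cross the mid-sagittal plane.
  Default volume target: 7600 mm³ per hemisphere.
* **VLV (motor-nuclei cluster)** — a ventral-lateral sub-ellipsoid
  (aspect 5.4 × 7.9 × 6.4 mm) clipped to the thalamus. Default volume:
  15% of the realized thalamic volume (healthy-cohort values span
  ~13–19%).
* **Vim** — a small ellipsoid whose *shape* comes from the
  `vim_extent_mm` parameter (full extents, default 3 × 8 × 5 mm in
  AP × DV × ML, mid-range of the classical 2–4, 7–10, 4–6 mm), placed in
  the inferior part of the VLV bounding cuboid and pushed flush against
  the lateral VLV surface before clipping. Default volume: 1.0% of the
  thalamus (reported outlines span ~0.4–1.5%, 35.5–94.5 mm³).
* **Vc / Vo** — dark slabs immediately posterior and anterior-superior to
  the Vim, reproducing the contrast sandwich that makes the Vim
  identifiable on SWI; **pulvinar** — the posterior slice of the thalamic
  cuboid with a lateral-dark/medial-bright gradient.

Absolute sizes are controlled by the volume targets, not by the aspect
parameters: for each structure the ellipsoid radius is chosen so that the
clipped mask holds exactly `round(target / voxel_volume)` voxels (the
n-th smallest value of the sorted squared-radius field). Volume fractions
therefore recover the requested ones to well under a tenth of a
percentage point, which is what makes fraction-recovery tests meaningful
rather than tautological — the *spatial relations* (containment,
adjacency, centroid position) remain emergent properties of the clipped
geometry.

Per-subject variability for cohort generation draws a global linear scale
(uniform ±5%, i.e. ±~15% in volume) and independent per-hemisphere
translations (uniform ±0.5 mm for the thalamus, ±0.25 mm extra for VLV
and Vim). All draws come from one explicitly seeded generator per call;
cohort member seeds derive deterministically from the master seed.

The SWI-like intensity volume paints mean levels (arbitrary units):
background 40, thalamus 45, Vim 62 (hyperintense), Vc/Vo 30 (dark),
pulvinar gradient 32–50, plus additive Gaussian noise (sd 3). With these
defaults the Vim-to-surround contrast is ≥ 3 noise sd, the regime where
direct delineation is plausible. Optional vessel artifacts are dark
(intensity 15) random-orientation cylinders (radius 0.4 mm, length
18 mm, two per hemisphere) anchored near the Vim, emulating the small
vessels that complicate delineation.

What the phantom does *not* emulate: MR physics (bias fields,
susceptibility anisotropy, distortion), registration error, partial
voluming, age-related contrast loss (`SwiParams` exposes the levels but no
quantitative elderly contrast is modelled), and realistic nucleus shapes
beyond clipped ellipsoids. Passing tests therefore validate the
*analysis machinery* and the stated geometric/statistical relations, not
performance on real SWI.

## Quadrilatere-of-Guiot targeting

The target is constructed from landmarks alone: laterally at
`wall + 11 mm` from the third-ventricle lateral wall; anteriorly at a
fraction (default 0.25) of the PC→AC distance from PC; vertically on the
AC-PC plane plus an offset (default 0). Only the 11 mm laterality is a
firm constant of the construction tradition; the AP fraction and height
vary between descriptions, so they are `GuiotParams` fields, not
hard-coded constants. A 2 mm-radius sphere around the point emulates the
90 Gy isodose volume of radiosurgical thalamotomy.

Repeated blind targeting is modelled as independent uniform perturbation
of every landmark coordinate within ±0.2 mm (half a voxel at 0.4 mm)
followed by snapping to the nearest voxel center. Because the constructed
coordinates are affine in the landmarks with coefficients summing to ≤ 1
per axis, each continuous coordinate stays within half a voxel of its
nominal value, and quantized repetitions can differ by at most one voxel
per axis — reproducing the whole-voxel reproducibility seen in manual
re-targeting (all six-repetition sessions stay below 1.3 mm
point-to-first distance; the lattice bound is √3·0.4 ≈ 0.69 mm).

## Eight-way geometric subdivision

The smallest axis-aligned cuboid over the ROI's voxel centers is split by
its axial mid-plane (superior/inferior) and by the two diagonals of its
axial rectangle. Since the diagonals join cuboid corners, the quadrant
test runs in coordinates normalized by the half-extents: `u` (lateral,
sign per hemisphere) and `v` (anterior); anterior iff `v > |u|`,
posterior iff `v < −|u|`, otherwise lateral (`u ≥ |v|`) or ventral
(`u ≤ −|v|`, the medial-facing quadrant, keeping the traditional name).
Tie-breaks are deterministic and documented: z-ties are superior,
diagonal ties fall to the lateral/ventral pair by the sign of `u`, the
exact center is lateral. Internally the normalization uses voxel-index
offsets (exact half-integers) instead of world mm — mathematically
identical on axis-aligned grids, but it makes tie comparisons and mirror
equivariance exact rather than float-fragile. A flat ROI (zero x or y
extent) has no defined diagonals and raises a degenerate-geometry error.

`classify_point` additionally reports an `on_boundary` flag when a point
lies within a tolerance (default 0.05, in normalized cuboid units) of the
mid-plane or of a diagonal; the flag is for interpretation ("around the
mid-plane") and never alters the partition.

## Spatial relations

* *Containment*: `|inner ∩ outer| / |inner|`.
* *Surface distance*: minimum Euclidean distance between boundary voxel
  centers, a boundary voxel being a mask voxel with a 6-neighbour outside
  the mask. Deterministic and checkable by brute force.
* *Adjacency*: a subregion of the outer ROI is "adjacent" to the inner
  ROI when the inner boundary comes within a threshold (default 1.0 mm,
  ≈ 2–3 voxels) of the outer-boundary voxels carrying that subregion's
  label. Adjacency judgments in the clinical literature are visual; the
  metric threshold is this package's operationalization, and reports are
  monotone in it.
* *Centroid localization*: the unweighted centroid of a mask classified
  against a reference cuboid; a centroid outside the cuboid is reported
  as `outside`, not raised.

## Intensity standardization and label fusion

Standardization follows the decile-landmark histogram-matching scheme:
per subject, the percentiles (1, 10, 20, …, 90, 99) of the thalamic VOI
intensities are computed (p1/p99 as robust extrema — the endpoint handling
is a documented dialect choice); the standard scale is the cohort-mean
landmark vector mapped affinely onto [0, 100]; each volume is then mapped
piecewise-linearly so its own landmarks land on the scale's, with linear
extrapolation beyond p1/p99. The map is monotone, exactly invariant to
affine intensity transforms of the input, and the identity on
already-standard inputs. Degenerate inputs (constant intensities,
collapsed deciles, < 100 masked voxels) are rejected rather than mapped.

Label fusion offers three rules on co-registered atlases:

* **majority** — unweighted vote;
* **local_weighted** — weights ∝ `exp(−β · MSD_i)` with `MSD_i` the mean
  squared intensity difference over a cubic patch (radius 2 voxels,
  zero-padded); β → 0 recovers the majority vote;
* **joint** — per voxel, `w = (M + εI)⁻¹ 1` normalized to sum 1, where
  `M_ij` is the patch mean of `|I_i − T| · |I_j − T|`, so atlases making
  *correlated* errors share weight instead of accumulating it. The
  unconstrained solution can carry negative weights; they are clipped to
  zero and renormalized so fused probabilities stay in [0, 1] — a
  deliberate simplification of the cited formulation, chosen to keep the
  fused output a convex combination. ε (default 1e−6) conditions the
  matrix inversion.

The fused Vim probability is `Σ w_i · label_i`; the output mask
thresholds it at 0.5. The trained corrective-learning post-step of the
original fusion method is out of scope.

The leave-one-out harness crops a VOI around the target's thalamus
(2 mm margin), builds the standard scale from the training subjects of
the current fold (the scale-seeding cohort is a free choice; using the
fold's training atlases keeps folds independent), standardizes everyone,
fuses the training Vim labels, and scores Dice against the target's
ground truth. Spreads are sample standard deviations (n − 1). On the
default eight-subject jittered phantom cohort the joint rule reaches a
mean Dice around 0.85–0.90: phantom cohorts are perfectly co-registered
apart from the sub-millimetre jitter, so this is an upper-bound regime
and deliberately *not* a reproduction of real-data accuracy, where
registration error and contrast variability dominate.

## Problem sizes and numerical choices

The shipped analyses use: 500 six-repetition targeting sessions, 20
phantom subjects for parameter recovery, an 8-subject cohort (16
hemisphere cases, 7 atlases per fold) for the LOO experiment, and 100
random masks for the subdivision oracle check — sizes chosen to match
the study's scale (9 subjects, 17 delineations, 6 repetitions) while
keeping the full suite around a minute. Sphere/ellipsoid membership uses
a 1e−9 relative tolerance on the squared radius so lattice points
mathematically on the surface are included regardless of float rounding.
NIfTI affines are stored in float32 by the format; spacings and origins
are rounded to 1e−6 mm on read so round-trips compare equal.

## Known limitations

* Ellipsoid phantoms cannot probe failure modes driven by real nucleus
  shape, registration error, or contrast pathology; LOO Dice here is an
  upper bound, not a forecast.
* The quadrilatere construction beyond the 11 mm laterality is
  parametric by design; the defaults are a reasonable reading of the
  construction tradition, not measured clinical constants.
* "Ventral" for the medial-facing quadrant follows the field's
  terminology for this subdivision even though the geometry makes it the
  medial quadrant.
* The cohort table ships with the package; its per-case values carry the
  rounding of the printed source (percent columns to 0.1–1 point), which
  is why ratio summaries are computed on the normalized columns and
  reported rounded.
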