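# Methods

## The measurement model

The tibial slope of a compartment is treated as a per-slice quantity: in
each sagittal (or coronal) slice the plateau is reduced to its two rim
points, and the slope is the signed angle between the rim-to-rim line and
the perpendicular to a proximal reference axis. The method's defining
property is that the reference axis is built entirely from the proximal
tibia — a transverse plane through the most anterior tuberosity point, the
slice with the longest chord in that plane, and two parallel chords 10 mm
apart — so the result cannot depend on how much diaphysis the scan
includes. Long-axis constructions do not have this property; their slope
estimate shifts with scan length, which is the motivating defect this
pipeline avoids (verified directly by the truncation test).

Assumptions inherited from the model:

* The subject is scanned supine and roughly neutrally aligned; the
  reference axis absorbs modest tilt (a sheared shaft tilts the axis with
  it), but gross malpositioning is not corrected.
* The tibia is the largest bright (or dark) connected bone in the field of
  view after global thresholding.
* The tuberosity's most anterior point falls 10–40 mm below the most
  superior tibial point (config `tuberosity_band_mm`); the band keeps the
  anterior plateau rim, which can protrude further anteriorly on some
  anatomies, out of the search. This operational definition of "the
  tuberosity point" is this package's construction; the underlying protocol
  does not define the landmark operationally. "Most anterior" is resolved
  with a 0.1 mm tolerance — boundary positions are not reliable below a
  fraction of a voxel, so candidates within tolerance of the maximum count
  as tied and the deterministic tie-breaks (inferior-most, then most
  central) decide; without this, image noise would pick an arbitrary point
  along a near-vertical anterior face and plane 1 would not be repeatable.

## Coordinate conventions

All volumes are resampled-free but reoriented at load into a single frame:
+x anterior, +y medial, +z superior, millimetres at voxel centres. Left
knees are mirrored about the sagittal midplane at load time (and unmirrored
on write), so compartment labels are laterality-independent. Laterality is
a required input; it is not inferred from cropped proximal-tibia scans.

## Contours

Segmentation is Otsu's global threshold (the minority class is bone),
largest 3D connected component (ties: voxel count, then the more inferior
centroid), holes filled slice-wise. The cortical shell operation
`mask − erode(mask)` reproduces the boundary-shell contract of the original
threshold-subtraction workflow; the measurement itself consumes polylines
traced by marching squares:

* from image intensities at the Otsu iso-level when the source volume is
  available — with partial-volume boundary voxels this localises the cortex
  well below voxel size;
* from the binary mask at the 0.5 level otherwise, followed by a one-voxel
  arc-length smoothing pass (binary staircase inflates perimeter by ~6%
  otherwise).

Per-slice component choice prefers the piece reaching most superiorly: a
slice can graze both the plateau overhang and the shaft as separate pieces,
and the articular measurement always concerns the superior one.

## Curvature and landmarks

Contours are resampled uniformly in arc length, smoothed with a periodic
Gaussian of scale `curvature_sigma_mm` (default 2 mm), and rescaled about
their centroid to preserve enclosed area — plain Gaussian smoothing shrinks
closed curves and would bias curvature by ~sigma²/2r². The reported
profile is the turning rate dθ/ds per unit of original arc length
(curvature of the smoothed curve times local speed), so the loop integral
equals the total turning 2π exactly for any closed simple contour — a
conservation property the tests check. The smoothing scale trades noise
robustness against corner localisation: detection runs at sigma, then each
rim node is re-localised at sigma/2.5 inside a 1.5·sigma arc window
(coarse-to-fine), which removes the drag of the smoothed maximum toward the
more convex flank of a corner.

Rim-node search is restricted to vertices within `superior_band_mm`
(default 25 mm) below the contour's most superior point. An absolute band
anchored at the top — rather than a fraction of the contour's height — is
used because a fractional cut excludes the posterior rim on thin peripheral
slices (where the facet's drop exceeds a fixed fraction of a short lens)
and changes when the distal shaft is truncated. Within the band, split at
mid-u, the maximal-positive-curvature vertex per half is the node, subject
to guards: `kappa_min` = 0.05/mm (a rim flatter than a 20 mm circle is not
a rim), a flat-maximum guard (near-constant curvature, e.g. a circular
slice), and an ambiguity guard (two near-equal peaks more than 5 mm apart —
measured cyclically so a corner containing the contour's start vertex is
not split in two). Guarded slices are skipped and logged, never guessed.

Concavity: the superior arc between the nodes is compared with the A-B
line; vertices more than `concavity_depth_min_mm` (0.1 mm, discretisation
guard) below it are dish points. The concavity zone of a compartment is the
normalized-distance span of the largest contiguous run of concave slices,
tolerating single-slice gaps. Published zone bands (lateral 35–60%, medial
45–70% of the compartment extent) are cohort observations, not constants of
the method, and are not hard-coded anywhere.

## Slopes and normalization

`slope_angle` returns `atan2(−t·â, |t·p̂|)` in degrees, where t = B − A, â
the in-plane axis direction and p̂ its perpendicular: positive exactly when
B lies on the inferior side of the perpendicular through A. Sagittal slices
medial of the SRS form the medial compartment, lateral ones the lateral
compartment; the SRS itself belongs to neither. Each slice's distance to
the reference slice is divided by the distance from the reference slice to
the outermost tibia-bearing slice on the same side (anterior/posterior of
the CRS for the coronal pass) and clamped to [0, 1]. Coronal samples from
the two sides can tie in normalized distance, so the coronal profile is
ordered by (distance, slice index); the sagittal profiles are strictly
increasing. Summaries use the sample SD (n−1); compartments with fewer than
two valid slices are reported absent, not zero. Cohort-level Pearson
correlations (coronal vs medial/lateral means) require at least three
complete subjects. The highlighted-zone classification uses strict
inequalities (mean MTS < 8°, mean LTS < 5.5°).

## The phantom

The generator emulates the features the pipeline actually keys on:

* a vertical shaft (radius 15 mm) flaring over 25 mm into an elliptical
  plateau, 50 mm AP × 70 mm ML — the smoothstep flare has zero slope at
  both ends so plateau walls are locally vertical at the rim;
* two planar facets with independent sagittal tilts and a common coronal
  tilt. Two planes with different dz/dx cannot share a sagittal ridge line,
  so the facets are joined by a 2 mm half-width linear blend strip at the
  midline; at the protocol's 2.4 mm slice pitch the first slice on either
  side is already clear of the strip;
* an anterior tuberosity crest (height 10 mm, Gaussian in y with 6 mm
  scale) whose anterior face is vertical below its apex, like the anterior
  crest of a real tibia. This makes the reference-axis construction exact
  in the continuum, and it means "most anterior point in the band" ties
  along the face — resolved, per the documented tie-breaks, at the band's
  inferior edge, which is what `expected_tuberosity_point` returns;
* optional elliptical-cap dish depressions per facet, with span given in
  normalized distance along the facet;
* intensity 1000 on background 0 with linear partial-volume boundary
  sampling (5×3×5 subsampling of boundary voxels) and seeded additive
  Gaussian noise, default SD 20 (SNR 50, a typical 3T acquisition);
* default spacing (0.5, 2.4, 0.5) mm: the target protocol's 1.6 mm
  sagittal slices with 0.8 mm gap give 2.4 mm centre-to-centre spacing;
  the in-plane resolution is not specified by the protocol and 0.5 mm is a
  typical 3T knee value.

Ground-truth slopes are the analytic dihedral angles of the facet planes
against the shaft-perpendicular plane — independent of voxelisation.

What the phantom does **not** emulate: MRI bias fields, cartilage,
trabecular texture, the femur and fibula (beyond the disconnected-fragment
test), osteophytes, and anatomic asymmetries of the rims. Passing the
phantom grid therefore demonstrates the geometry pipeline's correctness and
stability at the protocol's resolution, not robustness to every clinical
segmentation failure mode.

## Numerical choices and precision

* Contour resampling step: min(0.25 mm, perimeter/128); marching squares
  operates on slices padded with background so boundary-touching objects
  still close.
* Reference chords are read off the smoothed (area-preserving) contour at
  the curvature scale; on straight walls this averages the residual
  marching-squares wiggle. The sheared-cylinder check in the acceptance
  script recovers a 5° shaft shear to ~0.02°; across arbitrary shears the
  staircase phase of a nearly-vertical wall at 0.5 mm voxels can still
  leave a few tenths of a degree of axis error.
* With 2.4 mm in-plane sampling (coronal contours' ML axis), curvature
  estimates near the `kappa_min` threshold are unreliable (errors up to
  ~2× on gently curved arcs); the guards err on the side of skipping.
* Thick-slab partial volume rounds rim corners and shallows dishes: on
  2.4 mm slabs a 2 mm dish measures a few tenths of a millimetre shallow.
  The per-slice dish-depth check in the tests uses isotropic 0.5 mm
  sampling; the zone-bound recovery runs at the protocol spacing.
* All tie-breaks (tuberosity point, reference-slice chords, component
  choice) are total orders, so the pipeline is deterministic; phantom
  generation is bit-reproducible for a given spec and seed.

## Validation sizes

The validation grid is 96 phantoms (lateral slope ∈ {0, 4, 7, 12}°, medial
∈ {0, 5, 9, 15}°, coronal ∈ {0, 2}°, three seeds) at the protocol spacing;
the throughput check uses one isotropic 0.5 mm phantom (~240 slices over
both planes). These sizes exercise the full slope range reported for
healthy and ACL-injured populations while keeping a complete validation run
in the minutes range on a single CPU.

## Known limitations

* The tuberosity band and the superior search band are heuristics with
  config escape hatches; unusual anatomies (severe Osgood-Schlatter
  prominences, very short scans) may need adjustment.
* The outermost slice of a compartment is a thin sliver whose rim corners
  are heavily partial-volumed; its slope can be biased by a few degrees.
  It contributes 1/n to the compartment mean.
* Bone-dark sequences rely on the minority-class heuristic at the Otsu
  threshold; sequences where bone is not separable by one global threshold
  need an external mask (`--mask`).
* Coronal slopes inherit a per-slice geometric term when the medial and
  lateral facets differ strongly in sagittal tilt (the rim-to-rim line
  tilts with AP position); it cancels in the compartment mean for
  AP-symmetric plateaus.
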