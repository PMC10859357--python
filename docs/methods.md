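# Methods

## The involvement measure

The package quantifies how far a tumor wraps around a vessel as an angle
in [0, 360] degrees, computed purely from a 3D integer label volume and
its voxel spacing. For every 2D slice, along each of the three grid axes,
that contains at least one tumor voxel and one vessel voxel:

1. connected components of the vessel label are found in the slice
   (8-connectivity). A vessel curving through the volume may cross a
   plane several times; mixing those crossings would sum unrelated arcs,
   so each component is measured separately and the plane contributes the
   maximum over its components.
2. for each component, the outer boundary is extracted as a sub-pixel
   contour (marching squares at the 0.5 iso-level on the hole-filled
   mask) and its physical length *V* in mm is the component's
   circumference. Anisotropic in-plane spacing is respected by scaling
   each segment by the per-axis mm sizes.
3. the contact length *TV* is the summed length of the contour segments
   "in contact" with tumor (rule below). By construction *TV* ≤ *V*.
4. the plane's involvement is (*TV*/*V*) × 360 degrees.

The vessel's reported involvement is the maximum over all planes, with
the plane achieving it (the argmax plane) retained for inspection. A
vessel never sharing a plane with tumor reports exactly 0; a vessel with
no voxels at all is additionally flagged `absent`.

The degree formula has a second, "literal" mode, *TV*/(*TV*+(*TV*−*V*)) ×
360, retained for transparency because this algebraic form also circulates
for the measure. It is undefined at *TV* = *V*/2 (zero denominator,
reported as a degenerate-input error) and negative below half contact,
and agrees with the fraction mode only at the full-contact anchor
*TV* = *V* (both give 360). The fraction mode is the default and the only
mode consistent with an output range of [0, 360] and with sub-quarter
contact mapping into the 0–90° group; the literal mode exists so its
behaviour can be inspected rather than guessed at.

### Contour length estimator

Raw marching-squares polylines overestimate the circumference of digital
disks by 6–14 % for radii of 5–50 px (staircase excess at intermediate
edge orientations). The contour is therefore regularised with a circular
moving average of the closed vertex list, window 5 (a documented
constant), after which disk circumference is recovered to within 0.5 %
across that radius range. The smoothing preserves the vertex/segment
correspondence, so contact flags computed on the raw contour are applied
to the smoothed segment lengths, and the invariant *TV* ≤ *V* is exact.
The window is a compromise: window 3 leaves ~1–4 % bias, window 7
under-measures small components. Smoothing rounds genuine corners
(a 10×10 px square reads ~36.2 rather than 40 px), which is immaterial
for the convex, near-circular cross-sections the measure targets and for
the *ratio* TV/V that the degree actually uses.

### Contact rule

A contour segment is in contact under the default `across` rule when the
pixel directly across it — on the outside of the component, located by
probing half a pixel along the outward normal from the segment midpoint —
carries the tumor label. Because label masks are mutually exclusive,
tumor abuts rather than overlaps the vessel, and the across-pixel of a
boundary segment is exactly the first voxel the tumor can occupy. Probing
resolves diagonal (stair-step) abutment as well, because marching-squares
segments cut corners and their across-pixel is the diagonal neighbour.

A more tolerant `near8` rule additionally accepts tumor anywhere in the
8-neighbourhood of the inside boundary pixel. It is more forgiving of
ragged segmentation boundaries but smears the contact arc by roughly one
pixel at each arc end (about +6° per end at a 10 px vessel radius), which
is why it is not the default: on phantoms the `across` rule recovers wrap
angles within ±4° at 0.5 mm voxels, while `near8` systematically
overshoots small wraps.

### Component filters

Components below 4 px (configurable) are ignored — specks have
meaningless perimeters. Components without a single interior pixel (those
that vanish under a 3×3 erosion) are also ignored: one/two-pixel-wide
slivers arise where a plane grazes a vessel tangentially, their
"circumference" is twice their length, and their contact fraction is
dominated by rasterisation and noise; with segmentation-like jitter such
fragments otherwise read as near-total encasement. A cross-section with
no interior carries no circumferential information.

Components touching the image border keep their border segments in the
circumference but those segments can never be in contact (there is no
across-pixel); such measurements carry a warning in the report.

## Binning and staging

Continuous degrees are binned into the five radiological categories with
right-closed intervals — `0` (exact zero only), `(0, 90]`, `(90, 180]`,
`(180, 270]`, `(270, 360]`. Exact zero is kept distinct because the
rater scale has a dedicated "no contact" group.

Staging maps each vessel's degrees to a stage through its class rules
(default: CeTr/HA/SMA arterial, SMV/PV venous) and takes the worst vessel:
resectability criteria are defined per vessel, and one locally-advanced
grade vessel makes the case locally advanced. The bundled default table
encodes the DPCG scheme (arterial: 0 resectable, (0, 90] borderline,
> 90 locally advanced; venous: ≤ 90 resectable, (90, 270] borderline,
> 270 locally advanced) with the same right-closed boundary convention as
the binning, so arterial involvement of exactly 90° is borderline. Any
YAML table with the same schema can be substituted; validation rejects
gaps, overlaps or incomplete coverage of [0, 360]. Occlusion and stenosis
qualifiers that appear in published criteria are **not** evaluated — the
involvement input carries no such signal — and every decision carries
that caveat explicitly.

## Phantoms

The phantom generator is the package's validation instrument: it
rasterises straight (or helical) cylindrical vessels and tumor shells
that are annular sectors subtending an exact angle θ, abutting the vessel
surface with no gap or overlap beyond rasterisation. Ground truth
(angle, category, expected stage) is recomputed from θ through the public
binning/staging operations, never stored independently.

Default geometry: 96³ voxels at 0.5 mm isotropic, vessel radius 5 mm,
shell 3 mm, wrap band 20 slices — comparable to SMA caliber at CT-like
resolution, quantifiable in under a second. Two geometric choices matter:

- **vessels run the full volume length** while the wrap covers a 20-slice
  band. If vessel and wrap were co-extensive, longitudinal near-tangent
  planes would see thin sliver cross-sections with tumor along an entire
  long edge and read ~180° for *any* θ > 0; the long vessel dilutes those
  planes so the transverse planes, which measure θ directly, dominate.
- **the wrap is centred on the in-plane diagonal by default** (start
  angle 225° − θ/2, overridable). A sector edge exactly tangent-aligned
  with a grid axis is a degenerate configuration in which one tangent
  plane reads `band/(2L) × 360` (~37.5° at default geometry) regardless
  of θ; the diagonal position is the generic case. This tangent-plane
  floor is a real property of the circumference-based sweep, inherited by
  any implementation of it, and is documented rather than hidden: with
  axis-tangent wrap placement, small wraps are over-read.

Optional jitter emulates segmentation noise: every boundary voxel of
every structure toggles membership (structure ↔ background, never between
structures) with probability 0.1, from a seeded generator; identical spec
and seed give voxel-identical volumes. What the phantoms do *not* emulate:
irregular tumor margins, branching or deformed vasculature, partial-volume
effects, inter-slice misregistration, or systematic segmentation bias.
Passing phantom tests therefore demonstrates the geometry engine is
correct and noise-tolerant, not that clinical agreement will reach any
particular level.

## Evaluation statistics

Agreement is the fraction of records where the model's binned category
equals the rater's, optionally stratified (arteries vs veins by default).
Group summaries report median and quartiles of the model's continuous
degrees within each rater category; quartiles use linear interpolation
between order statistics (the convention is a documented constant). The
one-way ANOVA uses the classical between/within decomposition with the
p-value from the F distribution; with zero within-group variance and
unequal means the result is degenerate and reported as F = ∞, p = 0. The
0.05 significance threshold is conventional reporting, never a branch in
any decision logic.

## Validation suite sizes

The shipped tests and the acceptance script use: nine wrap angles
(30–360°) at 0.5 mm and 0.25 mm; digital disks r = 5–50 px; exhaustive
staging truth tables (5⁵ combinations); all six axis permutations; 50
(tests) / 30 (script) jittered five-vessel phantoms with wrap angles
drawn per category away from bin edges — boundary angles are inherently
ambiguous under categorical ground truth at finite resolution; and one
helical stress case. These sizes keep the full suite around a minute on
one CPU while exercising every category and stage.

## Known limitations

- Occlusion/stenosis are not detected; published criteria would grade an
  occluded vein as 360° regardless of geometric contact.
- The measure follows the vessel cross-section circumference, not a
  centerline; strongly deformed or obliquely cut vessels can be over- or
  under-read (the helical phantom bounds this for gentle curvature).
- Plane sweeps use the stored grid axes; no reorientation to anatomical
  axes is attempted. The degree is a within-plane ratio and the maximum
  over three orthogonal sweeps is rotation-robust (tested to ≤ 2° under
  grid permutations), but oblique acquisitions are measured in their
  native grid.
- Label masks are taken at face value; segmentation quality bounds
  measurement quality.
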