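# Methods

`astromigrate` quantifies how astrocyte progenitors move through the
developing cerebral cortex in time-lapse slice imaging: how fast and how
erratically they migrate, whether they travel along blood vessels, and
where they settle across the depth of the cortical plate (CP).  Because no
public dataset accompanies the analyses it implements, the package ships a
seeded synthetic generator that emulates the imaging inputs; every analysis
stage is validated against that generator and against independent oracles
(brute-force scans, analytic geometry, reference statistical
implementations).

## Coordinate conventions

All coordinates are physical micrometres in a right-handed frame: +y points
radially toward the pial surface, x is the mediolateral in-slice axis, and
z is the imaging depth.  Intensity arrays are indexed (Z, Y, X), 0-based,
and the centre of voxel *i* lies at `(i + 0.5) * voxel_size` per axis, so
physical-index round trips move a point by at most half a voxel.  Intervals
are half-open.  One fixed convention avoids sign errors in the
hemisphere-dependent statistics below.

## The synthetic slice model

`SimulationConfig` holds the study conditions; its defaults describe a
single imaged field:

| parameter | default | meaning |
|---|---|---|
| `field_size_um` | (300, 300, 50) | X, Y, Z extents; Z matches a ~50 um merged projection of a thicker slice |
| `frame_interval_h` | 0.25 | acquisition cadence, constrained to the 10-30 min range typical of slice time-lapse |
| `duration_h` | 24 | observation window |
| `erratic_speed_mean_umh` / `_sd` | 30 / 10 | lognormal per-frame speeds of erratic walkers |
| `erratic_turn_sd_deg` | 60 | wrapped-normal turning dispersion (a calibration choice; no measured value exists) |
| `erratic_drift_umh` | 3 | constant surface-ward (+y) velocity component |
| `radial_speed_mean_umh` / `_sd` | 12 / 4 | slower, directed migration |
| `radial_turn_sd_deg` | 10 | heading noise around +y |
| `vessel_guided_speed_umh` | 15 | crawling speed along a vessel axis |
| `attach_prob_per_frame` / `detach_prob_per_frame` | 0.3 / 0.02 | capture and release rates of the vessel-bound state |
| `capture_radius_um` | 5 | distance to a capsule surface within which capture can occur, matching the association threshold |
| `vessel_n_segments` / `vessel_radius_um` | 30 / 2 | capsule network; ~0.7% volume fraction of the default field |
| `vessel_radial_bias` | 0.7 | probability a segment is oriented within 30 degrees of +y |

**Vessel networks** are straight capsules (cylinder + hemispherical caps).
Each segment is radial (axis within 30 degrees of +y, sampled uniformly on
the spherical cap) with probability `vessel_radial_bias` and sampled from
the complement of that cone otherwise, so the realized radial fraction is
exactly Binomial(n, bias).  Segment lengths are uniform on 25-60% of the
smaller in-plane extent; endpoints are clamped one radius inside the field
so the whole capsule surface, where guided cells sit, stays in bounds.

**Erratic walkers** carry a planar heading updated by wrapped-normal turns,
a lognormal speed per frame (parameterized by arithmetic mean and SD), a
constant +y drift, and a small z jitter (SD 0.5 um/frame); positions
reflect at the field walls.  This is the simplest process that is fast,
weakly persistent, and drifts surface-ward.  **Radial walkers** re-draw
their heading around +y each frame with small noise; with zero noise they
are exactly straight surface-ward lines.  **Vessel-guided agents**
alternate between an attached state — sitting exactly one radius from their
segment's axis (on the abluminal surface, at a fixed azimuth) and crawling
along it at constant speed — and a detached state in which they move like
erratic walkers.  Detachment occurs stochastically per frame or on running
off a segment end; re-attachment requires being within `capture_radius_um`
of a capsule surface and succeeding a per-frame Bernoulli trial, after
which the position projects to the nearest surface point.  The attached
flag per sample is the ground-truth contact label used to validate the
classifier.

**Nuclei** are uniform over the field and stand in for a non-selected
DAPI-stained reference population.  **Rasterization** renders the vessel
channel as the union of capsules (voxel centre within one radius of an
axis), and cells as isotropic Gaussian blobs whose sigma is chosen so the
half-max isosurface encloses the requested cell volume
(`sigma = (3V/4pi)^(1/3) / sqrt(2 ln 2)`); a `marker` channel repeats the
blobs with independent noise, emulating an astrocyte-marker co-stain.
Additive Gaussian noise (`noise_sd`, default 1 at amplitude 100) is applied
per channel.  Every generator is a pure function of the config seed;
sub-streams are derived with `SeedSequence` spawn keys so, e.g., the
network does not change when the cell count does.

What the generator does *not* emulate: photobleaching, a realistic PSF,
anisotropic blob shapes, cell division within tracks, vessel growth, or
curved cortical geometry.  Passing tests therefore certify the measurement
code and its calibration on idealized inputs — not performance on real
movies, where segmentation quality and tissue curvature dominate.

## Trajectory statistics

Directions and turning angles are computed in the slice plane (x, y) only,
because traces are drawn on merged projections; speeds use the full 3D
displacement by default (`use_z=False` gives the planar variant, and the
pipeline reports both).  A frame enters the angular statistics only when
its speed strictly exceeds the gate (default 10 um/h) — the "more than"
reading makes every threshold in the package strict (>10 um/h, >20 um,
>6,000 um^3).  Zero-displacement steps carry no direction and are excluded
from angular statistics but counted in the outputs.

* **Turning angles**: signed difference of consecutive gated step
  directions, wrapped to (-180, 180]; intervening sub-gate frames are
  skipped, not interpolated.  The sign is negated in the left hemisphere so
  positive always means "rightward in the right hemisphere / leftward in
  the left".  Whether the original analysis used signed angles or compass
  bearings is not stated anywhere; the signed convention here is a
  documented choice.
* **Angles to the radial axis**: signed angle between a gated step and the
  per-field radial axis, lateral positive / medial negative, with lateral
  defined as +x in the right hemisphere and -x in the left.  The radial
  axis is a configuration input per field (in curved tissue it was
  determined visually per cell; that is out of scope here).
* **Polar summaries**: net in-plane first-to-last displacement and its
  radial-referenced direction; a closed loop has distance 0 and an
  undefined (flagged) direction.
* **Motility filter**: a track is motile iff its maximum displacement from
  the starting position within the first 24 h strictly exceeds 20 um.
* **Speed comparisons** use Welch's t on gated frame speeds, with the
  box-plot descriptives described under *Statistics*.

## Vessel association

`build_vessel_mask` thresholds the vessel channel, removes connected
components below `min_component_voxels` (default 8), and reconstructs the
mask: the surface is every occupied voxel with an empty 6-neighbour (the
array border counts as empty), and the skeleton is the 3D medial axis.
skimage's 3D thinning annihilates tubes of even symmetric voxel diameter;
for any component left skeleton-less the package substitutes the ridge of
the interior distance transform (the discrete medial locus).  The skeleton
is retained for QC only — all distances are measured to the surface.

Two distance notions are deliberately distinct:

* **Centre-to-surface distances** (`nearest_vessel_distance`) are Euclidean
  distances in physical um from a centroid to the nearest *surface-voxel
  centre* (KD-tree query; exact equality with a brute-force scan over all
  surface voxels is a tested invariant).  Centroids inside the occupancy
  get distance 0.  No sub-voxel interpolation is attempted; the natural
  tolerance of geometric assertions is half the voxel diagonal.  The
  distance transform path is anisotropy-aware throughout (per-axis voxel
  sizes).
* **Contact classification** (`classify_track_contacts`) asks whether a
  point overlaps the rasterized vessel: the background EDT is sampled at
  the exact point position by trilinear interpolation and half the voxel
  diagonal is subtracted (clamped at zero) to account for the occupied
  voxel's extent.  A point on the capsule surface therefore scores
  distance 0, and the default `contact_tolerance_um = 0` reproduces the
  "fused signals" overlap heuristic at voxel resolution.  The tolerance is
  exposed because that heuristic, not a distance rule, defined fusion in
  the original workflow.

**Edge exclusion** marks (never deletes) records within 15 um of either Z
face or within 20 um of any XY border, because a nearer vessel could lie
just outside the imaged volume; Z is checked first when both apply.  The
**association fraction** is the share of included cells strictly closer
than 5 um, with a 2.5-um histogram for peak inspection.  Its null model is
analytic: for uniform points, the expected fraction equals the volume
fraction of the 5-um-dilated capsule union, which the package computes by
Monte Carlo over the exact segment geometry (overlaps handled correctly).

**On-vessel persistence** selects tracks with a contiguous on-vessel run of
at least 5 h and reports their maximum distance from the start over the
whole observation.  The **off/on ratio** per field counts only tracks
traceable at least 10 h and calls a whole track "on" when the majority of
its frames are labelled on — a per-track aggregation rule the source
workflow leaves unstated; sensitivity to it can be probed by varying
`contact_tolerance_um`.  Fields without on-cells yield a flagged undefined
ratio, not infinity.

## Cortical depth distribution

Detection multiplies the reporter and marker channels voxelwise in float64
(never wrapped), thresholds the product, labels 26-connected components,
and keeps components that contain at least one local maximum of the product
and strictly exceed 6,000 um^3 in physical volume; centroids are
product-weighted.  The product threshold is a required parameter with no
canonical default.  For blobs rendered at amplitude A in both channels, a
product threshold of A^2/4 recovers the single-channel half-max isosurface
(the product of two Gaussians halves the effective variance), which is how
the synthetic fixtures and the demo pipeline choose it.

Relative depth projects each centroid onto the depth axis (the negated
radial axis) and maps it affinely so the upper (pial-side) CP border is 0
and the lower border is 1; out-of-range cells are flagged and excluded from
binning.  Bins are equal-width (four by default, bin 1 most superficial),
half-open with the last bin closed, so a depth exactly on an internal edge
falls in the deeper bin; counts always sum to the number of in-range cells.
Borders are straight lines per field.  Group comparisons of per-brain bin
fractions use Dunnett (against a control) or Tukey tests with the brain as
the unit of analysis; single-brain groups are rejected for inference.

## Statistics

`run_test` exposes exactly the tests the conventions require — Student's
and Welch's t, Mann-Whitney, Dunnett, Tukey's HSD, and Kruskal-Wallis-gated
Dunn comparisons — with no silent auto-selection; an F-test variance gate
(two-sided, alpha 0.05) is reported to guide the t-test choice but never
applied automatically.  All p-values are two-sided.  Every report carries
n, mean, SD, SEM, median, quartiles, and whiskers at exactly 1.5x the
interquartile range beyond the quartiles, plus the star mapping *, **,
***, **** at 0.05, 0.01, 0.001, 0.0001.

Dunnett adjusted p-values are computed by deterministic quadrature: in the
standard representation T_j = (lambda_j Z0 + sqrt(1-lambda_j^2) Z_j)/W with
lambda_j = sqrt(n_j/(n_j+n_0)) and W the scaled chi variate, conditioning
on (Z0, W) factorizes P(max|T_j| <= q) into a product of normal CDFs; the
Z0 integral uses 96-node Gauss-Hermite and the W integral adaptive
quadrature.  Agreement with a high-accuracy deterministic reference
integrator (R `mvtnorm::pmvt`, TVPACK) is ~1e-12, and repeated calls are
bit-identical — the reason this path is preferred over randomized
quasi-Monte-Carlo integration.  Dunn's post hoc uses pooled mid-ranks with
the tie correction and Bonferroni adjustment over the comparison family
(the adjustment is recorded in the report, since the named software
behaviour it mirrors does not document one).  Tukey p-values come from the
studentized-range distribution via `scipy.stats.tukey_hsd`.

Units of analysis follow the display: per-frame or per-cell for
distribution plots, per-brain for group inference; every report states its
unit.

## Verification scale and numerical choices

The test suite and `scripts/acceptance.py` run the whole chain at desk
scale, chosen so the full suite completes in well under a minute of compute
per module: 64^3 fields with up to 5 segments for the distance oracle
(50 instances x 200 centroids), 100 tracks per mode over five seeds for
contact recovery, 20 seeded replicates for each statistical-power property
(speed Welch, angle Mann-Whitney, depth-shift Dunnett), 10,000 uniform
nuclei against a 400,000-sample Monte-Carlo analytic fraction, and 20
constructed detection fixtures.  The depth-shift analog lowers the
superficial placement probability from 0.4 to 0.2 over 10 brains x 100
cells per group; with four equal bins its expected bin-1 fraction equals
the placement probability exactly, so the designed drop is recoverable
without detection noise.

The adhesion perturbation analog scales attach and detach probabilities
together — (1.0, 0.01), (0.5, 0.05), (0.1, 0.15) — because receptor loss
both hinders capture and promotes detachment, and because the median
included distance is bimodal (attached cells sit at ~0, detached cells at
the field-typical vessel distance): attach-only doses can leave the median
saturated.  Each dose pools three independently drawn vessel networks so
the comparison samples fields rather than one layout.

Degenerate inputs are handled explicitly rather than silently: empty vessel
masks are valid but make distances an error; empty track sets, zero
included records, single-brain groups, zero-variance variance gates, and
out-of-bounds centroids all raise or flag with a reason.  Ties at
thresholds follow the strict inequalities above; the internal-edge tie in
binning goes deeper; a zero-length step has no direction.

## Known limitations

* Straight capsules cannot represent curved or branching vessels; branch
  points exist in the rasterized union but not in the geometry model.
* Contact classification at voxel resolution cannot distinguish touching
  from sub-voxel gaps; agreement with ground truth is ~96-97%, not 100%.
* The erratic-walk turning dispersion is a calibration choice, not a
  measured quantity; conclusions that depend on its exact value should be
  re-examined per dataset.
* TrackMate XML support covers the spots+edges dialect with physical units;
  pixel-calibrated exports are rejected rather than converted.
* The depth analysis assumes straight CP borders per field and does not
  model cortical curvature.
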