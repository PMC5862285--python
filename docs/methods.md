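# Methods

This note records the models, conventions and numerical choices behind
embryotk, and what the synthetic phantoms do and do not establish about
behaviour on real scans.

## Coordinate and file conventions

Volumes are arrays indexed `(z, y, x)` — slice, row, column — with physical
spacing in micrometres per axis. On disk, NRRD `sizes` and `spacings` run
fast-to-slow `(x, y, z)` per the format; since a C-ordered `(z, y, x)` array
already stores x fastest, only the header order is reversed at the I/O
boundary and payload bytes are never permuted. Payloads are little-endian
always; big-endian files are converted on read. Supported sample types are
uint8, uint16 and float32, and a round trip never silently promotes them.
Raw, gzip and bzip2 encodings and attached/detached headers are all read;
the writer defaults to raw, with bzip2 behind a `compress` flag since
compression exists to save upload bandwidth, not as a universal default.
Slice stacks are ordered by natural-numeric filename sort (`s2` before
`s10`) because scanners emit unpadded indices; colour slices are rejected
rather than converted — the pipeline is strictly grey-scale.

## Autocrop

The crop box comes from a robust maximum intensity projection along z:
intensities above the `1 − clip_fraction` quantile (default
`clip_fraction = 0.001`) are clipped to that quantile before projecting.
"Robust" matters because a handful of hot voxels otherwise dominate the MIP,
drag the Otsu threshold up and shrink the box onto the artefact. The Otsu
threshold is computed on a fixed 256-bin histogram of the projection
regardless of bit depth (determinism across modalities); the returned value
is the bin **edge** maximizing the between-class variance, ties broken
towards the lowest edge. Equal-variance plateaus occur where histogram bins
are empty; any edge inside a plateau induces the identical
foreground/background split, which is the quantity the tests compare.

The in-plane (y, x) box is the tight bounding rectangle of above-threshold
projection pixels, dilated by `padding` (default 16 voxels) and clamped;
z-cropping is an explicit opt-in using a second projection along y with the
same threshold. An empty foreground raises an error instead of silently
returning the full volume, so batch logs surface the scans that need a
manually drawn rectangle. Otsu operates on the projection rather than the
volume histogram: it is cheaper, and matches the manual-crop interaction
where the user draws on the very same projection.

## Resampling

Binning averages non-overlapping `factor³` blocks (the standard CT
convention; sum and decimation were the alternatives, mean preserves the
intensity scale) and drops trailing partial blocks — floor semantics keep
every output voxel a mean of a full block. Resampling treats voxels as
cell-centred: output sample i of an axis sits at physical `(i + 0.5)·ts`,
mapped to input index `(i + 0.5)·ts/s − 0.5`, so the physical extent is
preserved to within one voxel per axis. Interpolated grey values are rounded
half-to-even and clipped to the dtype range. Label maps must be resampled
with nearest-neighbour interpolation; asking for linear raises an error
because interpolated label ids are anatomy that does not exist.

## Watershed candidate series

The engine produces a *nested* series of candidate segmentations:

1. Gradient magnitude of the intensity volume, Gaussian-smoothed with a
   sigma given in micrometres (converted to per-axis voxel sigmas), central
   differences scaled by spacing.
2. Foreground mask: Otsu on the intensity volume, connected components
   below 27 voxels removed (noise speckle), interior holes filled — dark
   fluid-filled structures (lumens, ventricles) belong to the specimen and
   must remain segmentable.
3. One base watershed of the gradient from its regional minima, restricted
   to the mask, 26-connectivity.
4. For each requested level ∈ (0, 1]: merge adjacent base regions whose
   saddle depth — the minimum pass height on their shared boundary minus
   the deeper of the two basin minima — is ≤ level × (foreground gradient
   dynamic range), via union-find over a static edge list.

Because the merge criterion is a static per-edge quantity and the edge set
grows monotonically with level, the candidates are strictly nested: region
boundaries at a higher level are a subset of those at a lower level and the
region count never increases. A plain re-run of h-minima watershed per level
would not guarantee this. At level 1.0 every edge qualifies, so a connected
foreground collapses to a single region.

Annotations (`level`, `region_id` → target label + name) are applied in
order with last-writer-wins, supporting the coarse-then-refine workflow:
annotate a coarse body region first, then overwrite organ interiors from
finer candidates. Scripted edits (relabel / delete / rename) stand in for
the manual curation pass a human would do in a viewer.

## Atlas tools

The population average is the voxelwise arithmetic mean in float32 of
registered volumes sharing grid and spacing; a mismatch raises an alignment
error since it signals unregistered inputs.

Displacement fields are pinned to one convention, because "apply the inverse
transform" underdetermines it: the field lives on the **target** grid, the
vector at voxel index v is `(dz, dy, dx)` in micrometres, and the propagated
label at v is the atlas label at the voxel nearest to
`v·spacing + d(v)` (pull-back). Out-of-bounds samples map to background.
Nearest-neighbour sampling is mandatory for labels, which also guarantees
propagation can never introduce a label id absent from the atlas.

Organ volumes are exact voxel counts × voxel volume (mm³). A Jacobian-
integrated volume would weight each voxel by the local volume change of the
registration; voxel counting after propagation was chosen as the direct
measurement on the propagated map, with Jacobian integration a possible
extension. Wild-type/mutant tables are joined over the union of labels; a
label missing on one side contributes 0, and the ratio is reported as NaN
where the wild-type volume is 0 rather than inventing a number.

## Heatmap analytics

Significant-region extraction labels the positive and negative voxels
*separately* with 26-connectivity and never merges across a shared +/−
boundary: local expansion and shrinkage are opposite effects, mirrored in
the red/blue display convention. Connectivity is configurable to 6 for
sensitivity checks. Components below `min_voxels` (default 5, overridable
to 1 — subtle phenotypes may be a handful of voxels) are dropped; records
are sorted by voxel volume descending with deterministic tie-breaks on the
bounding-box corner. A region's "position" is the integer midpoint of its
bounding box — the navigation target a slice viewer jumps to — with the
centroid also emitted. Vector filtering zeroes vectors below a Euclidean
magnitude threshold and decimates the grid by an integer stride, scaling
spacing accordingly. Overlays map positive t to a dark-red→red→yellow ramp
and negative t to its blue mirror, deliberately stopping short of white so
the strongest effects remain unambiguously coloured, alpha-blended (default
0.7) over the normalized greyscale average.

## Batch runner

Jobs run strictly in sequence; one failure marks that job failed and the
queue continues. Outputs are written to a temporary file and atomically
renamed, so an interrupted or failed job leaves no partial NRRD. Resume
detection stores a sha256 of the input content (file bytes, or sorted
name+bytes for a slice directory) in the output header and skips a job only
when the stored hash matches the current input. The output layout is
`<root>/<centre>/<procedure>/<allele>/`, with the allele parsed from the
`DATE_ALLELE_ZYGOSITY_SEX[_EXTRA…]` filename convention (strict vocabularies:
YYYYMMDD; het/hom/wt; XX/XY/ND; extra tokens preserved opaquely).

## Phantoms: what they emulate, and what they do not

Phantoms are a body ellipsoid containing nested organ ellipsoids at distinct
intensities plus additive Gaussian noise, clipped to the dtype. Ellipsoids
were chosen over meshes because their volumes are closed-form, which turns
accuracy checks into analytic oracles: crop-recovery against the known body
mask, voxel counts against 4/3·π·rz·ry·rx, volume ratios against
`(1 + α)^−3` for a locally linear radial field. Everything is a pure
function of (spec, seed); identical inputs are byte-identical outputs.

Default conditions: voxel spacing 14 µm (micro-CT-ish), 8-bit intensities,
body ≈ 90 grey over background ≈ 10. The robustness sweep draws random body
pose (centre, radii, rotation), intensity 130–220 and noise sd up to 10% of
the specimen-to-background dynamic range. The 5-organ segmentation phantom
uses organ radii ≥ 5 voxels and organ-to-body contrast of 45 grey at noise
sd 15 — i.e. contrast exactly 3× noise, the averaged-volume regime the
watershed engine is meant for — with one organ darker than the body standing
in for fluid-filled structures. The 10-organ preset names the structures of
a mid-gestation (E14.5) embryo atlas (liver, lungs, kidney, adrenal gland,
stomach lumen, lateral brain ventricle, mesencephalic vesicle, dorsal root
ganglia, trigeminal ganglion, humerus primordium) for composition and
documentation examples.

What phantoms do **not** model: beam hardening, ring artefacts, partial-
volume blur at organ boundaries, intensity inhomogeneity, anatomical
variability, or realistic organ shapes. Passing tests therefore establish
the correctness of the algorithms and conventions, and the achievable
accuracy under idealized contrast — not segmentation accuracy on real
embryos, which depends on staining and averaging quality.

## Problem sizes and tolerances

Test and acceptance problem sizes are chosen for thorough coverage at
interactive runtimes: phantoms 40–80 voxels per side, 1000 round-trip
volumes of 2–12 voxels per side, 200 Otsu images, 100 sparse heatmaps of
24³, 50 autocrop phantoms of 56³, 20 watershed phantoms of 40³, 16-volume
averages of 80³. Numerical tolerances: binning and grey rounding within 0.5
grey (half-even rounding), bin-composition within 1 grey, population-average
residual sd within 10% of σ/√n, organ-volume ratio within ±0.05 of the
engineered value (voxelization error ~3% at these radii), region mean-t
within 1e-6 of the flood-fill oracle. The autocrop idempotence check fixes
the threshold and disables quantile clipping, under which cropping is
exactly idempotent; with a re-estimated threshold the box may legitimately
move by a voxel as the histogram changes.

## Known limitations

* The watershed base over-segmentation can be large on very noisy volumes;
  merge levels are fractions of the dynamic range, so heavy outliers in the
  gradient compress the usable level scale.
* `region_count` fits uint16; volumes producing more than 65535 base
  regions are rejected rather than relabelled.
* Binning drops trailing partial blocks; callers who need every voxel
  should pad first.
* Displacement fields are assumed smooth at the voxel scale; nearest-
  neighbour label pull-back aliases fields with sub-voxel structure.
* The queue is strictly sequential by design; parallelism would be an
  extension (jobs are independent and order-preserving in the contract).
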