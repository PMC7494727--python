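# Methods

## Imaging model and conventions

A reconstructed micro-CT scan is treated as a 3D scalar grid with
per-axis physical spacing in mm, indexed `(slice, row, column)` with
slice 0 the first file in sorted order. Intensity is assumed to
increase with material density: air < clay support < chalky endosperm
< sound endosperm. Chalky endosperm is air-pocketed, hence less dense
and darker than sound endosperm, which is what makes it separable by
intensity alone. Scanner exports with inverted polarity are handled by
`invert=True` on the readers (`--invert` on the CLI).

Voxel spacing is taken from DICOM attributes (PixelSpacing,
SpacingBetweenSlices falling back to SliceThickness) or supplied by the
caller for plain image stacks; typical scan resolutions for this
application are 2.5–15 µm. All volumes are reported in mm³ as voxel
count × voxel volume — exact for the masks the pipeline produces, and
checkable against closed forms for rasterized solids. Surface-mesh
integration would differ by sub-voxel amounts and is deliberately not
used.

## Phantom generator

The phantom emulates a high-throughput scan of milled rice pressed
into a block of low-density modelling clay: ellipsoidal grains
(pairwise clearance ≥ 2 voxels, enforced), an axis-aligned clay box
surrounding them, and optional interior chalky inclusions. The
class-level image (default intensities 0 / 40 / 110 / 200 on an 8-bit
scale; the strict ordering is validated) is Gaussian-blurred
(`blur_sigma_mm`, converted to voxels per axis) and corrupted with
i.i.d. Gaussian noise (`noise_sd`), both defaulting to 0. Ground truth
— per-grain label map, chalk mask, clay mask, per-grain true volumes —
is the pre-blur, pre-noise rasterization, so truth is invariant to the
degradation parameters.

Rasterization is by voxel-center inclusion: a voxel belongs to an
ellipsoid iff its center satisfies the rotated ellipsoid inequality.
This makes brute-force enumeration an exact oracle and keeps volume
errors below 1% once a solid spans ≳ 40 voxels per axis.

Chalk inclusions come in two shapes. `centered_ball` is an idealized
white-core: a sphere at the grain center (must fit strictly inside).
`blob` produces the amorphous shapes real chalk takes: seeded Gaussian
noise smoothed to a chosen correlation length is thresholded at the
quantile matching the target volume fraction, restricted to the grain
eroded by one voxel, and the largest connected component is kept, with
enclosed cavities filled. The quantile is bisected (up to 20
iterations) until the component is within ±10% of the target. Because
the largest-component size can jump discontinuously when raising the
threshold splits off a branch, the ±10% window can fall inside such a
jump; the generator then trims the smallest overshooting component to
the exact target by priority region growing in descending field order
(connected by construction). Only a grain whose eroded interior is
smaller than the target raises `target fraction unattainable`.

**Default study conditions** (`multigrain_spec`): 10 grains, 4 chalky,
10 µm isotropic voxels, clay block present, no blur, no noise. The
default grain is a miniature ellipsoid with semi-axes 0.5 × 0.22 ×
0.20 mm — the ~2.3 length/width aspect ratio of indica rice, long axis
in-plane, minor diameter 40 voxels. A grid holding 10 real-size
(4–7 mm) kernels in a ~2 cm clay block at 10 µm would run to thousands
of voxels per axis; the miniature geometry preserves everything the
segmentation exploits (class structure, interiority of chalk, grain
separation) at a few-second generation cost, and every dimension is
overridable for full-scale runs. The default chalk fraction is 15% of
the grain volume so that planted inclusions stay above the 0.01 mm³
chalky-grain cutoff even at the blob generator's −10% tolerance.

What the phantom does **not** model: CT reconstruction physics (ring
and beam-hardening artifacts, cupping), partial-volume weighting at
surfaces beyond Gaussian blur, grain embryo anatomy, husk, or touching
grains. Passing recovery tests on phantoms therefore demonstrates the
correctness of the measurement chain, not robustness to every real
scanner artifact; real scans with strong artifacts may need manual
threshold bands.

## Segmentation pipeline

`segment_sample` runs: solid-band threshold → morphological cleanup
with 3D hole filling → grain instance labeling → per-sample chalk
extraction.

**Solid band ("auto").** A single binary Otsu cut on the full
intensity histogram (256 bins over the observed range), upper end the
volume maximum. A multi-level (4-class) cut was considered and is
available as `auto_threshold(volume, 4)`, but with noise it spends
cuts subdividing the dominant background: in an embedded-grain volume
the clay and air classes hold millions of voxels while chalk holds
well under 1%, and Otsu's count-weighted objective prefers splitting a
large class's noise spread over isolating a tiny class. The binary cut
robustly lands above the support material — between clay and chalk or
between chalk and endosperm. In the latter case chalky voxels drop out
of the solid mask, but chalk is interior to the grain, so the
mandatory 3D hole filling at the grain stage restores them to the
grain region; this is also why the classical workflow dilates and
fills holes after thresholding. Otsu cuts returned by the histogram
search are snapped to the midpoint between the nearest observed
intensities on either side, so on well-separated classes cuts fall
strictly between class values instead of on a bin center.

**Hole filling** is 3D and global: background components (6-connected,
the complement of the 26-connected foreground default) with no voxel
on the grid border become foreground. Chalk cavities and grain cracks
are 3D structures; per-slice filling would miss channels that escape
through neighboring slices.

**Grain labeling.** 26-connected components (robust to thin diagonal
bridges at coarse resolution; 6-connectivity selectable), components
below `min_grain_voxels` (default 500) discarded, survivors renumbered
1..N by descending voxel count with ties broken by first voxel in scan
order. The size filters replace the interactive mask-editing step of a
manual workflow. Touching grains are not split (the phantom enforces
clearance; watershed splitting is out of scope).

**Chalk band ("auto").** A 2-class Otsu cut computed on grain voxels
only — restricting to the grain makes chalk a non-negligible class —
with the volume minimum as the lower end: chalk is everything darker
than the chalk/endosperm cut inside the grain. An optional linear
contrast window (`center`, `width`, output [0, 255] floating point,
midpoint → 127.5, no quantization) can be applied first. The chalk
mask is intersected with the grain region, components below
`min_chalk_component_voxels` (default 30) are dropped, morphological
closing (ball radius `morph_radius_voxels`, default 0) and hole
filling are applied, and the result is re-intersected with the grain —
the subset invariant `chalk ⊆ grain` is asserted on every call. A
uniform (chalk-free) grain returns an empty mask rather than forcing a
degenerate cut.

Threshold bands are closed (`lo ≤ x ≤ hi`) so results are bit-exact
and order-independent.

## Metrics

* `CD-3D = 100·VC/VG`, volumes by voxel counting; errors for `VG = 0`
  or `VC > VG`. Reports print one decimal (full precision kept
  internally).
* `CD-2D`: union (any-voxel) projection of chalk and grain along one
  axis, pixel-count ratio. The default axis is the grain's
  smallest-bounding-box-extent axis, emulating a camera above a grain
  lying flat.
* Chalky rice rate: percent of grains whose chalk volume reaches
  `min_chalk_mm3` (default 0.01 mm³ ≈ 80 voxels at 5 µm). The rate is
  defined per grain, not per cross-section; national standards grade
  by visual area classes, which is out of scope, so the cutoff is a
  plain exposed volume threshold.
* Grain length/width: the slice with maximum grain cross-section area
  is found, a slab of `k_slices` (default 15) cross-sections centered
  there is union-projected, and on that plane length = maximum Feret
  (caliper) diameter between occupied-pixel centers, width = maximum
  extent perpendicular to the length axis. The slab makes the
  measurement robust to grains whose long axis is not exactly in one
  cross-section plane. Degenerate (single-pixel or one-pixel-wide)
  regions fall back to pixel-corner points so nonempty regions always
  have length ≥ width > 0. Pixel-center measurement recovers ellipse
  extents within ~1 px and is rotation-stable within 2 px.

## Numerical and degenerate-input choices

* Ties in the maximum-section search and in label ordering resolve to
  the smallest index — deterministic across runs.
* `auto_threshold` raises `degenerate histogram` on constant volumes;
  `segment_sample` converts this to `no grains detected` (an all-air
  volume is single-valued). An air-only volume *with* noise is not
  detectable by an unattended histogram cut — Otsu will split the
  noise — and is guarded only by `min_grain_voxels`; this is a known
  limitation of automatic thresholds.
* Blob generation, phantom noise, and all CLI runs are deterministic
  given their seeds; reruns produce byte-identical stacks and reports.
* Problem sizes in the test suite and acceptance script: the recovery
  benchmark uses the default 10-grain miniature phantom
  (57 × 268 × 440 voxels ≈ 6.7 M); oracle equivalence uses 100 random
  20³ masks; geometry checks use spheres/ellipsoids of 30–75 voxel
  radius. These sizes were chosen so the full chain, including the
  pure-Python oracles, completes in minutes on one CPU while keeping
  every grain ≥ 40 voxels across its minor diameter.

## Known limitations

* No watershed splitting of touching grains; scans must keep grains
  separated (the clay-embedding protocol does this physically).
* DICOM reading covers single-frame grayscale series with
  uncompressed/standard transfer syntaxes; multi-frame and compressed
  series are out of scope, as is DICOM writing.
* The 2D degree depends on the projection axis; for strongly
  non-convex chalk the smallest-extent-axis default may not match a
  particular photographic setup.
* Statistical comparison of 2D vs 3D values across kernels
  (significance testing) is out of scope; the package reports the
  per-grain metrics only.
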