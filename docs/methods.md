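# Methods

`ciliametry` measures primary cilia in 3D fluorescence microscopy
z-stacks: it segments a ciliary membrane-marker channel (e.g. Arl13b
immunostaining), detects cilium objects, measures each one — volume,
surface, span, intensity statistics, and a skeleton-based length — and
then pools per-condition measurement tables for quality control,
statistics and plotting. A phantom generator provides synthetic images
and tables with analytically known truth, which is how every stage of
the pipeline is validated.

## Phantom model

A synthetic cilium is a tube around a spline centerline. The centerline
is a natural cubic spline through control points, parametrized by
cumulative chord length; its arc length is computed by adaptive
quadrature of the speed and is the ground truth for the length
measurement (dense piecewise-linear resampling agrees to < 0.1%).
Random centerlines are gently curved (sinusoidal perpendicular offsets,
relative amplitude `curvature`, default 0.08) and rescaled until the
arc length hits a target drawn from the requested range.

Rendering mimics confocal acquisition:

- Geometry: every voxel whose center lies within the tube radius
  (physical, anisotropic distance) of the centerline is foreground.
- Optics: the scene is blurred with a separable Gaussian point-spread
  approximation, default sigmas (0.1, 0.1, 0.3) µm — roughly a 1.4-NA
  oil objective imaging a far-red dye. Because the axial sampling step
  (0.5 µm) is large compared to the tube diameter, the tube is rendered
  on a z-supersampled grid, blurred there, and then sampled at the
  slice centers. This is the band-limit-then-sample model of a real
  microscope: a tube passing between two slice centers contributes
  signal to both neighboring slices rather than vanishing. With all PSF
  sigmas zero the output is exactly the binary voxel-center
  rasterization (which the unit tests verify against a brute-force
  distance-to-segment oracle).
- Detection: a constant background offset (default 20) plus additive
  Gaussian noise with standard deviation `amplitude / snr`. `snr` is
  defined on the nominal foreground amplitude before PSF attenuation.

Defaults follow typical acquisition practice for cilia: voxel size
(0.08, 0.08, 0.5) µm (lateral pixel 0.05–0.1 µm, z-step 0.5–0.8 µm),
tube radius 0.25 µm, intensity 200 on a 16-bit scale. Centerlines keep
a margin from the grid faces (lateral 2r + 0.3 µm, axial r + 1.2 µm)
so that border-touching objects are constructed deliberately, never
produced by accident.

What the phantoms do *not* emulate: realistic (Gibson–Lanni) PSFs,
Poisson photon statistics (a flag could be added; Gaussian noise is
sufficient for threshold behavior), autofluorescent structures, nuclei,
or basal-body staining. Passing the recovery tests therefore
demonstrates correctness of the measurement chain under controlled
optics, not robustness to every real-world artifact.

Grouped measurement tables are generated separately: one folder per
condition, one TSV per replicate, values drawn from normal or lognormal
distributions with per-measurement location/scale and planted additive
effects. All tables carry a synthetic tool-version tag (default
"v0.1.7") so version-consistency checking can be exercised both ways.

## Segmentation (preparator)

Preprocessing is slice-wise: rolling-ball background subtraction
(radius in pixels, result clipped at zero) and 2D Gaussian smoothing.
Threshold selection runs on an intensity histogram — by default of the
maximum-intensity projection, mirroring how thresholds are chosen
manually on a projection; a full-stack histogram is available by
setting. Implemented methods: Otsu, Li (fixed-point minimum cross
entropy), Yen, Rényi entropy (three-order combination), Moments (Tsai),
Minimum (iterated 3-bin smoothing to bimodality), Shanbhag, plus manual
values. Foreground is intensity strictly above the returned integer
cut; criterion ties break toward the lowest qualifying bin.

Hysteresis segmentation takes a low and a high threshold (each a method
or value): the mask is the union of 26-connected components of the
low mask that contain at least one voxel above the high threshold, so
`mask(high) ⊆ result ⊆ mask(low)` always holds.

Two output styles: `keep-intensities` zeroes sub-threshold voxels
(background-removed image); `binary` sets supra-threshold voxels to the
maximum representable intensity. The output stack carries the segmented
channel first and, optionally, an unsegmented copy for intensity
quantification. Every run's settings and evaluated thresholds are
persisted in a plain-text metadata sidecar.

### Default recipe

The pipeline default is hysteresis with Yen as the low and Otsu as the
high threshold on the max-projection histogram, after Gaussian
smoothing with σ = 1.5 px. This was chosen by phantom validation: Otsu
alone occasionally splits a tube at axial-sampling intensity dips,
while Li as the low threshold collapses toward the background mode when
the foreground fraction is small (short cilia), ballooning the mask.
Yen remains stable across foreground fractions. These are defaults, not
dogma — threshold algorithms should still be compared per dataset.

## Morphometry (quantifier)

Objects are 26-connected components of the non-zero voxels of the
segmented channel. With "increase range" on (default), components
separated by a 1-voxel background gap are merged by labeling the
1-voxel-dilated mask and restricting labels to original foreground.
Objects below the minimum size are removed (`too-small`), as are
objects touching the first/last plane of any flagged axis (`border`);
every removal is reported with its reason. The suggested minimum size
scales inversely with the squared pixel size from the reference of 10
voxels at 0.1 µm/px, rounded up.

Per object:

- volume as voxel count and µm³ (exact product with the voxel volume);
- surface as the summed area of voxel faces not shared with the object
  (simple and exactly testable; a marching-cubes surface would differ);
- maximum span as the largest pairwise distance between voxel centers
  (convex-hull accelerated for large objects — exact, since the
  diameter is attained at hull vertices);
- intensity mean/SD (population)/min/max of the unsegmented channel
  within the mask, optionally also for additional channels A/B.

### Skeleton measures

The object mask (optionally closed to heal bridged gaps, optionally
blurred in XY with `gauss_xy_sigma` and re-binarized at 0.5 to smooth
noisy outlines) is thinned with 3D medial-axis thinning (Lee). The
skeleton voxels form a graph with edges between 26-neighbors, weighted
by the anisotropic physical step (`sqrt((ox·dx)² + (oy·dy)² +
(oz·dz)²)`).

- `tree_length` and `n_branches` are computed on the minimum spanning
  forest of that graph, which removes the redundant diagonal edges that
  26-adjacency creates at corners. A branch is a maximal chain between
  nodes of degree ≠ 2; a clean cilium has exactly one.
- `cilia_length` is the largest shortest path between any two
  endpoints (degree ≤ 1) of the full graph, Dijkstra with physical
  weights. Two corrections address digitization bias:
  1. *Chord subsampling*: summing per-voxel steps on an anisotropic
     grid overestimates oblique curves (every discrete z-jump replaces
     a gradual incline with a staircase). The selected path is summed
     as chords over every k-th voxel, k = ceil(max voxel size / min
     voxel size); on isotropic grids k = 1 and the chord sum equals the
     per-step sum exactly.
  2. *End-loss correction*: an ideal capsule's medial axis ends one
     local radius inside the mask tip, but discrete thinning retreats
     further. Each path end is extended by max(0, d_tip − r_local),
     where d_tip is the farthest axial mask extent in a forward cone
     from the end and r_local the anisotropic distance-to-background at
     the end voxel. The correction is exactly zero for an ideal capsule
     and for masks that are already thin skeletons, so it does not
     perturb the graph-level semantics the oracle tests check.
- `bending_ratio` is the straight end-to-end distance of the longest
  path (after extension) divided by `cilia_length`; 1 means straight.
  A single-voxel skeleton yields length 0 with undefined (NaN) bending;
  near-spherical stubs thin to ≤ 3 voxels and measure ≤ one voxel step.
- `orientation` is the unit end-to-end vector of the longest path.

On phantoms at the default acquisition settings (radius 0.25 µm, snr 5,
voxels 0.08/0.08/0.5 µm) this chain recovers ≥ 90% of arc lengths
within 10%, with a median absolute error around 3% (the acceptance
script recomputes this).

## Explorer

Pooling maps one folder per condition, one TSV per replicate; folder
names become group labels. Pooling is strict: empty folders and
unreadable tables are errors, and record counts are conserved into
every output — QC never deletes data.

Quality control is advisory. Per group, values of cilium length,
volume, maximum span, and marker-intensity mean/SD outside the Tukey
fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR; multiplier configurable) are
flagged; groups with fewer than 4 records skip fences with a notice.
Cilia with more than 1 skeleton branch are flagged as highly branched,
and zero-length cilia informationally. Tool-version consistency across
all pooled tables is checked by default; a mismatch produces a
prominent warning (cross-version pooling risks batch-dependent bias).

Feature selection for dimensionality reduction excludes ids, spatial
coordinates, threshold columns, voxel-unit duplicates of µm-unit
columns (name-convention rule: a `*_voxels` column is dropped when a
same-stem `*_um*` column exists), non-numeric and zero-variance
columns; retained columns are standardized. PCA is deterministic with
a sign convention (largest-magnitude loading positive); UMAP is seeded
(default seed 42, n_neighbors 15 auto-reduced with a warning, min_dist
0.1) and parameters are recorded in the outputs. LDA returns
discriminant coefficients per measurement, ranked by largest absolute
coefficient, with shrinkage ('auto', eigen solver) when classes have
fewer records than features.

### Statistics decision tree

Per measurement: one condition → no statistics; any condition with
fewer than 3 records → no test with a message. Otherwise Shapiro–Wilk
per group (subsampled above 5000 records, where the test's p-value is
no longer meaningful) and, if all groups are normal at α, Levene's test
across groups:

| situation | 2 groups | > 2 groups |
|---|---|---|
| normal, homogeneous | Student's t | one-way ANOVA + Tukey HSD |
| normal, heterogeneous | Welch's t | Welch ANOVA + Games–Howell |
| any non-normal | Mann–Whitney U | Kruskal–Wallis + Dunn (Holm) |

The heterogeneous and >2-group branches are this package's choices
(recorded in each result's rationale trace); Welch ANOVA, Games–Howell
and Dunn are implemented directly (verified against an independent
reference implementation in the tests). Stars: `***` p ≤ 0.001, `**`
p ≤ 0.01, `*` p ≤ 0.05, else `ns`. Integer-valued (ordinal)
measurements run through the same tree with a warning in the rationale.
Type-I control of the full selection + testing path is verified by
simulation (2000 identical-normal two-group datasets; rejection rate
within the binomial band around 0.05). "No statistics" mode skips the
tree but still writes all summary tables.

Superplots show each cilium as a jittered point (colored by replicate),
replicate means as large diamonds, a pooled violin with median and
quartile lines, and the significance annotation. Outputs go to an
`Analysis` folder next to the first group folder: `Data/` (CSV
summaries, pooled records, embedding coordinates), `Plots/` (PNG and
always also SVG), and `qc.txt`, `statistics.txt`, `summary.txt` at the
top level, plus the resolved configuration for self-describing runs.

## Numerical choices and edge cases

- Threshold ties break toward the lowest cut attaining the optimum
  within a small relative tolerance (float plateaus across empty bins).
- A histogram with fewer than two occupied bins raises "no contrast";
  an empty segmentation mask warns but does not raise.
- Table parsing never silently coerces: a mixed numeric/text column or
  a comma-decimal cell raises a dialect error. Micrometer quantities
  are written with 3 decimals, "." separator; write→read→write is
  byte-stable.
- Voxel sizes must be known (from TIFF metadata or explicit override);
  measurements are meaningless without them, so a missing voxel size is
  an error, not a default.
- Problem sizes in the test-suite and acceptance-script simulations
  (50 phantoms of 16×175×175 voxels, 20-seed preprocessing comparison,
  2000 statistical replicates) were chosen as the smallest sizes at
  which the verified quantities stabilize.

## Known limitations

- Lengths below ~2 µm (a handful of voxels at default resolution) carry
  relative errors up to ~15%; the absolute error stays at a few voxels.
- The surface and maximum-span definitions are artifact-defined
  (exposed faces; voxel-center distances) and may differ from other
  tools' conventions.
- The decision tree treats each measurement independently; no
  multiple-testing correction is applied across measurements, and
  pooling many cilia can make trivial differences significant — read
  effect sizes, not just stars.
- The Canny-style 3D edge-detection segmentation mode of some tools is
  not implemented; neither are GUI-based mask editing (a programmatic
  add/remove edit is provided) or Bayesian statistics.
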