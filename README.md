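# ciliametry

Quantitative 3D morphometry of primary cilia from fluorescence
microscopy z-stacks — segmentation, per-cilium measurement with
skeleton-based length, and replicate-aware statistics — plus a phantom
generator with analytically known ground truth so the whole pipeline is
testable without any real data.

Primary cilia are antenna-like, microtubule-based organelles whose
length changes with signaling state. The standard way to measure them
is to immunolabel a cilium-exclusive membrane marker (e.g. Arl13b),
acquire confocal z-stacks, threshold the marker channel into a 3D mask,
and measure each connected object. The headline measurement is the
**cilium length**: the mask is thinned to a 1-voxel-wide skeleton,
skeleton voxels become a graph with edges weighted by the anisotropic
physical step length, and the length is the largest shortest path
between skeleton endpoints,

    L = max_{(a,b) endpoints} dist_graph(a, b)   [µm],

with tree length (total skeleton length), branch count, bending ratio
(end-to-end distance / L), volume, surface, maximum span, and
per-channel intensity statistics alongside. Downstream, per-condition
folders of measurement tables are pooled, quality-controlled (Tukey
1.5×IQR outlier fences, branch-count and tool-version checks),
tested with a Shapiro/Levene-driven decision tree (Student/Welch/
Mann–Whitney, ANOVA/Welch-ANOVA/Kruskal–Wallis with Tukey/
Games–Howell/Dunn post-hocs), and rendered as superplots and PCA/UMAP
embeddings.

Who it is for: cell biologists quantifying ciliary length/morphology
changes across experimental conditions, and method developers who need
a fully scriptable, ground-truth-validated reference pipeline.

## Worked example

Simulate three phantom cilia, segment, measure, and analyze:

```bash
printf "seed=7\nn_phantoms=3\nrun_umap=False\n" > run.cfg
ciliametry all --config run.cfg --out work
```

which prints (abridged):

```
INFO ciliametry: ciliametry v0.1.0, seed 7
INFO ciliametry: phantom 0: arc length 7.001 um
INFO ciliametry: phantom 1: arc length 4.616 um
INFO ciliametry: phantom 2: arc length 8.962 um
INFO ciliametry: quantified phantom_000_prepared.tif: 1 cilia -> phantom_000_cilia.tsv
QC: 0 flagged cilia; version consistent: True
Analysis written to work/tables/Analysis
```

The three generated tubes have analytic centerline arc lengths 7.001,
4.616 and 8.962 µm; the pipeline (hysteresis Yen/Otsu segmentation
after a σ=1.5 px Gaussian blur, 26-connected labeling, skeletonization)
measures 7.313, 4.789 and 9.349 µm — each within 5% of truth despite
snr 5 noise and 0.08/0.08/0.5 µm anisotropic voxels. The first row of
`phantom_000_cilia.tsv`:

```
id  x_um   y_um   z_um   volume_voxels  volume_um3  ...  n_branches  tree_length_um  cilia_length_um  bending_ratio
1   9.320  9.411  3.267  1001           3.203       ...  1           8.769           7.313            0.938
```

one object, a single skeleton branch (a clean cilium), and a bending
ratio of 0.94 (gently curved). `work/tables/Analysis/` contains the
summary CSVs (`Data/`), superplot and PCA figures (`Plots/`, PNG +
SVG), and `qc.txt` / `statistics.txt` / `summary.txt`.

To analyze your own data instead: `ciliametry prepare` and
`ciliametry quantify` consume TIFF stacks (voxel sizes from ImageJ-
style metadata), and `ciliametry explore GROUP_DIR1 GROUP_DIR2 ...`
pools folders of per-replicate TSV tables, where each folder name is
the condition label.

## Library surface

```python
from ciliametry import (
    read_image_stack, segment_stack, SegmentationSettings,
    quantify_stack, QuantifySettings, compute_sampling_limits,
)
from ciliametry.explorer import pool_groups, qc_screen, select_features, embed
from ciliametry.stats import choose_test, run_stats
from ciliametry.phantom import generate_centerline, PhantomTruth, rasterize_scene
```

`compute_sampling_limits(668, 1.40)` returns the Rayleigh lateral
resolution (~291 nm) and Nyquist sampling interval (~146 nm) used to
pick pixel sizes at acquisition time.

See `docs/methods.md` for the model, algorithmic choices, and
limitations.

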