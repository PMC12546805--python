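"""Synthetic 3D cilia phantoms and grouped measurement tables.

Phantom images emulate confocal z-stacks of immunolabeled cilia: tubes of
known centerline arc length are rendered into an anisotropic voxel grid,
blurred with a per-axis Gaussian point-spread approximation, and
corrupted with a constant background offset plus Gaussian noise of a
stated signal-to-noise ratio.  Because the centerline is an analytic
spline, the ground-truth cilium length is known to arbitrary precision,
so pipeline-measured lengths can be validated quantitatively.

Grouped tables emulate pooled per-condition measurement folders: one
folder per experimental group, one TSV per replicate, with stated
distributions (normal / lognormal) and planted effect sizes so the
downstream statistics stage can be validated against known truth.

The default voxel size (0.08, 0.08, 0.5) um matches typical confocal
acquisition for cilia (lateral pixel 0.05-0.1 um, z-step 0.5-0.8 um);
tubes keep a margin from the grid border by default so border-exclusion
behavior is exercised only by explicitly constructed cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from ciliametry.io_formats import (
    CiliaTable,
    ImageStack,
    RunMetadata,
    write_cilia_table,
    write_image_stack,
)

DEFAULT_VOXEL_SIZE_UM = (0.08, 0.08, 0.5)


@dataclass
class CenterlineSpec:
    """A tube centerline given by ordered 3D control points in micrometers."""

    control_points: np.ndarray
    radius_um: float = 0.25
    intensity: float = 200.0

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValueError("control_points must be (N, 3)")
        if len(self.control_points) < 2:
            raise ValueError("need at least 2 control points")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")

    def spline(self) -> CubicSpline:
        """Natural cubic spline through the control points, parametrized
        by cumulative chord length."""
        pts = self.control_points
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        if chord[-1] == 0:
            raise ValueError("control points are all coincident")
        return CubicSpline(chord, pts, bc_type="natural")

    def arc_length(self) -> float:
        """Analytic arc length via adaptive quadrature over the spline."""
        cs = self.spline()
        deriv = cs.derivative()
        t_end = cs.x[-1]
        speed = lambda t: np.linalg.norm(deriv(t))
        total, _ = quad(speed, 0.0, t_end, limit=200,
                        points=cs.x if len(cs.x) <= 50 else None)
        return float(total)

    def sample(self, n: int) -> np.ndarray:
        """n points along the spline at uniform parameter steps."""
        cs = self.spline()
        return cs(np.linspace(0.0, cs.x[-1], n))


@dataclass
class PhantomTruth:
    """Generator parameters with analytic ground truth for one scene."""

    centerlines: list[CenterlineSpec]
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    snr: float = 5.0
    background_level: float = 20.0
    psf_sigma_um: tuple[float, float, float] = (0.1, 0.1, 0.3)
    seed: int = 0
    arc_lengths_um: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if not self.arc_lengths_um:
            self.arc_lengths_um = [c.arc_length() for c in self.centerlines]


@dataclass
class GroupSpec:
    """One experimental condition of a synthetic grouped dataset.

    ``location``/``scale`` map measurement name to distribution
    parameters; ``effect`` maps measurement name to an additive shift of
    the location relative to a reference group (0 = no planted effect).
    For ``lognormal``, location and scale parametrize the underlying
    normal of the log.
    """

    group_label: str
    n_replicates: int = 3
    cilia_per_replicate: int = 50
    distribution: str = "normal"
    location: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    effect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.cilia_per_replicate < 1:
            raise ValueError("replicate and cilia counts must be >= 1")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if any(s <= 0 for s in self.scale.values()):
            raise ValueError("scale parameters must be positive")


def generate_centerline(seed: int,
                        bounds_um: tuple[float, float, float],
                        length_range_um: tuple[float, float],
                        curvature: float = 0.1,
                        radius_um: float = 0.25,
                        intensity: float = 200.0,
                        margin_um=None) -> CenterlineSpec:
    """Generate a random tube centerline inside a box.

    The centerline is a gently curved spline: control points along a
    random direction with perpendicular sinusoidal offsets of relative
    amplitude ``curvature``, rescaled so the analytic arc length falls in
    ``length_range_um``.  Raises if the requested lengths cannot fit in
    the box (diagonal minus margins).

    ``margin_um`` keeps the centerline away from the box faces (scalar or
    per-axis); the default leaves generous axial headroom so that the
    rendered tube, its PSF tails and permissive low thresholds do not
    reach the first/last z-plane — border-touching objects are meant to
    be constructed explicitly, not produced by accident.
    """
    bounds = np.asarray(bounds_um, dtype=float)
    lo, hi = length_range_um
    if not (lo > 0 and hi >= lo):
        raise ValueError("length_range must satisfy 0 < lo <= hi")
    if margin_um is None:
        margin_um = (radius_um * 2 + 0.3, radius_um * 2 + 0.3, radius_um + 1.2)
    margin_um = np.broadcast_to(np.asarray(margin_um, dtype=float), (3,)).copy()
    usable = bounds - 2 * margin_um
    if np.any(usable <= 0) or lo > float(np.linalg.norm(usable)):
        raise ValueError(
            f"length range {length_range_um} infeasible for bounds {bounds_um} "
            f"with margin {margin_um}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(200):
        target = rng.uniform(lo, hi)
        direction = rng.normal(size=3)
        # keep tubes mostly in-plane: z extent is expensive in anisotropic grids
        direction[2] *= 0.2
        direction /= np.linalg.norm(direction)
        perp = np.cross(direction, rng.normal(size=3))
        if np.linalg.norm(perp) < 1e-9:
            continue
        perp /= np.linalg.norm(perp)
        n_ctrl = 5
        t = np.linspace(0, 1, n_ctrl)
        amp = curvature * target
        base = np.outer(t, direction) * target
        offset = np.outer(np.sin(np.pi * t), perp) * amp
        pts = base + offset
        # rescale so that the analytic arc length hits the target
        for _ in range(8):
            spec = CenterlineSpec(pts, radius_um=radius_um, intensity=intensity)
            length = spec.arc_length()
            factor = target / length
            if abs(factor - 1.0) < 1e-4:
                break
            pts = pts * factor
        spec = CenterlineSpec(pts, radius_um=radius_um, intensity=intensity)
        length = spec.arc_length()
        if not (lo <= length <= hi):
            continue
        # place the curve at a random position fully inside the bounds
        ext_lo, ext_hi = pts.min(axis=0), pts.max(axis=0)
        extent = ext_hi - ext_lo
        if np.any(extent > usable):
            continue
        shift = np.array([
            rng.uniform(margin_um[i] - ext_lo[i], bounds[i] - margin_um[i] - ext_hi[i])
            for i in range(3)
        ])
        placed = pts + shift
        if np.all(placed >= margin_um - 1e-9) and np.all(placed <= bounds - margin_um + 1e-9):
            return CenterlineSpec(placed, radius_um=radius_um, intensity=intensity)
    raise ValueError(
        f"could not place a centerline of length in {length_range_um} inside "
        f"{bounds_um} after 200 attempts"
    )


def rasterize_scene(truth: PhantomTruth, shape: tuple[int, int, int]) -> ImageStack:
    """Render a phantom scene into a (1, z, y, x) image stack.

    Voxels whose center lies within ``radius_um`` (physical, anisotropic
    distance) of any centerline receive the tube's foreground intensity;
    the volume is then blurred per axis with the physical PSF sigmas,
    offset by the background level, and corrupted with Gaussian noise of
    standard deviation ``foreground_amplitude / snr``.  Deterministic
    given ``truth.seed``.

    When a PSF is applied, the tube is rendered on a z-supersampled grid
    and the blurred volume is sampled at the slice centers.  This mimics
    how a microscope sees a continuous object through band-limiting
    optics: a tube passing between two slice centers still contributes
    signal to both neighboring slices instead of disappearing into the
    gap.  With all PSF sigmas zero the output is exactly the binary
    voxel-center-distance rasterization.
    """
    nz, ny, nx = shape
    dx, dy, dz = truth.voxel_size_um
    # odd supersampling factor so one fine plane coincides with each
    # coarse slice center
    if any(s > 0 for s in truth.psf_sigma_um):
        f = int(math.ceil(dz / min(dx, dy)))
        f = min(f | 1, 9)
    else:
        f = 1
    dz_fine = dz / f
    shape_fine = (nz * f, ny, nx)
    volume = np.zeros(shape_fine, dtype=float)
    spacing = np.array([dz_fine, dy, dx])

    for idx, cl in enumerate(truth.centerlines):
        n_samples = max(64, int(truth.arc_lengths_um[idx] / (min(dx, dy, dz) / 4)))
        pts = cl.sample(n_samples)  # (n, 3) in (x, y, z) um
        phys_zyx = pts[:, ::-1]
        limits = np.array([nz * dz, ny * dy, nx * dx])
        if np.any(phys_zyx - cl.radius_um < -1e-9) or np.any(phys_zyx + cl.radius_um > limits + 1e-9):
            raise ValueError(
                f"centerline {idx} (radius {cl.radius_um} um) exits the "
                f"{limits[::-1]} um grid"
            )
        lo_idx = np.maximum(np.floor((phys_zyx.min(axis=0) - cl.radius_um) / spacing).astype(int), 0)
        hi_idx = np.minimum(np.ceil((phys_zyx.max(axis=0) + cl.radius_um) / spacing).astype(int) + 1,
                            shape_fine)
        grids = np.meshgrid(*[(np.arange(lo_idx[a], hi_idx[a]) + 0.5) * spacing[a]
                              for a in range(3)], indexing="ij")
        coords = np.stack([g.ravel() for g in grids], axis=1)
        tree = cKDTree(phys_zyx)
        dist, _ = tree.query(coords, k=1)
        inside = (dist <= cl.radius_um).reshape([hi_idx[a] - lo_idx[a] for a in range(3)])
        region = volume[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
        region[inside] = np.maximum(region[inside], cl.intensity)

    sigma_vox = [truth.psf_sigma_um[2] / dz_fine, truth.psf_sigma_um[1] / dy,
                 truth.psf_sigma_um[0] / dx]
    if any(s > 0 for s in sigma_vox):
        volume = ndi.gaussian_filter(volume, sigma=sigma_vox)
    # sample the fine plane lying at each coarse slice center
    volume = volume[(f - 1) // 2::f]

    volume += truth.background_level
    amplitude = max((c.intensity for c in truth.centerlines), default=0.0)
    if truth.centerlines and np.isfinite(truth.snr):
        rng = np.random.default_rng(truth.seed)
        volume += rng.normal(0.0, amplitude / truth.snr, size=shape)
    volume = np.clip(volume, 0, 65535)
    return ImageStack(voxels=volume[np.newaxis].astype(np.uint16),
                      voxel_size_um=truth.voxel_size_um, bit_depth=16)


def write_phantom(truth: PhantomTruth, shape: tuple[int, int, int],
                  directory: str | Path, name: str = "phantom") -> tuple[Path, Path]:
    """Render and save a phantom TIFF plus its ground-truth TSV sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = rasterize_scene(truth, shape)
    img_path = write_image_stack(stack, directory / f"{name}.tif")
    lines = ["centerline\tarc_length_um\tradius_um\tintensity"]
    for i, (cl, L) in enumerate(zip(truth.centerlines, truth.arc_lengths_um)):
        lines.append(f"{i}\t{L:.6f}\t{cl.radius_um:.6f}\t{cl.intensity:.3f}")
    truth_path = directory / f"{name}_truth.tsv"
    truth_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return img_path, truth_path


@dataclass
class GroupedTablesResult:
    """Folders and tables produced by :func:`generate_grouped_tables`."""

    root: Path
    group_folders: dict[str, Path]
    tables: dict[str, dict[str, CiliaTable]]


def sample_group_frame(spec: GroupSpec, measurements: list[str],
                       rng: np.random.Generator):
    """Sample the per-cilium measurement values for one replicate."""
    import pandas as pd

    n = spec.cilia_per_replicate
    data = {"id": np.arange(1, n + 1)}
    for m in measurements:
        loc = spec.location.get(m, 0.0) + spec.effect.get(m, 0.0)
        scale = spec.scale.get(m, 1.0)
        if spec.distribution == "normal":
            data[m] = rng.normal(loc, scale, size=n)
        else:
            data[m] = rng.lognormal(mean=loc, sigma=scale, size=n)
    return pd.DataFrame(data)


def generate_grouped_tables(specs: list[GroupSpec], measurements: list[str],
                            seed: int, root: str | Path,
                            tool_version: str = "v0.1.7") -> GroupedTablesResult:
    """Write one folder per group with one TSV table per replicate.

    All tables carry an identical synthetic tool-version tag by default,
    so version-consistency checking downstream passes unless a mismatch
    is planted deliberately.
    """
    if not specs:
        raise ValueError("need at least one group spec")
    labels = [s.group_label for s in specs]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate group labels in {labels}")
    if len(measurements) != len(set(measurements)):
        raise ValueError("measurement names must be unique")
    root = Path(root)
    rng = np.random.default_rng(seed)
    folders: dict[str, Path] = {}
    tables: dict[str, dict[str, CiliaTable]] = {}
    for spec in specs:
        folder = root / spec.group_label
        folder.mkdir(parents=True, exist_ok=True)
        folders[spec.group_label] = folder
        tables[spec.group_label] = {}
        for rep in range(1, spec.n_replicates + 1):
            df = sample_group_frame(spec, measurements, rng)
            rep_id = f"replicate_{rep:02d}"
            table = CiliaTable(
                data=df,
                metadata=RunMetadata(tool_version=tool_version),
                replicate_id=rep_id,
                group_label=spec.group_label,
            )
            write_cilia_table(table, folder / f"{rep_id}.tsv")
            tables[spec.group_label][rep_id] = table
    return GroupedTablesResult(root=root, group_folders=folders, tables=tables)
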