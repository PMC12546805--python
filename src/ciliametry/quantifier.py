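"""Per-cilium object detection, filtering and morphometry.

A segmented stack is turned into labeled 26-connected objects, small
objects and border-touching objects are removed (with an exclusion
report), and each survivor is measured: volume, exposed-face surface,
maximum span, centroid, intensity statistics, and skeleton-based length
measures.

Skeleton measures
-----------------
The object mask is thinned to a 1-voxel-wide 3D skeleton (medial-axis
thinning).  Skeleton voxels become graph nodes; 26-adjacent voxels are
connected by edges weighted with the anisotropic physical step length
(a diagonal step weighs sqrt(dx² + dy² + dz²)).  Redundant diagonal
adjacencies at corners are resolved by taking the minimum spanning tree
of this graph, which for a clean thinned skeleton is the skeleton
itself.  Then:

- ``tree_length`` is the total physical length of all skeleton branches,
- ``n_branches`` is the number of branches (tree edges between nodes of
  degree != 2, i.e. junctions and endpoints; a clean unbranched cilium
  has exactly 1),
- ``cilia_length`` is the largest shortest path between any two skeleton
  endpoints — the length of the cilium measured along its centerline,
- ``bending_ratio`` is the straight end-to-end distance of that longest
  path divided by ``cilia_length`` (1 = straight, < 1 = bent).

A single-voxel skeleton (a spherical stub) yields ``cilia_length`` 0;
this is reported, not treated as an error.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.morphology import skeletonize

from ciliametry.io_formats import CiliaTable, CiliumRecord, ImageStack, RunMetadata
from ciliametry._version import __version__

logger = logging.getLogger(__name__)

STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LabeledMask:
    """Integer object labels per voxel (0 = background)."""

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    connectivity_used: int = 26
    increase_range: bool = False

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def object_voxels(self, label: int) -> np.ndarray:
        """(N, 3) array of (z, y, x) voxel indices of one object."""
        return np.argwhere(self.labels == label)


@dataclass
class ExclusionReport:
    """Objects removed by :func:`filter_objects`, with reasons."""

    removed: list[tuple[int, str]] = field(default_factory=list)

    def reasons(self) -> dict[int, str]:
        return dict(self.removed)


@dataclass
class QuantifySettings:
    """Settings for :func:`quantify_stack`.

    ``reconstruction_channel`` indexes the segmented channel;
    ``intensity_channel`` the unsegmented copy used for intensity
    statistics (defaults to the reconstruction channel itself when the
    stack has no copy).  ``channel_a`` / ``channel_b`` optionally name
    additional channels whose signal is quantified within the ciliary
    masks.
    """

    reconstruction_channel: int = 0
    intensity_channel: int | None = None
    channel_a: int | None = None
    channel_b: int | None = None
    min_size_voxels: int = 10
    exclude_borders: tuple[bool, bool, bool] = (True, True, True)
    increase_range: bool = True
    gauss_xy_sigma: float = 0.0
    skeletonize: bool = True


def label_objects(mask: np.ndarray,
                  voxel_size_um: tuple[float, float, float],
                  increase_range: bool = False) -> LabeledMask:
    """Label 26-connected foreground objects.

    With ``increase_range`` on, objects separated by a 1-voxel background
    gap are merged: labeling runs on the 1-voxel-dilated mask and the
    labels are restricted to the original foreground.
    """
    mask = np.asarray(mask) > 0
    if increase_range:
        dilated = ndi.binary_dilation(mask, structure=STRUCTURE_26)
        labels, _ = ndi.label(dilated, structure=STRUCTURE_26)
        labels = np.where(mask, labels, 0)
        labels = _relabel_consecutive(labels)
    else:
        labels, _ = ndi.label(mask, structure=STRUCTURE_26)
    return LabeledMask(labels=labels, voxel_size_um=voxel_size_um,
                       increase_range=increase_range)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    present = np.unique(labels)
    present = present[present > 0]
    mapping = np.zeros(labels.max() + 1 if labels.size else 1, dtype=labels.dtype)
    mapping[present] = np.arange(1, len(present) + 1)
    return mapping[labels]


def filter_objects(labeled: LabeledMask, min_size_voxels: int = 10,
                   exclude_borders: tuple[bool, bool, bool] = (False, False, False)
                   ) -> tuple[LabeledMask, ExclusionReport]:
    """Remove too-small and border-touching objects; relabel survivors.

    ``exclude_borders`` is an (x, y, z) triple of flags; an object with
    any voxel on the first or last plane of a flagged axis is removed
    with reason ``border``.  Objects with fewer than ``min_size_voxels``
    voxels are removed with reason ``too-small``.  The report lists every
    removal so that excluded cilia can be backtracked.
    """
    if min_size_voxels < 1:
        raise ValueError("min_size_voxels must be >= 1")
    labels = labeled.labels
    n = labeled.n_objects
    report = ExclusionReport()
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    ex_x, ex_y, ex_z = exclude_borders
    border_labels: set[int] = set()
    nz, ny, nx = labels.shape
    if ex_z:
        border_labels |= set(np.unique(labels[[0, nz - 1], :, :]))
    if ex_y:
        border_labels |= set(np.unique(labels[:, [0, ny - 1], :]))
    if ex_x:
        border_labels |= set(np.unique(labels[:, :, [0, nx - 1]]))
    border_labels.discard(0)
    for lbl in range(1, n + 1):
        if sizes[lbl] < min_size_voxels:
            keep[lbl] = False
            report.removed.append((lbl, "too-small"))
        elif lbl in border_labels:
            keep[lbl] = False
            report.removed.append((lbl, "border"))
    filtered = np.where(keep[labels], labels, 0)
    filtered = _relabel_consecutive(filtered)
    out = LabeledMask(labels=filtered, voxel_size_um=labeled.voxel_size_um,
                      increase_range=labeled.increase_range)
    return out, report


def suggest_min_size(pixel_size_um: float,
                     reference: tuple[float, float] = (0.1, 10)) -> int:
    """Suggested minimum cilium size (voxels) for a lateral pixel size.

    Pixel size is a length while the cilium footprint is an area, so the
    minimum size scales with the inverse square of the pixel size:
    halving the pixel size quadruples the suggested minimum.  The
    reference point is 10 voxels at 0.1 um/px; the result is a lower
    bound ("at least"), rounded up to a whole voxel count.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    ref_px, ref_size = reference
    return int(math.ceil(ref_size * (ref_px / pixel_size_um) ** 2 - 1e-9))


def measure_morphology(voxels: np.ndarray,
                       voxel_size_um: tuple[float, float, float]) -> dict:
    """Volume, exposed-face surface, maximum span and centroid of an object.

    ``voxels`` is an (N, 3) array of (z, y, x) indices.  Surface is the
    total area of voxel faces not shared with another object voxel; the
    maximum span is the largest pairwise distance between voxel centers
    in physical micrometers (computed exactly; via the convex hull for
    large objects, which is still exact since the diameter is attained
    at hull vertices).
    """
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        raise ValueError("object has no voxels")
    dx, dy, dz = voxel_size_um
    n = len(voxels)
    volume_um3 = n * dx * dy * dz

    vset = set(map(tuple, voxels))
    face_area = {0: dx * dy, 1: dx * dz, 2: dy * dz}  # faces normal to z, y, x
    surface = 0.0
    for v in voxels:
        z, y, x = (int(c) for c in v)
        for axis, (ddz, ddy, ddx) in enumerate(
                [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]):
            if (z + ddz, y + ddy, x + ddx) not in vset:
                surface += face_area[0 if ddz else (1 if ddy else 2)]

    phys = voxels[:, ::-1] * np.array([dx, dy, dz])  # (x, y, z) in um
    centroid = phys.mean(axis=0)
    max_span = _max_pairwise_distance(phys)
    return {
        "volume_voxels": n,
        "volume_um3": volume_um3,
        "surface_um2": surface,
        "max_span_um": max_span,
        "centroid_um": tuple(centroid),
    }


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) == 1:
        return 0.0
    if len(points) > 2000:
        try:
            hull = ConvexHull(points, qhull_options="QJ")
            points = points[hull.vertices]
        except QhullError:
            pass  # degenerate (collinear/coplanar): fall through to exact pdist
    return float(pdist(points).max())


def _skeleton_graph(skel_voxels: np.ndarray,
                    voxel_size_um: tuple[float, float, float]) -> nx.Graph:
    """Graph over 26-adjacent skeleton voxels with physical edge weights."""
    dx, dy, dz = voxel_size_um
    nodes = [tuple(int(c) for c in v) for v in skel_voxels]
    node_set = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) > (0, 0, 0)]
    for z, y, x in nodes:
        for oz, oy, ox in offsets:
            nb = (z + oz, y + oy, x + ox)
            if nb in node_set:
                w = math.sqrt((ox * dx) ** 2 + (oy * dy) ** 2 + (oz * dz) ** 2)
                g.add_edge((z, y, x), nb, weight=w)
    return g


def _physical(node, voxel_size_um) -> np.ndarray:
    dx, dy, dz = voxel_size_um
    z, y, x = node
    return np.array([x * dx, y * dy, z * dz])


def skeletonize_and_measure(voxels: np.ndarray, shape: tuple[int, int, int],
                            voxel_size_um: tuple[float, float, float],
                            gauss_xy_sigma: float = 0.0,
                            path_step: int | None = None,
                            close_gaps: bool = False,
                            assume_skeleton: bool = False) -> dict:
    """Skeleton-based length measures of one object.

    With ``gauss_xy_sigma > 0`` the object mask is blurred in XY as a
    float image and re-binarized at half maximum before thinning, which
    smooths noisy mask outlines and reduces spurious skeleton side
    branches.  ``close_gaps`` applies one morphological closing before
    thinning, so 1-voxel background gaps bridged during labeling do not
    split the skeleton.

    ``path_step`` controls the digitization-bias correction of
    ``cilia_length``: the longest skeleton path is summed as chords over
    every ``path_step``-th voxel instead of per-voxel steps.  Summing
    per-voxel steps on an anisotropic grid systematically overestimates
    the length of an oblique curve (every discrete z-jump replaces a
    gradual incline with a staircase), so the default chooses the stride
    from the voxel anisotropy, ``ceil(max(d) / min(d))``; for an
    isotropic grid this is 1 and the chord sum equals the per-step sum
    exactly.

    ``assume_skeleton`` treats the voxel set as an already-thinned
    skeleton (useful for measuring externally constructed skeletons).
    """
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        raise ValueError("object has no voxels")
    dxyz = voxel_size_um
    if path_step is None:
        path_step = max(1, int(math.ceil(max(dxyz) / min(dxyz))))
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(voxels.T)] = True
    if close_gaps:
        mask = ndi.binary_closing(mask, structure=STRUCTURE_26)
    if gauss_xy_sigma > 0:
        blurred = ndi.gaussian_filter(mask.astype(float),
                                      sigma=(0, gauss_xy_sigma, gauss_xy_sigma))
        remask = blurred >= 0.5
        if remask.any():
            mask = remask
    skel = mask if assume_skeleton else skeletonize(mask)
    skel_voxels = np.argwhere(skel)
    if len(skel_voxels) == 0:
        # thinning can annihilate very small objects; fall back to centroid
        skel_voxels = np.array([np.round(voxels.mean(axis=0)).astype(int)])
    graph = _skeleton_graph(skel_voxels, voxel_size_um)
    # spanning forest: resolves redundant corner diagonals so that total
    # branch length and branch counts are well defined
    tree = nx.minimum_spanning_tree(graph, weight="weight")

    n_branches = 0
    tree_length = 0.0
    cilia_length = 0.0
    bending_ratio = float("nan")
    orientation = (float("nan"),) * 3

    for comp_nodes in nx.connected_components(tree):
        sub = tree.subgraph(comp_nodes)
        tree_length += sub.size(weight="weight")
        special = [v for v in sub if sub.degree(v) != 2]
        if len(comp_nodes) == 1:
            n_branches += 1
            continue
        if not special:  # pure cycle (cannot occur in a spanning tree, safety)
            n_branches += 1
            continue
        n_branches += _count_branches(sub, special)

    # cilium length: largest shortest path between endpoints on the full
    # voxel graph (diagonal shortcuts count; endpoints have degree <= 1)
    endpoints = [v for v in graph if graph.degree(v) <= 1]
    if len(endpoints) >= 2:
        best = (0.0, None, None)
        for a in endpoints:
            lengths = nx.single_source_dijkstra_path_length(graph, a, weight="weight")
            for b in endpoints:
                d = lengths.get(b)
                if d is not None and d > best[0]:
                    best = (d, a, b)
        step_length, a, b = best
        if step_length > 0 and a is not None:
            path = nx.shortest_path(graph, a, b, weight="weight")
            cilia_length = _chord_length(path, voxel_size_um, path_step)
            pa, pb = _physical(a, voxel_size_um), _physical(b, voxel_size_um)
            # end-loss correction: for a capsule-shaped mask the medial
            # axis ends one local radius inside the mask tip; if thinning
            # retreated the skeleton end further than that, extend it back
            # by the difference
            edt = ndi.distance_transform_edt(
                mask, sampling=(voxel_size_um[2], voxel_size_um[1], voxel_size_um[0]))
            ext_a, pa = _end_extension(path, mask, edt, voxel_size_um, reverse=False)
            ext_b, pb2 = _end_extension(path, mask, edt, voxel_size_um, reverse=True)
            pb = pb2
            cilia_length += ext_a + ext_b
            # the longest path is part of the tree, so the tree shares its
            # end losses; keeps tree_length >= cilia_length
            tree_length += ext_a + ext_b
            chord = float(np.linalg.norm(pb - pa))
            bending_ratio = min(chord / cilia_length, 1.0) if cilia_length > 0 else float("nan")
            direction = pb - pa
            norm = np.linalg.norm(direction)
            if norm > 0:
                orientation = tuple(direction / norm)
    return {
        "n_branches": int(n_branches),
        "tree_length_um": float(tree_length),
        "cilia_length_um": float(cilia_length),
        "bending_ratio": float(bending_ratio),
        "orientation": orientation,
        "n_skeleton_voxels": len(skel_voxels),
    }


def _end_extension(path: list, mask: np.ndarray, edt: np.ndarray,
                   voxel_size_um, reverse: bool, cone_slack_um: float = 0.15):
    """Extension of one end of the longest path toward the mask tip.

    For a capsule-shaped mask the medial axis ends exactly one local
    radius inside the mask tip, so the true endpoint lies at
    ``d_tip - r_local`` beyond the skeleton end when discrete thinning
    retreated further than that.  ``d_tip`` is the farthest axial
    projection of mask voxels inside a forward cone from the path end
    along the outgoing direction; ``r_local`` is the anisotropic
    distance-to-background at the end voxel.  For a mask that is itself
    a thin skeleton there are no voxels beyond the end and the
    extension is zero.
    """
    nodes = path[::-1] if reverse else path
    end = nodes[-1]
    inner = nodes[max(0, len(nodes) - 6)]
    p_end = _physical(end, voxel_size_um)
    p_inner = _physical(inner, voxel_size_um)
    direction = p_end - p_inner
    norm = np.linalg.norm(direction)
    if norm == 0:
        return 0.0, p_end
    direction /= norm
    vox = np.argwhere(mask)
    phys = vox[:, ::-1] * np.asarray(voxel_size_um)
    rel = phys - p_end
    proj = rel @ direction
    lateral = np.linalg.norm(rel - np.outer(proj, direction), axis=1)
    ahead = (proj > 0) & (lateral <= proj + cone_slack_um)
    if not ahead.any():
        return 0.0, p_end
    d_tip = float(proj[ahead].max())
    r_local = float(edt[end])
    ext = max(0.0, d_tip - r_local)
    return ext, p_end + direction * ext


def _chord_length(path: list, voxel_size_um, step: int) -> float:
    """Length of a voxel path summed as chords over every ``step``-th node.

    The endpoints are always included, so ``step == 1`` reproduces the
    per-voxel-step (Dijkstra) length exactly.
    """
    pts = np.array([_physical(v, voxel_size_um) for v in path])
    idx = list(range(0, len(pts), step))
    if idx[-1] != len(pts) - 1:
        idx.append(len(pts) - 1)
    sel = pts[idx]
    return float(np.linalg.norm(np.diff(sel, axis=0), axis=1).sum())


def _count_branches(tree: nx.Graph, special: list) -> int:
    """Count maximal degree-2 chains between junction/end nodes."""
    special_set = set(special)
    seen_edges = set()
    branches = 0
    for s in special:
        for nb in tree.neighbors(s):
            edge = frozenset((s, nb))
            if edge in seen_edges:
                continue
            # walk the chain from s through nb to the next special node
            prev, cur = s, nb
            chain_edges = [edge]
            while cur not in special_set:
                nxt = next(v for v in tree.neighbors(cur) if v != prev)
                chain_edges.append(frozenset((cur, nxt)))
                prev, cur = cur, nxt
            seen_edges.update(chain_edges)
            branches += 1
    return branches


def measure_intensity(voxels: np.ndarray, stack: ImageStack, channel: int) -> dict:
    """Mean/SD/min/max of one channel's original intensities in the mask.

    The standard deviation is the population SD (ddof=0).
    """
    if not 0 <= channel < stack.n_channels:
        raise IndexError(f"channel {channel} invalid for {stack.n_channels}-channel stack")
    voxels = np.asarray(voxels)
    values = stack.voxels[channel][tuple(voxels.T)].astype(float)
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=0)),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def quantify_stack(stack: ImageStack, settings: QuantifySettings,
                   metadata: RunMetadata | None = None,
                   source_image: str = "") -> CiliaTable:
    """Full per-object pipeline: label, filter, measure.

    The reconstruction channel is binarized at > 0 (the preparator's
    output encodes background as 0 in both segmentation styles), objects
    are labeled with 26-connectivity, filtered by minimum size and
    border exclusion, and each surviving object is measured into one
    :class:`~ciliametry.io_formats.CiliumRecord`.
    """
    recon = stack.channel(settings.reconstruction_channel)
    background_fraction = float((recon == 0).mean())
    if background_fraction < 0.5:
        warnings.warn(
            "reconstruction channel has little zero background; it may be "
            "unsegmented or heavily over-segmented — check the channel "
            "selection and segmentation quality"
        )
    mask = recon > 0
    labeled = label_objects(mask, stack.voxel_size_um,
                            increase_range=settings.increase_range)
    n_initial = labeled.n_objects
    labeled, report = filter_objects(labeled, settings.min_size_voxels,
                                     settings.exclude_borders)
    logger.info("quantify: %d objects detected, %d excluded, %d measured",
                n_initial, len(report.removed), labeled.n_objects)

    intensity_channel = settings.intensity_channel
    if intensity_channel is None:
        intensity_channel = settings.reconstruction_channel

    nz, ny, nx_ = mask.shape
    records = []
    for lbl in range(1, labeled.n_objects + 1):
        vox = labeled.object_voxels(lbl)
        morph = measure_morphology(vox, stack.voxel_size_um)
        rec = CiliumRecord(
            id=lbl,
            x_um=morph["centroid_um"][0],
            y_um=morph["centroid_um"][1],
            z_um=morph["centroid_um"][2],
            volume_voxels=morph["volume_voxels"],
            volume_um3=morph["volume_um3"],
            surface_um2=morph["surface_um2"],
            max_span_um=morph["max_span_um"],
            touches_x_border=int(vox[:, 2].min() == 0 or vox[:, 2].max() == nx_ - 1),
            touches_y_border=int(vox[:, 1].min() == 0 or vox[:, 1].max() == ny - 1),
            touches_z_border=int(vox[:, 0].min() == 0 or vox[:, 0].max() == nz - 1),
        )
        if settings.skeletonize:
            skel = skeletonize_and_measure(vox, mask.shape, stack.voxel_size_um,
                                           settings.gauss_xy_sigma,
                                           close_gaps=settings.increase_range)
            rec.n_branches = skel["n_branches"]
            rec.tree_length_um = skel["tree_length_um"]
            rec.cilia_length_um = skel["cilia_length_um"]
            rec.bending_ratio = skel["bending_ratio"]
            rec.orientation_x, rec.orientation_y, rec.orientation_z = skel["orientation"]
        stats = measure_intensity(vox, stack, intensity_channel)
        rec.recon_intensity_mean = stats["mean"]
        rec.recon_intensity_sd = stats["sd"]
        rec.recon_intensity_min = stats["min"]
        rec.recon_intensity_max = stats["max"]
        for name, ch in (("channel_a", settings.channel_a),
                         ("channel_b", settings.channel_b)):
            if ch is not None:
                s = measure_intensity(vox, stack, ch)
                rec.extra[f"{name}_intensity_mean"] = s["mean"]
                rec.extra[f"{name}_intensity_sd"] = s["sd"]
                rec.extra[f"{name}_intensity_min"] = s["min"]
                rec.extra[f"{name}_intensity_max"] = s["max"]
        records.append(rec)

    meta = metadata if metadata is not None else RunMetadata(tool_version=f"v{__version__}")
    meta.settings.setdefault("min_size_voxels", str(settings.min_size_voxels))
    meta.settings.setdefault("exclude_borders", str(settings.exclude_borders))
    meta.settings.setdefault("gauss_xy_sigma", str(settings.gauss_xy_sigma))
    return CiliaTable.from_records(records, source_image=source_image, metadata=meta)
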