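"""Independent brute-force oracles shared by the verification suites.

Everything here is deliberately naive (explicit loops, exhaustive
search, scipy-sparse Dijkstra) and independent of the package's own
implementation paths.
"""

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import dijkstra


def exhaustive_otsu(hist):
    p = hist / hist.sum()
    bins = np.arange(hist.size)
    best_t, best = 0, -1.0
    for t in range(hist.size - 1):
        w0 = p[: t + 1].sum()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[: t + 1] * bins[: t + 1]).sum() / w0
        mu1 = (p[t + 1:] * bins[t + 1:]).sum() / w1
        val = w0 * w1 * (mu0 - mu1) ** 2
        if val > best + 1e-10 * max(best, 1.0):
            best, best_t = val, t
    return best_t


def exhaustive_yen(hist):
    p = hist / hist.sum()
    best_t, best = 0, -np.inf
    for t in range(hist.size - 1):
        w0 = p[: t + 1].sum()
        w1 = 1 - w0
        g0 = (p[: t + 1] ** 2).sum()
        g1 = (p[t + 1:] ** 2).sum()
        if w0 <= 0 or w1 <= 0 or g0 <= 0 or g1 <= 0:
            continue
        val = -np.log(g0 * g1) + 2 * np.log(w0 * w1)
        if val > best + 1e-12:
            best, best_t = val, t
    return best_t


def exhaustive_shanbhag(hist):
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P2 = 1 - P1
    nz = np.nonzero(p)[0]
    best_t, best = nz[0], np.inf
    for t in range(nz[0], nz[-1]):
        if P1[t] <= 0 or P2[t] <= 0:
            continue
        tb = 0.5 / P1[t]
        eb = -sum(p[ih] * np.log(1 - tb * P1[ih - 1]) for ih in range(1, t + 1)) * tb
        to = 0.5 / P2[t]
        eo = -sum(p[ih] * np.log(1 - to * P2[ih]) for ih in range(t + 1, hist.size)) * to
        val = abs(eb - eo)
        if val < best - 1e-12:
            best, best_t = val, t
    return best_t


def bimodal_histograms(n, bins=256, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    x = np.arange(bins)
    for _ in range(n):
        lo = rng.integers(10, bins // 2 - 10)
        hi = rng.integers(bins // 2 + 10, bins - 10)
        h = rng.integers(500, 3000) * np.exp(-((x - lo) ** 2) / (2 * rng.uniform(3, 15) ** 2))
        h += rng.integers(100, 1500) * np.exp(-((x - hi) ** 2) / (2 * rng.uniform(3, 15) ** 2))
        h += rng.poisson(0.5, bins)
        out.append(np.round(h))
    return out


def bruteforce_label_filter(mask, min_size, border_flags):
    """Count surviving objects by explicit per-object checks."""
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3)))
    nz, ny, nx = mask.shape
    ex_x, ex_y, ex_z = border_flags
    survivors = 0
    for lbl in range(1, n + 1):
        vox = np.argwhere(labels == lbl)
        if len(vox) < min_size:
            continue
        if ex_z and (vox[:, 0].min() == 0 or vox[:, 0].max() == nz - 1):
            continue
        if ex_y and (vox[:, 1].min() == 0 or vox[:, 1].max() == ny - 1):
            continue
        if ex_x and (vox[:, 2].min() == 0 or vox[:, 2].max() == nx - 1):
            continue
        survivors += 1
    return survivors


def dijkstra_longest_endpoint_path(voxels, voxel_size_um):
    """Largest shortest path between endpoints via scipy-sparse Dijkstra.

    Nodes are skeleton voxels; edges join 26-neighbors with physical step
    weights.  Endpoints are nodes with exactly one neighbor.
    """
    voxels = [tuple(int(c) for c in v) for v in voxels]
    index = {v: i for i, v in enumerate(voxels)}
    n = len(voxels)
    dx, dy, dz = voxel_size_um
    graph = lil_matrix((n, n))
    degree = np.zeros(n, dtype=int)
    for v in voxels:
        for oz in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for ox in (-1, 0, 1):
                    if (oz, oy, ox) == (0, 0, 0):
                        continue
                    nb = (v[0] + oz, v[1] + oy, v[2] + ox)
                    if nb in index:
                        w = np.sqrt((ox * dx) ** 2 + (oy * dy) ** 2 + (oz * dz) ** 2)
                        graph[index[v], index[nb]] = w
                        degree[index[v]] += 1
    endpoints = [i for i in range(n) if degree[i] == 1]
    if len(endpoints) < 2:
        return 0.0
    dist = dijkstra(graph.tocsr(), directed=False, indices=endpoints)
    best = 0.0
    for row in dist:
        vals = row[endpoints]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            best = max(best, vals.max())
    return float(best)


def random_tree_skeleton(rng, shape=(12, 12, 12), n_branches=2):
    """Grow a random thin 26-connected tree of voxels inside ``shape``."""
    voxels = [tuple(int(c) for c in np.array(shape) // 2)]
    vox_set = set(voxels)
    for _ in range(n_branches):
        current = voxels[rng.integers(len(voxels))]
        direction = rng.integers(-1, 2, size=3)
        while not direction.any():
            direction = rng.integers(-1, 2, size=3)
        for _ in range(int(rng.integers(3, 7))):
            nxt = tuple(np.clip(np.array(current) + direction, 0,
                                np.array(shape) - 1))
            if nxt == current:
                break
            if nxt not in vox_set:
                vox_set.add(nxt)
                voxels.append(nxt)
            current = nxt
    return np.array(sorted(vox_set))
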