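"""Histogram-based automatic threshold selection.

All methods take a 1D histogram of bin counts (bin ``i`` holding the count
of intensity ``i``) and return an integer threshold ``t``; foreground is
defined as intensity strictly greater than ``t``.  Ties in a criterion are
broken toward the lowest qualifying bin, which makes every method
deterministic.

Implemented formulations
------------------------
- ``otsu``: maximize between-class variance (Otsu 1979).
- ``li``: minimum cross entropy between the image and its two-level
  reconstruction (Li & Lee 1993), via the Li & Tam (1998) fixed-point
  iteration.
- ``yen``: maximize Yen's maximum-correlation criterion (Yen et al. 1995).
- ``renyi_entropy``: the three-threshold Rényi-entropy combination of
  Sahoo et al. (1997): maximum-entropy thresholds at orders 1/2, 1 and 2
  combined with closeness-dependent weights.
- ``moments``: moment-preserving thresholding (Tsai 1985).
- ``minimum``: iterative 3-bin mean smoothing of the histogram until it is
  bimodal, threshold at the valley between the two modes (Prewitt &
  Mendelsohn 1966).
- ``shanbhag``: fuzzy-membership information measure (Shanbhag 1994),
  minimizing the absolute difference of background and object information.
"""

from __future__ import annotations

import numpy as np

METHOD_NAMES = (
    "otsu",
    "li",
    "yen",
    "renyi_entropy",
    "moments",
    "minimum",
    "shanbhag",
)

# Aliases matching the capitalized names used in the segmentation UI of
# common tools, so settings files can use either spelling.
_ALIASES = {
    "otsu": "otsu",
    "li": "li",
    "yen": "yen",
    "renyientropy": "renyi_entropy",
    "renyi_entropy": "renyi_entropy",
    "moments": "moments",
    "minimum": "minimum",
    "shanbhag": "shanbhag",
}


class NoContrastError(ValueError):
    """Histogram has fewer than two occupied bins: no threshold exists."""


def _validate(hist) -> np.ndarray:
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size == 0:
        raise ValueError("histogram must be a non-empty 1D array of counts")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(hist) < 2:
        raise NoContrastError("no contrast: fewer than 2 occupied histogram bins")
    return hist


def auto_threshold(hist, method: str) -> int:
    """Select a threshold from a histogram with the named method.

    Parameters
    ----------
    hist : array-like
        Bin counts; bin index is the intensity value.
    method : str
        One of :data:`METHOD_NAMES` (case-insensitive; "RenyiEntropy"
        also accepted).

    Returns
    -------
    int
        Threshold ``t``; foreground is intensity ``> t``.
    """
    key = _ALIASES.get(method.replace("-", "_").replace(" ", "").lower())
    if key is None:
        raise ValueError(f"unknown threshold method {method!r}; known: {METHOD_NAMES}")
    hist = _validate(hist)
    return int(_DISPATCH[key](hist))


def threshold_otsu(hist) -> int:
    """Lowest cut maximizing between-class variance."""
    hist = _validate(hist)
    p = hist / hist.sum()
    bins = np.arange(hist.size)
    w0 = np.cumsum(p)[:-1]          # weight of class <= t
    w1 = 1.0 - w0
    m = np.cumsum(p * bins)
    mu_total = m[-1]
    mu0 = np.divide(m[:-1], w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(mu_total - m[:-1], w1, out=np.zeros_like(w1), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    return _first_argmax(sigma_b)


def _first_argmax(values: np.ndarray, rtol: float = 1e-10) -> int:
    """Lowest index attaining the maximum up to a relative tolerance.

    Plateaus of the criterion (e.g. across empty histogram bins) differ
    only by floating-point noise; the documented tie-break is the lowest
    qualifying cut.
    """
    mx = values.max()
    return int(np.argmax(values >= mx - rtol * max(abs(mx), 1.0)))


def threshold_li(hist) -> int:
    """Iterative minimum cross entropy (Li & Tam 1998 fixed point).

    Starting from the histogram mean, the threshold is updated as
    ``(mu_b - mu_f) / (ln mu_b - ln mu_f)`` with class means taken below
    and above the current threshold, until the update moves by less than
    half a bin.
    """
    hist = _validate(hist)
    bins = np.arange(hist.size, dtype=float)
    p = hist / hist.sum()
    t = float((p * bins).sum())
    eps = 1e-12
    for _ in range(200):
        low = bins <= t
        wb, wf = p[low].sum(), p[~low].sum()
        if wb <= 0 or wf <= 0:
            break
        mu_b = max((p[low] * bins[low]).sum() / wb, eps)
        mu_f = max((p[~low] * bins[~low]).sum() / wf, eps)
        denom = np.log(mu_b) - np.log(mu_f)
        if denom == 0:
            break
        t_new = (mu_b - mu_f) / denom
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    return int(t)


def threshold_yen(hist) -> int:
    """Lowest cut maximizing Yen's maximum-correlation criterion."""
    hist = _validate(hist)
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P1_sq = np.cumsum(p ** 2)
    P2_sq = P1_sq[-1] - P1_sq
    best_t, best_val = 0, -np.inf
    for t in range(hist.size - 1):
        w0, w1 = P1[t], 1.0 - P1[t]
        if w0 <= 0 or w1 <= 0 or P1_sq[t] <= 0 or P2_sq[t] <= 0:
            continue
        val = -np.log(P1_sq[t] * P2_sq[t]) + 2 * np.log(w0 * w1)
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return int(best_t)


def _max_entropy_renyi(p: np.ndarray, rho: float) -> int:
    """Cut maximizing the sum of background and object Rényi entropies."""
    P1 = np.cumsum(p)
    best_t, best_val = 0, -np.inf
    n = p.size
    first = int(np.argmax(p > 0))
    last = n - 1 - int(np.argmax(p[::-1] > 0))
    for t in range(first, last):
        w0, w1 = P1[t], 1.0 - P1[t]
        if w0 <= 0 or w1 <= 0:
            continue
        pb = p[: t + 1] / w0
        pf = p[t + 1:] / w1
        pb = pb[pb > 0]
        pf = pf[pf > 0]
        if abs(rho - 1.0) < 1e-12:
            val = -(pb * np.log(pb)).sum() - (pf * np.log(pf)).sum()
        else:
            val = (np.log((pb ** rho).sum()) + np.log((pf ** rho).sum())) / (1.0 - rho)
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return best_t


def threshold_renyi_entropy(hist) -> int:
    """Three-order Rényi-entropy threshold combination.

    Maximum-entropy cuts are found at orders rho = 1/2, 1 and 2; the final
    threshold is a weighted combination of the sorted cuts, with weights
    depending on how close the three cuts are to each other.
    """
    hist = _validate(hist)
    p = hist / hist.sum()
    t1 = _max_entropy_renyi(p, 1.0)    # Shannon limit
    t2 = _max_entropy_renyi(p, 0.5)
    t3 = _max_entropy_renyi(p, 2.0)
    ts = sorted((t1, t2, t3))
    t_star1, t_star2, t_star3 = ts
    d12, d23 = abs(t_star1 - t_star2), abs(t_star2 - t_star3)
    if (d12 <= 5 and d23 <= 5) or (d12 > 5 and d23 > 5):
        beta = (1.0, 2.0, 1.0)
    elif d12 <= 5 < d23:
        beta = (0.0, 1.0, 3.0)
    else:
        beta = (3.0, 1.0, 0.0)
    P1 = np.cumsum(p)
    omega = P1[t_star3] - P1[t_star1]
    opt = (
        t_star1 * (P1[t_star1] + 0.25 * omega * beta[0])
        + 0.25 * t_star2 * omega * beta[1]
        + t_star3 * (1.0 - P1[t_star3] + 0.25 * omega * beta[2])
    )
    return int(round(opt))


def threshold_moments(hist) -> int:
    """Moment-preserving threshold (Tsai): match the first three moments.

    The gray-level fraction assigned to the background by the two-level
    moment-preserving image determines the threshold as a p-tile cut.
    """
    hist = _validate(hist)
    p = hist / hist.sum()
    bins = np.arange(hist.size, dtype=float)
    m1 = (p * bins).sum()
    m2 = (p * bins ** 2).sum()
    m3 = (p * bins ** 3).sum()
    cd = m2 - m1 * m1
    if cd <= 0:
        raise NoContrastError("degenerate histogram: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        disc = 0.0
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise NoContrastError("degenerate histogram: coincident moment levels")
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels below threshold
    cum = np.cumsum(p)
    # p-tile: first bin where the cumulative fraction reaches p0
    idx = int(np.argmax(cum >= p0 - 1e-12))
    return idx


def threshold_minimum(hist, max_iter: int = 10000) -> int:
    """Valley threshold after iterated 3-bin mean smoothing to bimodality."""
    hist = _validate(hist)
    smooth = hist.astype(float)
    for _ in range(max_iter):
        maxima = _local_maxima(smooth)
        if len(maxima) == 2:
            break
        padded = np.pad(smooth, 1, mode="edge")
        smooth = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    else:
        raise RuntimeError("histogram did not become bimodal after smoothing")
    maxima = _local_maxima(smooth)
    lo, hi = maxima
    valley = lo + int(np.argmin(smooth[lo: hi + 1]))
    return int(valley)


def _local_maxima(h: np.ndarray) -> list[int]:
    """Direction-walk local maxima: where the series stops rising and
    starts falling; a flat plateau before a fall counts once."""
    maxima = []
    direction = 1
    for i in range(h.size - 1):
        if direction > 0:
            if h[i + 1] < h[i]:
                direction = -1
                maxima.append(i)
        elif h[i + 1] > h[i]:
            direction = 1
    return maxima


def threshold_shanbhag(hist) -> int:
    """Shanbhag's fuzzy information measure, minimized over cuts."""
    hist = _validate(hist)
    p = hist / hist.sum()
    n = p.size
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    first = int(np.argmax(p > 0))
    last = n - 1 - int(np.argmax(p[::-1] > 0))
    best_t, best_val = first, np.inf
    for t in range(first, last):
        if P1[t] <= 0 or P2[t] <= 0:
            continue
        term = 0.5 / P1[t]
        ent_back = 0.0
        for ih in range(1, t + 1):
            ent_back -= p[ih] * np.log(1.0 - term * P1[ih - 1])
        ent_back *= term
        term = 0.5 / P2[t]
        ent_obj = 0.0
        for ih in range(t + 1, n):
            ent_obj -= p[ih] * np.log(1.0 - term * P2[ih])
        ent_obj *= term
        val = abs(ent_back - ent_obj)
        if val < best_val - 1e-12:
            best_val, best_t = val, t
    return int(best_t)


_DISPATCH = {
    "otsu": threshold_otsu,
    "li": threshold_li,
    "yen": threshold_yen,
    "renyi_entropy": threshold_renyi_entropy,
    "moments": threshold_moments,
    "minimum": threshold_minimum,
    "shanbhag": threshold_shanbhag,
}
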