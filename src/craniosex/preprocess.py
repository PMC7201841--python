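"""Image preprocessing chain for skull captures.

Grayscale conversion (ITU-R 601 luminance), bicubic upscaling, median
filtering, fuzzy C-means intensity segmentation and Canny contour
extraction.  Images are 2D float arrays with intensities in [0, 1],
0-based (row, col) coordinates, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters, transform

__all__ = [
    "FCMResult",
    "Contour",
    "to_grayscale",
    "upscale",
    "median_filter",
    "fcm_segment",
    "canny_contour",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if not np.all(np.isfinite(img)) or img.min() < 0 or img.max() > 1:
        raise ValueError("intensities must be finite and in [0, 1]")
    return img


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luminance 0.299 R + 0.587 G + 0.114 B per pixel."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("channels must be in [0, 1]")
    return rgb @ _LUMA


def upscale(img: np.ndarray, factor: float = 2.0) -> np.ndarray:
    """Bicubic upscaling to round(factor * dims); factor 1 is the identity."""
    img = _check_gray(img)
    if factor < 1:
        raise ValueError("upscale factor must be >= 1")
    out_shape = (int(round(factor * img.shape[0])),
                 int(round(factor * img.shape[1])))
    if out_shape == img.shape:
        return img.copy()
    out = transform.resize(img, out_shape, order=3, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median over a window x window neighborhood, edge-replicated borders."""
    img = _check_gray(img)
    if window < 3 or window % 2 == 0:
        raise ValueError("median window must be an odd integer >= 3")
    return ndimage.median_filter(img, size=window, mode="nearest")


@dataclass(frozen=True)
class FCMResult:
    """Fuzzy C-means segmentation of pixel intensities.

    memberships have shape (c,) + image shape and sum to 1 per pixel;
    centroids are sorted ascending; labels are the per-pixel argmax.
    """

    memberships: np.ndarray
    centroids: np.ndarray
    labels: np.ndarray
    n_iter: int
    objective: list
    degenerate: bool = False


def fcm_segment(img: np.ndarray, c: int = 2, fuzzifier: float = 2.0,
                tol: float = 1e-5, max_iter: int = 300,
                seed: int = 0) -> FCMResult:
    """Standard FCM on pixel intensities.

    Iterates the inverse-distance membership rule
    u_ij = 1 / sum_k (|x_i - c_j| / |x_i - c_k|)^{2/(m-1)} and the fuzzified
    centroid update until the largest centroid shift is below ``tol``; the
    objective sum u^m |x - c|^2 is non-increasing across iterations.
    Centroids are initialized at evenly spaced intensity quantiles, so the
    result is deterministic (``seed`` is accepted for interface stability).
    An (effectively) constant image yields a degenerate single cluster,
    flagged in the result.
    """
    img = _check_gray(img)
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    x = img.ravel()
    if np.ptp(x) < 1e-12:
        memberships = np.full((c,) + img.shape, 1.0 / c)
        centroids = np.full(c, float(x[0]) if x.size else 0.0)
        labels = np.zeros(img.shape, dtype=int)
        return FCMResult(memberships=memberships, centroids=centroids,
                         labels=labels, n_iter=0, objective=[],
                         degenerate=True)

    q = np.linspace(0, 1, c + 2)[1:-1]
    centroids = np.quantile(x, q)
    # quantile init can collide on heavily quantized images; spread if so
    if np.min(np.diff(np.sort(centroids))) < 1e-12:
        centroids = np.linspace(x.min(), x.max(), c + 2)[1:-1]

    power = 2.0 / (fuzzifier - 1.0)
    objective: list[float] = []
    u = None
    for n_iter in range(1, max_iter + 1):
        d = np.abs(x[None, :] - centroids[:, None])
        zero = d < 1e-15
        d = np.where(zero, 1e-15, d)
        inv = d ** (-power)
        u = inv / inv.sum(axis=0, keepdims=True)
        # exact-hit pixels get full membership in the touching cluster
        hit = zero.any(axis=0)
        if hit.any():
            u[:, hit] = zero[:, hit] / zero[:, hit].sum(axis=0, keepdims=True)
        um = u ** fuzzifier
        new_centroids = um @ x / um.sum(axis=1)
        objective.append(float(np.sum(um * (x[None, :] - centroids[:, None]) ** 2)))
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift < tol:
            break

    order = np.argsort(centroids)
    centroids = centroids[order]
    u = u[order]
    labels = np.argmax(u, axis=0).reshape(img.shape)
    return FCMResult(memberships=u.reshape((c,) + img.shape),
                     centroids=centroids, labels=labels,
                     n_iter=n_iter, objective=objective, degenerate=False)


@dataclass(frozen=True)
class Contour:
    """Ordered (row, col) pixel chain of the longest connected Canny edge."""

    points: np.ndarray   # (n, 2) int, possibly empty
    empty: bool

    def __len__(self) -> int:
        return len(self.points)


def _order_chain(coords: np.ndarray) -> np.ndarray:
    """Order edge pixels by 8-connected traversal from an endpoint."""
    coord_set = {tuple(p) for p in coords}
    neighbors = {}
    for p in coord_set:
        r, col = p
        nb = [(r + dr, col + dc)
              for dr in (-1, 0, 1) for dc in (-1, 0, 1)
              if (dr, dc) != (0, 0) and (r + dr, col + dc) in coord_set]
        neighbors[p] = nb
    start = min((p for p in coord_set),
                key=lambda p: (len(neighbors[p]), p))
    ordered = [start]
    visited = {start}
    current = start
    while True:
        nxt = [p for p in neighbors[current] if p not in visited]
        if not nxt:
            break
        # prefer 4-connected continuation for a tighter traversal
        nxt.sort(key=lambda p: (abs(p[0] - current[0]) + abs(p[1] - current[1]), p))
        current = nxt[0]
        ordered.append(current)
        visited.add(current)
    return np.asarray(ordered, dtype=int)


def canny_contour(img: np.ndarray, sigma: float = 2.0,
                  low: float = 0.1, high: float = 0.2) -> Contour:
    """Longest connected Canny edge chain.

    ``low`` and ``high`` are hysteresis thresholds as fractions of the
    maximum smoothed gradient magnitude.  A featureless image returns an
    empty contour (with ``empty=True``) rather than an error.
    """
    img = _check_gray(img)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    smoothed = ndimage.gaussian_filter(img, sigma)
    gmax = float(np.hypot(filters.sobel_h(smoothed),
                          filters.sobel_v(smoothed)).max())
    if gmax == 0.0:
        return Contour(points=np.empty((0, 2), dtype=int), empty=True)
    edges = feature.canny(img, sigma=sigma,
                          low_threshold=low * gmax,
                          high_threshold=high * gmax)
    if not edges.any():
        return Contour(points=np.empty((0, 2), dtype=int), empty=True)
    labels, n = ndimage.label(edges, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(edges, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    coords = np.argwhere(labels == largest)
    return Contour(points=_order_chain(coords), empty=False)
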