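"""Intensity-clustering segmentation of trabecular ROIs.

Pixels are clustered in the 1-D grayscale intensity space (no spatial
coordinates) by K-means (Lloyd's algorithm) or Fuzzy C-means, then rendered
as grayscale (pixel -> its centroid) or color (cluster -> fixed palette
entry) segmentation images.  Because an 8-bit image holds at most 256
distinct intensities, both algorithms run on the weighted intensity
histogram rather than on the raw pixel list, which is exactly equivalent
and orders of magnitude faster.

Clusters are always canonicalized to ascending-centroid order so that
cluster index i means the same thing (i-th darkest tissue compartment)
across images — a precondition for the downstream feature vectors to be
comparable.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from osteoseg.roi_io import RoiImage

DEFAULT_K_LIST = (8, 10, 12, 15)


@dataclass(frozen=True)
class ClusterConfig:
    """Configuration of one clustering run.

    For K-means, ``algorithm='exact'`` (the default) minimizes the
    within-cluster SSE globally by dynamic programming over the intensity
    histogram — in 1-D the optimal clusters are contiguous intervals of the
    sorted intensities, so the optimum is computable exactly and no
    initialization is needed.  ``algorithm='lloyd'`` runs classical Lloyd
    iteration instead, which can stop in a local optimum.

    ``init='quantile'`` places initial centroids at the (i+0.5)/K intensity
    quantiles, which is deterministic and needs no seed; ``init='random'``
    samples K distinct observed intensities with the seeded generator.
    ``init`` applies to Lloyd's K-means and to FCM.
    """

    K: int = 10
    method: str = "kmeans"  # {"kmeans", "fcm"}
    algorithm: str = "exact"  # {"exact", "lloyd"}; K-means only
    fuzzifier_m: float = 2.0
    tol: float = 1e-4
    max_iter: int = 300
    init: str = "quantile"  # {"quantile", "random"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.method not in ("kmeans", "fcm"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.algorithm not in ("exact", "lloyd"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.fuzzifier_m <= 1.0:
            raise ValueError(f"fuzzifier m must be > 1, got {self.fuzzifier_m}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.init not in ("quantile", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class SegmentationResult:
    """Per-pixel hard labels plus the canonical (ascending) centroids.

    ``memberships`` is the per-pixel K-column fuzzy membership matrix for
    FCM and ``None`` for K-means.  ``objective_history`` records the
    objective value after every iteration (within-cluster SSE for K-means,
    the weighted fuzzy objective for FCM) and is nonincreasing.
    """

    labels: np.ndarray
    centroids: np.ndarray
    memberships: np.ndarray | None
    n_iter: int
    objective: float
    objective_history: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.centroids)


def _prepare(image: RoiImage | np.ndarray, K: int):
    """Flatten to (unique intensity values, counts) and validate K."""
    pixels = image.pixels if isinstance(image, RoiImage) else np.asarray(image)
    flat = pixels.reshape(-1).astype(np.float64)
    if flat.size == 0:
        raise ValueError("cannot segment an empty image")
    if K > flat.size:
        raise ValueError(f"K={K} exceeds the number of pixels ({flat.size})")
    values, counts = np.unique(flat, return_counts=True)
    return flat, values, counts.astype(np.float64)


def _init_centroids(flat: np.ndarray, values: np.ndarray, cfg: ClusterConfig) -> np.ndarray:
    if cfg.init == "quantile":
        qs = (np.arange(cfg.K) + 0.5) / cfg.K
        return np.quantile(flat, qs)
    rng = np.random.default_rng(cfg.seed)
    if len(values) >= cfg.K:
        return np.sort(rng.choice(values, size=cfg.K, replace=False).astype(np.float64))
    return np.sort(rng.choice(flat, size=cfg.K, replace=True).astype(np.float64))


def _assign(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment; ties go to the lower cluster index."""
    dist = np.abs(values[:, None] - centroids[None, :])
    return np.argmin(dist, axis=1)


def _sse(values: np.ndarray, counts: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    return float(np.sum(counts * (values - centroids[assign]) ** 2))


def _kmeans_exact(image, values: np.ndarray, counts: np.ndarray, K: int) -> SegmentationResult:
    """Globally optimal 1-D K-means by dynamic programming.

    Optimal 1-D clusters are contiguous intervals of the sorted unique
    intensities, so minimizing SSE reduces to optimally placing K-1 interval
    boundaries — an O(U^2 K) dynamic program over the U <= 256 weighted
    unique values.
    """
    U = len(values)
    k_eff = min(K, U)
    # Weighted prefix sums give interval SSE in O(1):
    # cost(i, j) = sum w v^2 - (sum w v)^2 / sum w over values[i:j].
    w0 = np.concatenate([[0.0], np.cumsum(counts)])
    w1 = np.concatenate([[0.0], np.cumsum(counts * values)])
    w2 = np.concatenate([[0.0], np.cumsum(counts * values**2)])
    dw = w0[None, :] - w0[:, None]
    ds = w1[None, :] - w1[:, None]
    d2 = w2[None, :] - w2[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = d2 - np.where(dw > 0, ds**2 / np.where(dw > 0, dw, 1.0), 0.0)
    cost = np.where(dw > 0, np.maximum(cost, 0.0), 0.0)  # cost[i, j] for interval [i, j)

    INF = np.inf
    D = np.full((k_eff + 1, U + 1), INF)
    D[0, 0] = 0.0
    back = np.zeros((k_eff + 1, U + 1), dtype=np.int64)
    for k in range(1, k_eff + 1):
        cand = D[k - 1][:, None] + cost  # cand[i, j]: last cluster = [i, j)
        cand[np.isnan(cand)] = INF
        back[k] = np.argmin(cand, axis=0)
        D[k] = cand[back[k], np.arange(U + 1)]

    # Backtrack interval boundaries and assign unique values to clusters.
    bounds = [U]
    j = U
    for k in range(k_eff, 0, -1):
        j = int(back[k][j])
        bounds.append(j)
    bounds = bounds[::-1]
    assign = np.empty(U, dtype=np.int64)
    centroids = np.empty(K, dtype=np.float64)
    for k in range(k_eff):
        lo, hi = bounds[k], bounds[k + 1]
        assign[lo:hi] = k
        wsum = counts[lo:hi].sum()
        centroids[k] = float(np.sum(counts[lo:hi] * values[lo:hi]) / wsum) if wsum > 0 else values[lo]
    # Fewer distinct intensities than K: pad trailing clusters (empty) with
    # the top centroid so the canonical centroid vector keeps length K.
    centroids[k_eff:] = centroids[k_eff - 1]
    objective = float(D[k_eff, U])
    labels = _labels_for_pixels(image, values, assign)
    return SegmentationResult(
        labels=labels,
        centroids=centroids,
        memberships=None,
        n_iter=1,
        objective=objective,
        objective_history=[objective],
    )


def kmeans_segment(
    image: RoiImage | np.ndarray,
    cfg: ClusterConfig,
    initial_centroids: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment by K-means on pixel intensities.

    With ``cfg.algorithm='exact'`` (default) the within-cluster SSE is
    minimized globally by the 1-D dynamic program.  With ``'lloyd'``,
    classical Lloyd iteration runs from the configured initialization (or
    the explicit ``initial_centroids``) until the largest centroid movement
    is <= ``cfg.tol`` or ``cfg.max_iter`` is reached; empty clusters are
    repaired by moving their centroid onto the intensity farthest from its
    current centroid.  Results are canonicalized to ascending-centroid
    order, so permuting ``initial_centroids`` leaves the result unchanged.
    """
    if cfg.method != "kmeans":
        raise ValueError(f"kmeans_segment called with method={cfg.method!r}")
    flat, values, counts = _prepare(image, cfg.K)
    if cfg.algorithm == "exact":
        return _kmeans_exact(image, values, counts, cfg.K)
    if initial_centroids is not None:
        centroids = np.asarray(initial_centroids, dtype=np.float64).copy()
        if centroids.shape != (cfg.K,):
            raise ValueError(f"initial_centroids must have shape ({cfg.K},)")
    else:
        centroids = _init_centroids(flat, values, cfg).astype(np.float64)
    history: list[float] = []
    assign = _assign(values, centroids)
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        # Repair empty clusters before the update so K clusters survive.
        present = np.bincount(assign, minlength=cfg.K) > 0
        if not present.all():
            dist_own = np.abs(values - centroids[assign])
            for k in np.where(~present)[0]:
                far = int(np.argmax(dist_own))
                if dist_own[far] <= 0:
                    break  # degenerate image: fewer distinct values than K
                centroids[k] = values[far]
                assign = _assign(values, centroids)
                dist_own = np.abs(values - centroids[assign])

        new_centroids = centroids.copy()
        for k in range(cfg.K):
            mask = assign == k
            w = counts[mask]
            if w.sum() > 0:
                new_centroids[k] = np.sum(w * values[mask]) / w.sum()
        movement = float(np.max(np.abs(new_centroids - centroids)))
        centroids = new_centroids
        assign = _assign(values, centroids)
        history.append(_sse(values, counts, centroids, assign))
        if movement <= cfg.tol:
            break

    centroids, assign, _ = _canonicalize(centroids, assign)
    labels = _labels_for_pixels(image, values, assign)
    return SegmentationResult(
        labels=labels,
        centroids=centroids,
        memberships=None,
        n_iter=n_iter,
        objective=history[-1],
        objective_history=history,
    )


def fcm_segment(
    image: RoiImage | np.ndarray,
    cfg: ClusterConfig,
    initial_centroids: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment by standard Fuzzy C-means on pixel intensities.

    Memberships follow the usual inverse-distance rule with exponent
    2/(m-1); centroids are membership-weighted means.  A pixel coinciding
    exactly with a centroid receives full membership in that cluster.
    Iteration stops when the largest membership change is <= ``cfg.tol``.
    Hard labels are the per-pixel membership argmax.
    """
    if cfg.method != "fcm":
        raise ValueError(f"fcm_segment called with method={cfg.method!r}")
    flat, values, counts = _prepare(image, cfg.K)
    if initial_centroids is not None:
        centroids = np.asarray(initial_centroids, dtype=np.float64).copy()
    else:
        centroids = _init_centroids(flat, values, cfg).astype(np.float64)
    m = cfg.fuzzifier_m
    expo = 2.0 / (m - 1.0)

    u = _fcm_memberships(values, centroids, expo)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        um = u**m
        w = counts[:, None] * um
        denom = w.sum(axis=0)
        # A cluster with zero total membership keeps its centroid.
        new_centroids = np.where(denom > 0, (w * values[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), centroids)
        new_u = _fcm_memberships(values, new_centroids, expo)
        delta = float(np.max(np.abs(new_u - u)))
        centroids, u = new_centroids, new_u
        d2 = (values[:, None] - centroids[None, :]) ** 2
        history.append(float(np.sum(counts[:, None] * (u**m) * d2)))
        if delta <= cfg.tol:
            break

    order = np.argsort(centroids, kind="stable")
    centroids = centroids[order]
    u = u[:, order]
    assign = np.argmax(u, axis=1)
    labels = _labels_for_pixels(image, values, assign)
    memberships = _expand_to_pixels(image, values, u)
    return SegmentationResult(
        labels=labels,
        centroids=centroids,
        memberships=memberships,
        n_iter=n_iter,
        objective=history[-1],
        objective_history=history,
    )


def _fcm_memberships(values: np.ndarray, centroids: np.ndarray, expo: float) -> np.ndarray:
    """Membership matrix over unique values; rows sum to one.

    Uses the ratio form u_ik = 1 / sum_j (d_ik / d_ij)^expo, which is stable
    for small fuzzifiers: ratios for the nearest centroid never exceed 1 and
    an overflowing ratio simply drives a far cluster's membership to 0.
    """
    d = np.abs(values[:, None] - centroids[None, :])
    coincident = d == 0.0
    has_coincident = coincident.any(axis=1)
    d_safe = np.where(coincident, 1.0, d)
    with np.errstate(over="ignore"):
        ratios = (d_safe[:, :, None] / d_safe[:, None, :]) ** expo
        u = 1.0 / ratios.sum(axis=2)
    # Full membership to the (first) coincident centroid: no division by zero.
    for i in np.where(has_coincident)[0]:
        u[i] = 0.0
        u[i, int(np.argmax(coincident[i]))] = 1.0
    return u


def _canonicalize(centroids: np.ndarray, assign: np.ndarray):
    """Reorder clusters by ascending centroid and remap assignments."""
    order = np.argsort(centroids, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return centroids[order], remap[assign], order


def _labels_for_pixels(image, values: np.ndarray, assign: np.ndarray) -> np.ndarray:
    pixels = image.pixels if isinstance(image, RoiImage) else np.asarray(image)
    idx = np.searchsorted(values, pixels.reshape(-1).astype(np.float64))
    return assign[idx].reshape(pixels.shape)


def _expand_to_pixels(image, values: np.ndarray, u: np.ndarray) -> np.ndarray:
    pixels = image.pixels if isinstance(image, RoiImage) else np.asarray(image)
    idx = np.searchsorted(values, pixels.reshape(-1).astype(np.float64))
    return u[idx].reshape(pixels.shape + (u.shape[1],))


def segment(image: RoiImage | np.ndarray, cfg: ClusterConfig) -> SegmentationResult:
    """Dispatch to K-means or FCM according to ``cfg.method``."""
    if cfg.method == "kmeans":
        return kmeans_segment(image, cfg)
    return fcm_segment(image, cfg)


def render_grayscale_segmentation(seg: SegmentationResult) -> RoiImage:
    """Replace each pixel by its cluster centroid (rounded to 0-255)."""
    lut = np.clip(np.floor(seg.centroids + 0.5), 0, 255).astype(np.uint8)
    return RoiImage(lut[seg.labels], source_id="segmentation-grayscale")


def cluster_palette(K: int) -> np.ndarray:
    """Fixed maximally-distinct palette: K equal hue steps at full S and V."""
    cols = [colorsys.hsv_to_rgb(i / K, 1.0, 1.0) for i in range(K)]
    return np.clip(np.floor(np.array(cols) * 255 + 0.5), 0, 255).astype(np.uint8)


def render_color_segmentation(seg: SegmentationResult) -> np.ndarray:
    """Map canonical cluster i to palette color i; returns an HxWx3 array."""
    return cluster_palette(seg.K)[seg.labels]


def cluster_summary(seg: SegmentationResult) -> pd.DataFrame:
    """Per-cluster table: index, centroid intensity, pixel count."""
    counts = np.bincount(seg.labels.reshape(-1), minlength=seg.K)
    return pd.DataFrame(
        {
            "cluster": np.arange(seg.K),
            "centroid": seg.centroids,
            "pixel_count": counts,
        }
    )
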