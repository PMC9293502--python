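"""Fuzzy C-means clustering engines for grayscale image segmentation.

Four engines share one alternating-optimization loop:

* :func:`fit_fcm` — classical fuzzy C-means on pixel intensities, minimizing
  ``J = sum_k sum_i u_ik^s (p_i - y_k)^2`` subject to row-stochastic
  memberships.
* :func:`fit_kfcm` — kernelized FCM: distances are computed in the feature
  space induced by a Gaussian RBF kernel, ``d^2 = 2 (1 - K(p, y))`` with
  ``K(x, y) = exp(-(x - y)^2 / sigma^2)``.  More robust to outlying
  intensities because the kernel saturates far from a center.
* :func:`fit_bcfcm` — bias-corrected FCM: adds a neighborhood regularizer
  ``(alpha / N_R) sum_{r in N_i} (p_r - y_k)^2`` so each pixel is pulled
  toward the class of its spatial neighbors (noise / inhomogeneity
  robustness).
* :func:`fit_enfcm` — efficiency-enhanced FCM: clusters the gray-level
  histogram of a neighborhood-filtered image instead of individual pixels,
  giving the same fixed points at a fraction of the distance evaluations.

All engines operate on the masked pixels of an :class:`IntensityImage` and
return a :class:`ClusteringResult` holding the fuzzy partition, the cluster
centers, the per-iteration objective trace and a defuzzified label map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class InvalidInputError(ValueError):
    """Raised for malformed inputs (non-finite data, shape mismatch, n < c)."""


class DegenerateInputError(ValueError):
    """Raised when the data cannot support the requested clustering
    (e.g. all pixels identical, single-pixel image for a spatial engine)."""


class DegenerateClusterError(RuntimeError):
    """Raised when a cluster loses all support (zero membership mass)."""

    def __init__(self, cluster_index: int):
        self.cluster_index = int(cluster_index)
        super().__init__(
            f"cluster {cluster_index} has zero membership mass (empty cluster)"
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IntensityImage:
    """A 2D or 3D grayscale image with optional physical spacing and mask.

    Parameters
    ----------
    values
        Real-valued intensity grid, arbitrary units.
    spacing
        Physical pixel size in mm per axis (metadata only).
    mask
        Boolean grid of pixels to cluster; defaults to the full grid.
    """

    values: np.ndarray
    spacing: Optional[tuple] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise InvalidInputError(
                f"image must be 2D or 3D, got {self.values.ndim}D"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("image contains non-finite values")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise InvalidInputError(
                    f"mask shape {self.mask.shape} != image shape "
                    f"{self.values.shape}"
                )

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """Flat vector of the masked intensities, in C-order scan order."""
        return self.values[self.mask]


@dataclass
class ClusteringConfig:
    """Shared configuration for all four engines.

    ``fuzzifier`` is the softness exponent s (> 1; s = 2 is the conventional
    choice).  ``kernel_bandwidth`` is the Gaussian sigma for the kernelized
    engine ("auto" resolves to the standard deviation of the masked
    intensities).  ``spatial_weight`` is the neighborhood weight alpha used
    by the bias-corrected and histogram engines.  ``neighborhood`` is the
    Chebyshev radius of the neighbor stencil (1 -> 3x3 minus center in 2D).
    """

    n_clusters: int = 3
    fuzzifier: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    kernel_bandwidth: float | Literal["auto"] = "auto"
    spatial_weight: float = 0.85
    neighborhood: int = 1
    n_bins: int = 256
    seed: int = 0
    init: Literal["quantile", "random"] = "quantile"

    def __post_init__(self):
        if self.n_clusters < 1:
            raise InvalidInputError("n_clusters must be >= 1")
        if not self.fuzzifier > 1:
            raise InvalidInputError("fuzzifier must be > 1")
        if not self.tol > 0:
            raise InvalidInputError("tol must be > 0")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")
        if self.kernel_bandwidth != "auto" and not self.kernel_bandwidth > 0:
            raise InvalidInputError("kernel_bandwidth must be > 0 or 'auto'")
        if self.spatial_weight < 0:
            raise InvalidInputError("spatial_weight must be >= 0")
        if self.n_bins < 1:
            raise InvalidInputError("n_bins must be >= 1")


@dataclass
class MembershipMatrix:
    """An n x c fuzzy partition: entries in [0, 1], rows summing to 1."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidInputError("membership matrix must be non-empty n x c")

    def validate(self, atol: float = 1e-9) -> None:
        u = self.values
        if np.any(u < -atol) or np.any(u > 1 + atol):
            raise InvalidInputError("membership values outside [0, 1]")
        if not np.allclose(u.sum(axis=1), 1.0, atol=atol):
            raise InvalidInputError("membership rows do not sum to 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusteringResult:
    """Output of an engine run."""

    membership: MembershipMatrix
    centers: np.ndarray
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    labels: Optional[np.ndarray] = None
    engine: str = ""
    n_distance_evals: int = 0


# ---------------------------------------------------------------------------
# Update primitives
# ---------------------------------------------------------------------------

def _memberships_from_distances(dist: np.ndarray, s: float) -> np.ndarray:
    """Row-stochastic memberships minimizing sum u^s d for fixed distances.

    ``u_ik = [sum_z (d_ik / d_iz)^(1/(s-1))]^-1``.  A zero distance gives the
    pixel full membership in the lowest-index zero-distance cluster.
    """
    dist = np.asarray(dist, dtype=float)
    u = np.empty_like(dist)
    zero = dist <= 0.0
    has_zero = zero.any(axis=1)
    if has_zero.any():
        rows = np.where(has_zero)[0]
        u[rows] = 0.0
        u[rows, np.argmax(zero[rows], axis=1)] = 1.0
    reg = ~has_zero
    if reg.any():
        w = dist[reg] ** (-1.0 / (s - 1.0))
        u[reg] = w / w.sum(axis=1, keepdims=True)
    return u


def update_memberships(
    data: np.ndarray,
    centers: np.ndarray,
    s: float = 2.0,
    distance_kind: Literal["euclidean-squared", "kernel-induced"] = "euclidean-squared",
    sigma: float = 1.0,
) -> MembershipMatrix:
    """One membership update for intensity data against the given centers.

    ``euclidean-squared`` uses ``d_ik = (p_i - y_k)^2`` (plain FCM);
    ``kernel-induced`` uses ``d_ik = 1 - exp(-(p_i - y_k)^2 / sigma^2)``
    (the kernel-space distance up to the constant factor 2, which cancels in
    the ratio).
    """
    data = np.asarray(data, dtype=float).ravel()
    centers = np.asarray(centers, dtype=float).ravel()
    if not (np.all(np.isfinite(data)) and np.all(np.isfinite(centers))):
        raise InvalidInputError("non-finite data or centers")
    if not s > 1:
        raise InvalidInputError("fuzzifier must be > 1")
    diff2 = (data[:, None] - centers[None, :]) ** 2
    if distance_kind == "euclidean-squared":
        dist = diff2
    elif distance_kind == "kernel-induced":
        dist = -np.expm1(-diff2 / (sigma * sigma))
    else:
        raise InvalidInputError(f"unknown distance_kind {distance_kind!r}")
    return MembershipMatrix(_memberships_from_distances(dist, s))


def update_centers(
    data: np.ndarray,
    membership: MembershipMatrix | np.ndarray,
    s: float = 2.0,
    kernel_sigma: Optional[float] = None,
    centers: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One center update: the u^s-weighted mean of the data per cluster.

    With ``kernel_sigma`` set, the weights are ``u^s K(p, y)`` evaluated at
    the current ``centers`` (one Gaussian mean-shift step — the kernelized
    fixed-point form).
    """
    data = np.asarray(data, dtype=float).ravel()
    u = membership.values if isinstance(membership, MembershipMatrix) else np.asarray(membership, float)
    if not np.all(np.isfinite(data)):
        raise InvalidInputError("non-finite data")
    us = u ** s
    if kernel_sigma is None:
        w = us
    else:
        if centers is None:
            raise InvalidInputError("kernel center update needs current centers")
        centers = np.asarray(centers, dtype=float).ravel()
        k = np.exp(-((data[:, None] - centers[None, :]) ** 2) / (kernel_sigma ** 2))
        w = us * k
    denom = w.sum(axis=0)
    for k_idx in np.where(denom <= 0)[0]:
        raise DegenerateClusterError(k_idx)
    return (w * data[:, None]).sum(axis=0) / denom


def defuzzify(membership: MembershipMatrix, mask: np.ndarray) -> np.ndarray:
    """Hard label grid from a fuzzy partition: per-pixel argmax (ties to the
    lowest cluster index), -1 outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.full(mask.shape, -1, dtype=int)
    labels[mask] = np.argmax(membership.values, axis=1)
    return labels


# ---------------------------------------------------------------------------
# Shared fitting machinery
# ---------------------------------------------------------------------------

def _init_centers(data: np.ndarray, config: ClusteringConfig) -> np.ndarray:
    c = config.n_clusters
    if config.init == "quantile":
        q = (np.arange(c) + 0.5) / c
        return np.quantile(data, q)
    if config.init == "random":
        uniq = np.unique(data)
        if uniq.size < c:
            raise DegenerateInputError(
                f"only {uniq.size} distinct intensities for {c} clusters"
            )
        rng = np.random.default_rng(config.seed)
        return np.sort(rng.choice(uniq, size=c, replace=False))
    raise InvalidInputError(f"unknown init {config.init!r}")


def _check_fit_inputs(data: np.ndarray, config: ClusteringConfig) -> None:
    if data.size < config.n_clusters:
        raise InvalidInputError(
            f"n < c: {data.size} masked pixels for {config.n_clusters} clusters"
        )
    if config.n_clusters >= 2 and np.ptp(data) == 0:
        raise DegenerateInputError("all masked pixels have identical intensity")


def _neighbor_stats(image: IntensityImage, radius: int):
    """Per-masked-pixel neighbor count, mean and mean-of-squares over masked
    neighbors within a Chebyshev-`radius` stencil, edges clipped.

    Pixels with no masked neighbor fall back to their own value, so the
    spatial term degenerates gracefully to the plain data term there.
    """
    vals, mask = image.values, image.mask
    size = 2 * radius + 1
    footprint = np.ones((size,) * vals.ndim)
    footprint[(radius,) * vals.ndim] = 0.0
    maskf = mask.astype(float)
    cnt = ndimage.convolve(maskf, footprint, mode="constant", cval=0.0)
    sm = ndimage.convolve(vals * maskf, footprint, mode="constant", cval=0.0)
    sq = ndimage.convolve(vals * vals * maskf, footprint, mode="constant", cval=0.0)
    cnt_m, sm_m, sq_m = cnt[mask], sm[mask], sq[mask]
    p = vals[mask]
    safe = cnt_m > 0
    mean = np.where(safe, sm_m / np.maximum(cnt_m, 1), p)
    meansq = np.where(safe, sq_m / np.maximum(cnt_m, 1), p * p)
    return cnt_m, mean, meansq


def _converged(u_new: np.ndarray, u_old: Optional[np.ndarray], tol: float) -> bool:
    return u_old is not None and float(np.max(np.abs(u_new - u_old))) < tol


def fit_fcm(image: IntensityImage, config: ClusteringConfig) -> ClusteringResult:
    """Classical FCM on the masked intensities.

    Alternates the closed-form membership update ``u_ik \\propto
    d_ik^{-1/(s-1)}`` and center update ``y_k = sum u^s p / sum u^s`` until
    the max absolute membership change drops below ``tol`` or ``max_iter``
    is reached.  Each half-step is the exact coordinate minimizer, so the
    objective trace is nonincreasing.
    """
    data = image.masked_values()
    _check_fit_inputs(data, config)
    s = config.fuzzifier
    centers = _init_centers(data, config)
    u_prev = None
    trace: list[float] = []
    n_evals = 0
    for it in range(config.max_iter):
        d = (data[:, None] - centers[None, :]) ** 2
        n_evals += d.size
        u = _memberships_from_distances(d, s)
        centers = update_centers(data, u, s)
        d_new = (data[:, None] - centers[None, :]) ** 2
        trace.append(float(np.sum(u ** s * d_new)))
        if _converged(u, u_prev, config.tol):
            break
        u_prev = u
    membership = MembershipMatrix(u)
    return ClusteringResult(
        membership=membership,
        centers=centers,
        objective_trace=trace,
        n_iter=len(trace),
        labels=defuzzify(membership, image.mask),
        engine="fcm",
        n_distance_evals=n_evals,
    )


def _resolve_sigma(data: np.ndarray, config: ClusteringConfig) -> float:
    if config.kernel_bandwidth == "auto":
        sd = float(np.std(data))
        return sd if sd > 0 else 1.0
    return float(config.kernel_bandwidth)


def fit_kfcm(image: IntensityImage, config: ClusteringConfig) -> ClusteringResult:
    """Kernelized FCM with a Gaussian RBF kernel.

    Minimizes ``sum_k sum_i u_ik^s 2 (1 - K(p_i, y_k))``.  Memberships use
    the kernel-induced distance ``1 - K``; centers take one kernel-weighted
    mean-shift step ``y_k = sum u^s K p / sum u^s K`` per iteration, which
    monotonically decreases the objective (mean-shift ascent on the
    kernel-weighted density).
    """
    data = image.masked_values()
    _check_fit_inputs(data, config)
    s = config.fuzzifier
    sigma = _resolve_sigma(data, config)
    sig2 = sigma * sigma
    centers = _init_centers(data, config)
    u_prev = None
    trace: list[float] = []
    n_evals = 0
    for it in range(config.max_iter):
        diff2 = (data[:, None] - centers[None, :]) ** 2
        n_evals += diff2.size
        d = -np.expm1(-diff2 / sig2)  # 1 - K, cancellation-safe for large sigma
        u = _memberships_from_distances(d, s)
        centers = update_centers(data, u, s, kernel_sigma=sigma, centers=centers)
        d_new = -np.expm1(-((data[:, None] - centers[None, :]) ** 2) / sig2)
        trace.append(float(np.sum(u ** s * 2.0 * d_new)))
        if _converged(u, u_prev, config.tol):
            break
        u_prev = u
    membership = MembershipMatrix(u)
    return ClusteringResult(
        membership=membership,
        centers=centers,
        objective_trace=trace,
        n_iter=len(trace),
        labels=defuzzify(membership, image.mask),
        engine="kfcm",
        n_distance_evals=n_evals,
    )


def fit_bcfcm(image: IntensityImage, config: ClusteringConfig) -> ClusteringResult:
    """Bias-corrected FCM: FCM plus a spatial neighborhood regularizer.

    Objective: ``sum_k sum_i u_ik^s [ (p_i - y_k)^2 +
    (alpha / |N_i|) sum_{r in N_i} (p_r - y_k)^2 ]`` with neighborhoods
    clipped at image edges (|N_i| is the actual masked neighbor count).
    Setting ``alpha = 0`` reduces exactly to FCM.
    """
    if image.values.size == 1:
        raise DegenerateInputError("spatial engine needs more than one pixel")
    data = image.masked_values()
    _check_fit_inputs(data, config)
    s, alpha = config.fuzzifier, config.spatial_weight
    _, nb_mean, nb_meansq = _neighbor_stats(image, config.neighborhood)
    centers = _init_centers(data, config)
    u_prev = None
    trace: list[float] = []
    n_evals = 0

    def distances(y: np.ndarray) -> np.ndarray:
        # (p_i - y_k)^2 + alpha * mean_r (p_r - y_k)^2, expanded in moments
        d = (data[:, None] - y[None, :]) ** 2
        d += alpha * (
            nb_meansq[:, None] - 2.0 * y[None, :] * nb_mean[:, None] + y[None, :] ** 2
        )
        return d

    for it in range(config.max_iter):
        d = distances(centers)
        n_evals += d.size
        u = _memberships_from_distances(d, s)
        us = u ** s
        denom = (1.0 + alpha) * us.sum(axis=0)
        for k_idx in np.where(denom <= 0)[0]:
            raise DegenerateClusterError(k_idx)
        centers = (us * (data + alpha * nb_mean)[:, None]).sum(axis=0) / denom
        trace.append(float(np.sum(us * distances(centers))))
        if _converged(u, u_prev, config.tol):
            break
        u_prev = u
    membership = MembershipMatrix(u)
    return ClusteringResult(
        membership=membership,
        centers=centers,
        objective_trace=trace,
        n_iter=len(trace),
        labels=defuzzify(membership, image.mask),
        engine="bcfcm",
        n_distance_evals=n_evals,
    )


def _quantize(values: np.ndarray, n_bins: int):
    """Gray-level quantization: lossless when the distinct values fit in
    ``n_bins``, otherwise uniform bins represented by their centers.

    Returns (levels, counts, per-pixel level index).
    """
    uniq, inverse, counts = np.unique(values, return_inverse=True, return_counts=True)
    if uniq.size <= n_bins:
        return uniq, counts.astype(float), inverse
    lo, hi = float(values.min()), float(values.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    remap = np.cumsum(keep) - 1
    return centers[keep], counts[keep], remap[idx]


def fit_enfcm(image: IntensityImage, config: ClusteringConfig) -> ClusteringResult:
    """Efficiency-enhanced FCM via gray-level histogram clustering.

    Builds the linearly filtered image ``xi_i = (p_i + alpha * mean_r p_r) /
    (1 + alpha)``, quantizes it to at most ``n_bins`` gray levels with counts
    ``gamma_l``, clusters the levels minimizing ``sum_k sum_l gamma_l u_kl^s
    (xi_l - y_k)^2``, then maps level memberships back to pixels.  With
    ``alpha = 0`` and lossless quantization this is an exact reweighting of
    pixel-level FCM.
    """
    if image.values.size == 1:
        raise DegenerateInputError("spatial engine needs more than one pixel")
    data = image.masked_values()
    _check_fit_inputs(data, config)
    if config.n_bins < config.n_clusters:
        raise InvalidInputError("n_bins must be >= n_clusters")
    s, alpha = config.fuzzifier, config.spatial_weight
    _, nb_mean, _ = _neighbor_stats(image, config.neighborhood)
    xi = (data + alpha * nb_mean) / (1.0 + alpha)
    levels, gamma, pixel_level = _quantize(xi, config.n_bins)
    if levels.size < config.n_clusters:
        raise DegenerateInputError(
            f"only {levels.size} filtered gray levels for "
            f"{config.n_clusters} clusters"
        )
    centers = _init_centers(xi, config)
    u_prev = None
    trace: list[float] = []
    n_evals = 0
    for it in range(config.max_iter):
        d = (levels[:, None] - centers[None, :]) ** 2
        n_evals += d.size
        u = _memberships_from_distances(d, s)
        us = u ** s
        denom = (gamma[:, None] * us).sum(axis=0)
        for k_idx in np.where(denom <= 0)[0]:
            raise DegenerateClusterError(k_idx)
        centers = (gamma[:, None] * us * levels[:, None]).sum(axis=0) / denom
        d_new = (levels[:, None] - centers[None, :]) ** 2
        trace.append(float(np.sum(gamma[:, None] * us * d_new)))
        if _converged(u, u_prev, config.tol):
            break
        u_prev = u
    membership = MembershipMatrix(u[pixel_level])
    return ClusteringResult(
        membership=membership,
        centers=centers,
        objective_trace=trace,
        n_iter=len(trace),
        labels=defuzzify(membership, image.mask),
        engine="enfcm",
        n_distance_evals=n_evals,
    )


ENGINES = {
    "fcm": fit_fcm,
    "kfcm": fit_kfcm,
    "bcfcm": fit_bcfcm,
    "enfcm": fit_enfcm,
}


def fit(image: IntensityImage, config: ClusteringConfig, engine: str = "kfcm") -> ClusteringResult:
    """Dispatch to one of the four engines by name."""
    try:
        fn = ENGINES[engine]
    except KeyError:
        raise InvalidInputError(
            f"unknown engine {engine!r}; choose from {sorted(ENGINES)}"
        ) from None
    return fn(image, config)
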