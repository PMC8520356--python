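"""Hybrid global/local Otsu threshold segmentation guided by edge saliency.

The segmentation family implemented here targets 2-D grayscale brain MR
slices in which the structures of interest (brain tissue vs. CSF-filled
ventricles and background) differ chiefly in gray level.  The pipeline:

1. Sobel gradient magnitudes ``S(i,j)`` are computed over the slice,
   together with their global mean ``S_avg`` and 3x3 local window means
   ``S_mu(i,j)``.
2. Each pixel is classified as *detail* (edge class, label ``l1``) when
   ``min(S, S_mu) > S_avg``, else *remainder* (``l2``).  Requiring the
   local window mean to exceed the global mean as well suppresses isolated
   noise spikes: a lone impulse has high ``S`` on its neighbours but a
   diluted ``S_mu``.
3. The label map partitions the slice into a detail sub-image ``I1`` and a
   remainder sub-image ``I2``.  Each sub-image receives its own Otsu
   threshold (``T1``, ``T2``); the whole-image Otsu threshold ``T_otsu``
   serves as a fallback when a sub-image is empty or degenerate.
4. Per-sub-image binary maps ``B1``/``B2`` are merged into the final map
   ``B``, each pixel taking the value assigned by its owning sub-image.

Thresholding the edge band separately places its cut near the boundary
mid-intensity, while the remainder sub-image is thresholded on a histogram
free of partial-volume ramp pixels; both effects matter on noisy, shading-
corrupted slices where a single global threshold is biased by the mixed
boundary population.

All thresholds follow the convention ``foreground = gray > T`` (invertible
via ``invert=True`` for acquisitions where the target class is dark).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage


class SegmentationError(ValueError):
    """Raised for invalid segmentation inputs (bad masks, empty histograms)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrayImage:
    """A 2-D integer gray-level slice with physical pixel spacing.

    Parameters
    ----------
    values : ndarray of int, shape (M, N)
        Gray levels in ``[0, gray_levels - 1]``.  M, N >= 3.
    pixel_spacing : float
        In-plane pixel size in mm/pixel (isotropic).
    gray_levels : int
        Number of representable gray levels L (256 for 8-bit data).
    """

    values: np.ndarray
    pixel_spacing: float = 1.0
    gray_levels: int = 256

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] < 3:
            raise SegmentationError("image must be 2-D with at least 3x3 pixels")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise SegmentationError("gray values must be integers")
        v = np.round(np.asarray(v, dtype=float)).astype(np.int64)
        if self.gray_levels < 2:
            raise SegmentationError("gray_levels must be >= 2")
        if v.min() < 0 or v.max() >= self.gray_levels:
            raise SegmentationError(
                f"gray values must lie in [0, {self.gray_levels - 1}]"
            )
        if not self.pixel_spacing > 0:
            raise SegmentationError("pixel_spacing must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def histogram(self) -> np.ndarray:
        """Gray-level histogram with ``gray_levels`` bins."""
        return np.bincount(self.values.ravel(), minlength=self.gray_levels)


@dataclass(frozen=True)
class GradientMap:
    """Sobel gradient magnitudes plus the summary statistics used downstream.

    ``S_avg`` is the global mean of ``S``; ``S_mu`` holds 3x3 window means of
    ``S`` (edge-replicated borders).
    """

    S: np.ndarray
    S_avg: float
    S_mu: np.ndarray

    def __post_init__(self) -> None:
        if self.S.shape != self.S_mu.shape:
            raise SegmentationError("S and S_mu must share a shape")


@dataclass(frozen=True)
class LabelMap:
    """Binary pixel classification: detail/edge class ``l1`` vs. rest ``l2``."""

    detail: np.ndarray  # bool; True = l1

    @property
    def labels(self) -> np.ndarray:
        """Integer encoding: 1 for the detail class l1, 2 for l2."""
        return np.where(self.detail, 1, 2)


class OtsuResult(NamedTuple):
    threshold: int
    degenerate: bool


@dataclass(frozen=True)
class SegmentationResult:
    """Full record of one hybrid segmentation run, intermediates included."""

    label_map: LabelMap
    T_otsu: int
    T1: int
    T2: int
    I1_mask: np.ndarray
    I2_mask: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    B: np.ndarray


# ---------------------------------------------------------------------------
# gradient and pixel classification
# ---------------------------------------------------------------------------


def sobel_gradient(img: GrayImage) -> GradientMap:
    """Sobel gradient magnitude map with global and 3x3-local means.

    The magnitude is the Euclidean norm ``sqrt(Gx^2 + Gy^2)`` of the two
    standard 3x3 Sobel responses; image borders are handled by edge
    replication, as are the 3x3 windows for ``S_mu``.
    """
    f = img.values.astype(float)
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    S = np.hypot(gx, gy)
    S_mu = ndimage.uniform_filter(S, size=3, mode="nearest")
    return GradientMap(S=S, S_avg=float(S.mean()), S_mu=S_mu)


def classify_pixels(grad: GradientMap) -> LabelMap:
    """Label pixels as detail (``l1``) or remainder (``l2``).

    A pixel is detail iff both its own gradient magnitude and its 3x3-window
    gradient mean strictly exceed the global gradient mean:
    ``min(S, S_mu) > S_avg``.  The strict inequality makes constant images
    (S identically zero) all-``l2``, so the hybrid pipeline degrades to a
    plain global Otsu threshold.
    """
    detail = np.minimum(grad.S, grad.S_mu) > grad.S_avg
    return LabelMap(detail=detail)


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------


def otsu_threshold(histogram: Sequence[float] | np.ndarray) -> OtsuResult:
    """Gray level maximizing the between-class variance of a histogram.

    Candidate thresholds t run over ``[0, L-2]``; class 0 is ``{g <= t}``.
    The between-class variance is ``w0(t) w1(t) (mu0(t) - mu1(t))^2``.  Ties
    are broken by the smallest maximizing t so results are reproducible.  A
    histogram concentrated on a single gray level returns that level with
    ``degenerate=True`` (no meaningful split exists).

    With integer counts the between-class variance is the rational
    ``(MT W0 - N M0)^2 / (N^2 W0 (N - W0))`` (W0/M0 the class-0 count and
    gray sum, N/MT the totals), so the maximizer is found with exact integer
    arithmetic: tie-breaking is deterministic across platforms and immune to
    floating-point plateau noise.
    """
    h = np.asarray(histogram)
    if h.ndim != 1 or h.size < 2:
        raise SegmentationError("histogram must be 1-D with at least two bins")
    if np.any(h < 0):
        raise SegmentationError("histogram counts must be non-negative")
    if not np.allclose(h, np.round(np.asarray(h, dtype=float))):
        raise SegmentationError("histogram counts must be integers")
    h = np.round(np.asarray(h, dtype=float)).astype(object)
    total = int(sum(h))
    if total <= 0:
        raise SegmentationError("empty histogram")
    nonzero = np.flatnonzero(h)
    if nonzero.size == 1:
        return OtsuResult(threshold=int(nonzero[0]), degenerate=True)

    counts = [int(v) for v in h]
    N = total
    MT = sum(g * c for g, c in enumerate(counts))
    best_t, best_num, best_den = 0, 0, 1
    W0 = 0
    M0 = 0
    for t in range(len(counts) - 1):
        W0 += counts[t]
        M0 += t * counts[t]
        if W0 == 0 or W0 == N:
            continue
        num = (MT * W0 - N * M0) ** 2
        den = W0 * (N - W0)
        # exact fraction comparison: num/den > best_num/best_den
        if num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    return OtsuResult(threshold=best_t, degenerate=False)


def between_within_variances(
    histogram: Sequence[float] | np.ndarray, t: int
) -> tuple[float, float, float]:
    """(between, within, total) variance decomposition at threshold ``t``.

    Exposed for verification: for a normalized histogram the identity
    ``between + within = total`` holds at every candidate threshold.
    """
    p = np.asarray(histogram, dtype=float)
    p = p / p.sum()
    g = np.arange(p.size, dtype=float)
    mT = float(np.dot(p, g))
    total = float(np.dot(p, (g - mT) ** 2))
    w0 = float(p[: t + 1].sum())
    w1 = 1.0 - w0
    between = 0.0
    within = total
    if w0 > 0 and w1 > 0:
        m0 = float(np.dot(p[: t + 1], g[: t + 1])) / w0
        m1 = (mT - w0 * m0) / w1
        between = w0 * w1 * (m0 - m1) ** 2
        v0 = float(np.dot(p[: t + 1], (g[: t + 1] - m0) ** 2)) / w0
        v1 = float(np.dot(p[t + 1 :], (g[t + 1 :] - m1) ** 2)) / w1
        within = w0 * v0 + w1 * v1
    return between, within, total


# ---------------------------------------------------------------------------
# thresholded maps
# ---------------------------------------------------------------------------


def global_segment(img: GrayImage, T: int) -> np.ndarray:
    """Binary map: 1 where ``f(x, y) > T``, else 0."""
    if not 0 <= T <= img.gray_levels - 1:
        raise SegmentationError(f"threshold {T} outside [0, {img.gray_levels - 1}]")
    return (img.values > T).astype(np.uint8)


def multi_segment(img: GrayImage, thresholds: Sequence[int]) -> np.ndarray:
    """Label image with ``n + 1`` classes from ascending thresholds T1..Tn.

    Class k holds pixels with ``T_k < f <= T_{k+1}`` (``T_0 = -inf``,
    ``T_{n+1} = +inf``), so the classes partition the image and ``n = 1``
    reproduces :func:`global_segment`.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise SegmentationError("need at least one threshold")
    if np.any(np.diff(t) <= 0):
        raise SegmentationError("thresholds must be strictly ascending")
    return np.searchsorted(t, img.values, side="left").astype(np.int64)


def decompose(
    img: GrayImage, labels: LabelMap, T_otsu: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split the image into the detail sub-image I1 and remainder I2.

    Returns boolean membership masks ``(I1_mask, I2_mask)``; they are
    complementary by construction.  ``T_otsu`` is validated here because the
    caller records it as the fallback threshold for degenerate sub-images.
    """
    if labels.detail.shape != img.shape:
        raise SegmentationError("label map does not conform to the image")
    if not 0 <= T_otsu <= img.gray_levels - 1:
        raise SegmentationError("T_otsu outside the gray range")
    I1 = labels.detail.copy()
    return I1, ~I1


def threshold_subimage(
    img: GrayImage, member_mask: np.ndarray, fallback_T: int
) -> tuple[int, np.ndarray]:
    """Otsu-threshold one sub-image; binary output is zero off-membership.

    Degenerate member populations (empty, or a single distinct gray level)
    fall back to the whole-image threshold ``fallback_T`` so that every
    member pixel still receives a defined decision.
    """
    m = np.asarray(member_mask, dtype=bool)
    if m.shape != img.shape:
        raise SegmentationError("member mask does not conform to the image")
    B = np.zeros(img.shape, dtype=np.uint8)
    if not m.any():
        warnings.warn(
            "empty sub-image: falling back to the whole-image Otsu threshold",
            stacklevel=2,
        )
        return int(fallback_T), B
    values = img.values[m]
    hist = np.bincount(values, minlength=img.gray_levels)
    res = otsu_threshold(hist)
    T = int(fallback_T) if res.degenerate else res.threshold
    B[m] = (values > T).astype(np.uint8)
    return T, B


def merge_masks(
    B1: np.ndarray, B2: np.ndarray, I1_mask: np.ndarray, I2_mask: np.ndarray
) -> np.ndarray:
    """Merge per-sub-image binary maps: B = B1 on I1, B2 on I2.

    The membership masks must partition the image (no overlap between the
    segmented areas, no uncovered pixel).
    """
    I1 = np.asarray(I1_mask, dtype=bool)
    I2 = np.asarray(I2_mask, dtype=bool)
    if I1.shape != I2.shape or I1.shape != np.asarray(B1).shape:
        raise SegmentationError("mask shapes do not conform")
    if np.any(I1 & I2):
        raise SegmentationError("sub-image masks overlap")
    if not np.all(I1 | I2):
        raise SegmentationError("sub-image masks do not cover the image")
    return np.where(I1, B1, B2).astype(np.uint8)


# ---------------------------------------------------------------------------
# full pipelines
# ---------------------------------------------------------------------------


def global_otsu_segment(img: GrayImage, invert: bool = False) -> tuple[int, np.ndarray]:
    """Single-threshold baseline: whole-image Otsu + global_segment."""
    T = otsu_threshold(img.histogram()).threshold
    B = global_segment(img, T)
    if invert:
        B = (1 - B).astype(np.uint8)
    return T, B


def hvs_segment(img: GrayImage, invert: bool = False) -> SegmentationResult:
    """Edge-guided hybrid segmentation of one slice.

    Composes :func:`sobel_gradient` -> :func:`classify_pixels` ->
    whole-image :func:`otsu_threshold` -> :func:`decompose` ->
    :func:`threshold_subimage` on I1 and I2 -> :func:`merge_masks`.  All
    intermediates are retained in the returned :class:`SegmentationResult`.
    The run is fully deterministic.

    With ``invert=True`` the binary maps are complemented so the dark class
    becomes foreground (for acquisitions with inverted contrast polarity).
    """
    grad = sobel_gradient(img)
    labels = classify_pixels(grad)
    T_otsu = otsu_threshold(img.histogram()).threshold
    I1, I2 = decompose(img, labels, T_otsu)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty I1 legitimately degrades to Otsu
        T1, B1 = threshold_subimage(img, I1, T_otsu)
        T2, B2 = threshold_subimage(img, I2, T_otsu)
    if invert:
        B1 = (I1 & (B1 == 0)).astype(np.uint8)
        B2 = (I2 & (B2 == 0)).astype(np.uint8)
    B = merge_masks(B1, B2, I1, I2)
    return SegmentationResult(
        label_map=labels,
        T_otsu=T_otsu,
        T1=T1,
        T2=T2,
        I1_mask=I1,
        I2_mask=I2,
        B1=B1,
        B2=B2,
        B=B,
    )


def tiled_otsu_segment(
    img: GrayImage, tile_size: int = 32, invert: bool = False
) -> np.ndarray:
    """Fixed-tiling local-threshold baseline (uniform k x k tiles, per-tile Otsu).

    Provided only as the classical local-threshold comparison point; not part
    of :func:`hvs_segment`.  Degenerate tiles fall back to the whole-image
    threshold.
    """
    if tile_size < 2:
        raise SegmentationError("tile_size must be >= 2")
    T_global = otsu_threshold(img.histogram()).threshold
    B = np.zeros(img.shape, dtype=np.uint8)
    M, N = img.shape
    for r0 in range(0, M, tile_size):
        for c0 in range(0, N, tile_size):
            tile = img.values[r0 : r0 + tile_size, c0 : c0 + tile_size]
            res = otsu_threshold(np.bincount(tile.ravel(), minlength=img.gray_levels))
            T = T_global if res.degenerate else res.threshold
            B[r0 : r0 + tile_size, c0 : c0 + tile_size] = tile > T
    if invert:
        B = (1 - B).astype(np.uint8)
    return B


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)`` between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise SegmentationError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)
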