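"""Low-level image primitives shared by the segmentation pipeline.

Conventions
-----------
* Volumes are numpy arrays indexed ``[x, y, z]``; axis 2 is the axial stack
  index, increasing from distal (metacarpals) to proximal (radius/ulna).
* Binary masks are boolean arrays; label maps are small-integer arrays with
  0 for background.
* The default connectivity is "face" (4-neighbourhood in 2D, 6 in 3D),
  matching the unit-diamond structuring element used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "structuring_element",
    "morph",
    "fill_holes_2d",
    "connected_components",
    "keep_largest",
    "gradient_magnitude",
    "max_entropy_threshold",
    "smooth_histogram",
]


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: a square/cube or a diamond (city-block ball).

    ``half_size`` is the radius; the full linear extent is ``2*half_size+1``.
    """

    kind: Literal["square", "diamond"]
    half_size: int
    ndim: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("square", "diamond"):
            raise ValueError(f"unknown structuring element kind: {self.kind!r}")
        if self.half_size < 0:
            raise ValueError("half_size must be >= 0")
        if self.ndim not in (2, 3):
            raise ValueError("only 2D and 3D structuring elements are supported")

    @property
    def footprint(self) -> np.ndarray:
        n, r = self.ndim, self.half_size
        if r == 0:
            return np.ones((1,) * n, dtype=bool)
        if self.kind == "square":
            return np.ones((2 * r + 1,) * n, dtype=bool)
        unit = ndimage.generate_binary_structure(n, 1)
        return ndimage.iterate_structure(unit, r).astype(bool)


def structuring_element(kind: str, half_size: int, ndim: int = 2) -> StructuringElement:
    return StructuringElement(kind, half_size, ndim)  # type: ignore[arg-type]


def morph(mask: np.ndarray, op: str, se: StructuringElement) -> np.ndarray:
    """Binary morphology with a flat structuring element.

    ``op`` is one of ``erode``, ``dilate``, ``open``, ``close``.  Opening is
    erosion followed by dilation, closing the reverse; both are idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != se.ndim:
        raise ValueError(f"mask is {mask.ndim}D but structuring element is {se.ndim}D")
    fp = se.footprint
    if op == "erode":
        return ndimage.binary_erosion(mask, structure=fp, border_value=0)
    if op == "dilate":
        return ndimage.binary_dilation(mask, structure=fp, border_value=0)
    if op == "open":
        return ndimage.binary_opening(mask, structure=fp, border_value=0)
    if op == "close":
        # border_value=0 on the dilation step keeps closing from annexing the
        # image frame; scipy's binary_closing does exactly this.
        return ndimage.binary_closing(mask, structure=fp, border_value=0)
    raise ValueError(f"unknown morphological operation: {op!r}")


def fill_holes_2d(slice_mask: np.ndarray) -> np.ndarray:
    """Fill background regions of a 2D mask not connected to the image border."""
    slice_mask = np.asarray(slice_mask, dtype=bool)
    if slice_mask.ndim != 2:
        raise ValueError("fill_holes_2d expects a 2D mask")
    return ndimage.binary_fill_holes(slice_mask)


def _structure(ndim: int, connectivity: str) -> np.ndarray:
    if connectivity == "face":
        return ndimage.generate_binary_structure(ndim, 1)
    if connectivity == "full":
        return ndimage.generate_binary_structure(ndim, ndim)
    raise ValueError(f"unknown connectivity: {connectivity!r}")


def connected_components(
    mask: np.ndarray, connectivity: str = "face"
) -> tuple[np.ndarray, np.ndarray]:
    """Label connected components of a binary mask.

    Returns ``(labels, sizes)`` where labels run 1..K in deterministic order
    (raster order of each component's lexicographically smallest voxel) and
    ``sizes[k-1]`` is the voxel count of component ``k``.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_structure(mask.ndim, connectivity))
    if n == 0:
        return labels, np.zeros(0, dtype=np.int64)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes.astype(np.int64)


def keep_largest(mask: np.ndarray, k: int = 1, connectivity: str = "face") -> np.ndarray:
    """Keep the union of the k largest connected components.

    Ties in size are broken in favour of the component whose anchor voxel
    (lexicographically smallest) comes first, i.e. by ascending label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels, sizes = connected_components(mask, connectivity)
    if sizes.size <= k:
        return np.asarray(mask, dtype=bool).copy()
    # stable sort => equal sizes keep ascending label order
    order = np.argsort(-sizes, kind="stable")[:k]
    keep = np.zeros(sizes.size + 1, dtype=bool)
    keep[order + 1] = True
    return keep[labels]


def gradient_magnitude(volume: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """Gradient-magnitude relief of an intensity volume.

    The volume is blurred with a small Gaussian (3-tap kernel per axis, i.e.
    half-size one voxel), then per-axis Prewitt derivatives are combined as a
    Euclidean norm.  Borders are handled by edge replication so that no
    artificial ridge appears at the volume faces.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if any(s < 3 for s in volume.shape):
        raise ValueError("volume must be at least 3 voxels along every axis")
    blurred = ndimage.gaussian_filter(volume, sigma=sigma, radius=1, mode="nearest")
    sq = np.zeros_like(blurred)
    for axis in range(volume.ndim):
        d = ndimage.prewitt(blurred, axis=axis, mode="nearest")
        sq += d * d
    return np.sqrt(sq)


def smooth_histogram(histogram: np.ndarray, box: int) -> np.ndarray:
    """Centred running average of a histogram with edge replication."""
    histogram = np.asarray(histogram, dtype=np.float64)
    if box < 1 or box % 2 == 0:
        raise ValueError("box must be a positive odd integer")
    if box == 1:
        return histogram.copy()
    r = box // 2
    padded = np.pad(histogram, r, mode="edge")
    kernel = np.full(box, 1.0 / box)
    return np.convolve(padded, kernel, mode="valid")


def max_entropy_threshold(histogram: np.ndarray) -> int:
    """Maximum-entropy (Kapur) threshold of an intensity histogram.

    Returns the cut index ``t`` maximizing the sum of Shannon entropies of the
    sub-histograms ``[0..t]`` (background) and ``[t+1..]`` (foreground); on
    ties the lowest ``t`` wins.  Voxels are classified foreground when their
    intensity exceeds ``t``.
    """
    histogram = np.asarray(histogram, dtype=np.float64)
    if histogram.ndim != 1 or histogram.size < 2:
        raise ValueError("histogram must be 1D with at least two bins")
    if np.any(histogram < 0):
        raise ValueError("histogram counts must be non-negative")
    total = histogram.sum()
    if total <= 0 or np.count_nonzero(histogram) < 2:
        raise ValueError("histogram must have at least two occupied bins")

    p = histogram / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)

    best_t, best_val = -1, -np.inf
    for t in range(histogram.size - 1):
        p_b = cum_p[t]
        p_f = 1.0 - p_b
        if p_b <= 0.0 or p_f <= 0.0:
            continue
        h_b = np.log(p_b) - cum_plogp[t] / p_b
        h_f = np.log(p_f) - (cum_plogp[-1] - cum_plogp[t]) / p_f
        val = h_b + h_f
        if val > best_val:
            best_val, best_t = val, t
    if best_t < 0:
        raise ValueError("no valid threshold: histogram mass is degenerate")
    return int(best_t)
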