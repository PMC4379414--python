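"""Hand-mask extraction and the soft-tissue (background) marker.

The mask separates the imaged hand from the dark surround: a global
threshold is picked at the histogram valley right of the air mode, then each
axial slice is regularized with a closing (to re-include dark cortical bone
and tendons), 2D hole filling, and a final erosion that keeps the mask
surface inside the skin.  The one-voxel inner surface of the mask serves as
the watershed background marker: it lies in soft tissue whose intensity
overlaps the bone marrow range, exactly the regions that must not be
captured by any bone basin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import StructuringElement, fill_holes_2d, morph, smooth_histogram

__all__ = ["MaskParams", "select_mask_threshold", "build_hand_mask", "background_marker"]


@dataclass(frozen=True)
class MaskParams:
    """Hand-mask parameters.

    The histogram valley is searched in ``[i_low, i_high]`` gray levels on a
    running-average-smoothed histogram (``smooth_box`` bins wide).  ``box``
    is the closing half-size in pixels; the final erosion uses half of it.
    """

    i_low: int = 200
    i_high: int = 500
    smooth_box: int = 11
    box: int = 5

    def __post_init__(self) -> None:
        if self.i_low >= self.i_high:
            raise ValueError("i_low must be below i_high")
        if self.box < 1:
            raise ValueError("box must be >= 1")

    @property
    def erosion_half_size(self) -> int:
        return self.box // 2


def select_mask_threshold(volume: np.ndarray, params: MaskParams = MaskParams()) -> int:
    """Threshold at the minimum of the smoothed histogram within
    ``[i_low, i_high]``; the lowest intensity wins on ties."""
    vol = np.asarray(volume)
    hist = np.bincount(vol.ravel().astype(np.int64),
                       minlength=params.i_high + 1).astype(np.float64)
    smoothed = smooth_histogram(hist, params.smooth_box)
    lo, hi = params.i_low, params.i_high
    if hi >= smoothed.size:
        raise ValueError("volume intensities never reach the search range")
    window = smoothed[lo : hi + 1]
    return lo + int(np.argmin(window))  # argmin returns the first minimum


def build_hand_mask(volume: np.ndarray, th: int,
                    params: MaskParams = MaskParams()) -> np.ndarray:
    """Hand mask from slicewise 2D morphology of the thresholded volume.

    Per axial slice: threshold (> th), closing with a square of half-size
    ``box``, 2D hole filling, erosion with a square of half-size ``box//2``.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("build_hand_mask expects a 3D volume")
    close_se = StructuringElement("square", params.box, ndim=2)
    erode_se = StructuringElement("square", params.erosion_half_size, ndim=2)
    out = np.zeros(vol.shape, dtype=bool)
    binary = vol > th
    for z in range(vol.shape[2]):
        s = morph(binary[:, :, z], "close", close_se)
        s = fill_holes_2d(s)
        out[:, :, z] = morph(s, "erode", erode_se)
    return out


def background_marker(mask: np.ndarray) -> np.ndarray:
    """One-voxel inner surface of the hand mask, in-plane per axial slice.

    The surface is the mask minus its unit-diamond erosion computed slice by
    slice, so the marker is guaranteed to stay inside the mask.  Slices that
    are only one pixel thick survive unchanged (their erosion is empty).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("background_marker of an empty mask")
    if mask.ndim == 2:
        eroded = ndimage.binary_erosion(
            mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0)
        return mask & ~eroded
    out = np.zeros(mask.shape, dtype=bool)
    unit = ndimage.generate_binary_structure(2, 1)
    for z in range(mask.shape[2]):
        s = mask[:, :, z]
        out[:, :, z] = s & ~ndimage.binary_erosion(s, structure=unit, border_value=0)
    return out
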