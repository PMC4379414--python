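"""Automatic selection of the registration cross sections.

Two bespoke slice classifiers drive the 2D registration stages.  The
radioulnar classifier works on the mean-intensity axial profile of the
masked volume: scanning local maxima from the proximal end, it accepts the
first one preceded (distally) by a sufficiently deep and sufficiently close
minimum -- the signature of the bright radius/ulna marrow next to the dark
wrist-joint gap.  The metacarpal classifier thresholds the volume above the
maximum-entropy level plus a safety buffer, filters the resulting clusters
by axial extent and by their distal position, and picks the axial slice with
the highest mean of the filtered binary image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import connected_components, max_entropy_threshold, smooth_histogram

__all__ = [
    "AxialProfile",
    "axial_profile",
    "select_radioulnar_slice",
    "ClusterFeatures",
    "cluster_features",
    "select_metacarpal_slice",
    "SliceSelectionError",
]


class SliceSelectionError(RuntimeError):
    """Raised when a slice classifier finds no qualifying cross section."""


@dataclass(frozen=True)
class AxialProfile:
    """Mean intensity per axial slice, restricted to hand-mask voxels.

    ``valid[z]`` is False for slices where the mask is empty (the profile
    value is 0 there).
    """

    values: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def axial_profile(volume: np.ndarray, mask: np.ndarray) -> AxialProfile:
    vol = np.asarray(volume, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if vol.shape != m.shape:
        raise ValueError("volume and mask shapes differ")
    counts = m.sum(axis=(0, 1))
    if not counts.any():
        raise ValueError("axial_profile: mask is empty everywhere")
    sums = np.where(m, vol, 0.0).sum(axis=(0, 1))
    valid = counts > 0
    values = np.zeros(vol.shape[2], dtype=np.float64)
    values[valid] = sums[valid] / counts[valid]
    return AxialProfile(values=values, valid=valid)


def _local_extrema(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima (non-strict on one side)."""
    maxima, minima = [], []
    for i in range(1, len(p) - 1):
        if p[i] >= p[i - 1] and p[i] >= p[i + 1] and (p[i] > p[i - 1] or p[i] > p[i + 1]):
            maxima.append(i)
        if p[i] <= p[i - 1] and p[i] <= p[i + 1] and (p[i] < p[i - 1] or p[i] < p[i + 1]):
            minima.append(i)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def select_radioulnar_slice(
    profile: AxialProfile | np.ndarray,
    min_rel_depth: float = 0.10,
    max_dist_frac: float = 0.15,
    smooth_box: int = 3,
) -> int:
    """Representative radius/ulna cross section from the axial profile.

    Local extrema are detected on the box-smoothed profile.  Scanning maxima
    from the highest slice index downward, a maximum M is accepted if some
    local minimum m at distance ``0 < z_M - z_m < max_dist_frac * L`` has
    relative depth ``(p_M - p_m) / (0.5 * (p_M + p_m)) > min_rel_depth``.
    """
    values = profile.values if isinstance(profile, AxialProfile) else np.asarray(profile, float)
    L = len(values)
    if L < 5:
        raise ValueError("profile too short for slice selection")
    p = smooth_histogram(values, smooth_box)
    maxima, minima = _local_extrema(p)
    max_dist = max_dist_frac * L
    for zm in maxima[::-1]:
        near = minima[(minima < zm) & (zm - minima < max_dist)]
        for zmin in near:
            depth = (p[zm] - p[zmin]) / (0.5 * (p[zm] + p[zmin]))
            if depth > min_rel_depth:
                return int(zm)
    raise SliceSelectionError(
        "radioulnar slice classifier failed: no profile maximum with a "
        "sufficiently deep nearby minimum")


@dataclass(frozen=True)
class ClusterFeatures:
    """Axial bounding features of one thresholded cluster.

    Coordinates use the distal-positive axial frame: ``x = L - 1 - z`` in
    slice units, origin at the most distal slice of the field of view.
    """

    label: int
    d: int        # axial extent in slices
    x_min: int
    x_max: int
    size: int


def cluster_features(components: np.ndarray, n_slices: int | None = None) -> list[ClusterFeatures]:
    comp = np.asarray(components)
    if n_slices is None:
        n_slices = comp.shape[2]
    out = []
    for label in range(1, int(comp.max()) + 1):
        where = np.nonzero(comp == label)
        if len(where[0]) == 0:
            continue
        z_min, z_max = int(where[2].min()), int(where[2].max())
        out.append(ClusterFeatures(
            label=label,
            d=z_max - z_min + 1,
            x_min=n_slices - 1 - z_max,
            x_max=n_slices - 1 - z_min,
            size=len(where[0]),
        ))
    return out


def select_metacarpal_slice(
    volume: np.ndarray,
    th_me: int | None = None,
    buffer: int = 200,
    n_keep: int = 10,
    x_th_frac: float = 0.35,
) -> int:
    """Representative cross section through the metacarpal bases.

    The volume is thresholded at ``th_me + buffer`` (``th_me`` defaults to
    the maximum-entropy threshold of the volume histogram); connected
    clusters whose distal-frame ``x_min`` exceeds ``x_th_frac * L`` are
    ranked by axial extent and at most ``n_keep`` survive.  The returned
    slice maximizes the slice mean of the filtered binary image (lowest
    index on ties).
    """
    vol = np.asarray(volume)
    if th_me is None:
        th_me = max_entropy_threshold(np.bincount(vol.ravel().astype(np.int64)))
    binary = vol > th_me + buffer
    if not binary.any():
        raise SliceSelectionError("metacarpal slice selection: nothing above "
                                  "the cluster threshold")
    comp, _ = connected_components(binary)
    L = vol.shape[2]
    feats = cluster_features(comp, n_slices=L)
    passing = [f for f in feats if f.x_min > x_th_frac * L]
    if not passing:
        raise SliceSelectionError("metacarpal slice selection: no cluster "
                                  "passes the distal-position filter")
    passing.sort(key=lambda f: (-f.d, f.label))
    kept = passing[:n_keep]
    filtered = np.isin(comp, [f.label for f in kept])
    score = filtered.mean(axis=(0, 1))
    return int(np.argmax(score))
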