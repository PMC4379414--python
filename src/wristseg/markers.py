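"""Construction of the final 3D watershed markers.

Registered atlas markers are only candidates: they are grown into short 3D
paths along the bone marrow (radius/ulna, metacarpals), or filtered,
regularized and capped at eight components (carpals), before being assembled
together with the background marker into a validated, pairwise-disjoint
marker set.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, QhullError

from .imaging import StructuringElement, connected_components, fill_holes_2d, keep_largest, morph

__all__ = [
    "MarkerSet",
    "grow_marker",
    "central_pixel",
    "carpal_region",
    "finalize_carpal_markers",
    "assemble_markers",
    "match_components",
]


@dataclass
class MarkerSet:
    """Named binary object markers plus one background marker.

    Object markers must be pairwise disjoint and disjoint from the
    background marker; :func:`assemble_markers` enforces this.
    """

    markers: dict[str, np.ndarray]
    background: np.ndarray
    stage: str = ""
    _order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._order = list(self.markers.keys())

    @property
    def names(self) -> list[str]:
        return list(self._order)

    def to_labelmap(self) -> np.ndarray:
        """Label volume: objects 1..K in insertion order, background K+1."""
        out = np.zeros(self.background.shape, dtype=np.int32)
        for i, name in enumerate(self._order, start=1):
            out[self.markers[name]] = i
        out[self.background] = len(self._order) + 1
        return out

    def label_names(self) -> dict[int, str]:
        table = {i: name for i, name in enumerate(self._order, start=1)}
        table[len(self._order) + 1] = "background"
        return table


def assemble_markers(
    object_markers: dict[str, np.ndarray],
    background: np.ndarray,
    stage: str = "",
) -> MarkerSet:
    """Validate and assemble markers into a disjoint :class:`MarkerSet`.

    Overlap between two object markers is an error (ambiguous seeds); overlap
    between the background marker and an object marker is resolved by
    trimming the background, with a warning.
    """
    background = np.asarray(background, dtype=bool).copy()
    clean: dict[str, np.ndarray] = {}
    claimed = np.zeros(background.shape, dtype=bool)
    for name, m in object_markers.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != background.shape:
            raise ValueError(f"marker {name!r} shape differs from background")
        if not m.any():
            raise ValueError(f"marker for {name!r} is empty")
        if (m & claimed).any():
            raise ValueError(f"marker {name!r} overlaps another object marker")
        claimed |= m
        clean[name] = m
    overlap = background & claimed
    if overlap.any():
        warnings.warn(f"background marker overlapped object markers on "
                      f"{int(overlap.sum())} voxels; background trimmed")
        background &= ~claimed
    return MarkerSet(markers=clean, background=background, stage=stage)


def grow_marker(
    volume: np.ndarray,
    seed: tuple[int, int, int],
    depth_slices: int = 10,
    direction: str = "proximal",
) -> np.ndarray:
    """Extend a seed voxel to a 3D path marker by best-first region growing.

    Starting from the seed, voxels are merged in order of decreasing image
    intensity over face neighbours (FIFO among equal intensities), restricted
    to the seed's side of the axial axis: ``proximal`` admits slices
    ``z >= z_seed``, ``distal`` admits ``z <= z_seed``.  Growth stops at the
    first merged voxel V whose axial distance from the seed equals
    ``depth_slices``; the returned marker is the predecessor path from V back
    to the seed.  If the volume edge cuts growth short the truncated path is
    returned with a warning.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("grow_marker expects a 3D volume")
    if direction not in ("proximal", "distal"):
        raise ValueError(f"unknown growth direction: {direction!r}")
    sx, sy, sz = (int(c) for c in seed)
    if not (0 <= sx < vol.shape[0] and 0 <= sy < vol.shape[1] and 0 <= sz < vol.shape[2]):
        raise ValueError("seed outside the volume")
    step = 1 if direction == "proximal" else -1

    pred: dict[tuple[int, int, int], tuple[int, int, int] | None] = {(sx, sy, sz): None}
    heap: list[tuple[float, int, tuple[int, int, int]]] = []
    age = 0
    heapq.heappush(heap, (-vol[sx, sy, sz], age, (sx, sy, sz)))
    age += 1
    deepest = (sx, sy, sz)
    stop = None
    while heap:
        _, _, v = heapq.heappop(heap)
        if abs(v[2] - sz) > abs(deepest[2] - sz):
            deepest = v
        if abs(v[2] - sz) >= depth_slices:
            stop = v
            break
        x, y, z = v
        for nb in ((x - 1, y, z), (x + 1, y, z), (x, y - 1, z),
                   (x, y + 1, z), (x, y, z - 1), (x, y, z + 1)):
            if nb in pred:
                continue
            if not (0 <= nb[0] < vol.shape[0] and 0 <= nb[1] < vol.shape[1]
                    and 0 <= nb[2] < vol.shape[2]):
                continue
            if (nb[2] - sz) * step < 0:
                continue
            pred[nb] = v
            heapq.heappush(heap, (-vol[nb], age, nb))
            age += 1
    if stop is None:
        warnings.warn("grow_marker reached the volume edge before the requested "
                      "depth; marker truncated")
        stop = deepest
    marker = np.zeros(vol.shape, dtype=bool)
    cur: tuple[int, int, int] | None = stop
    while cur is not None:
        marker[cur] = True
        cur = pred[cur]
    return marker


def central_pixel(marker_2d: np.ndarray) -> tuple[int, int]:
    """Foreground pixel of a 2D marker at the largest city-block distance
    from the background (image border counts as background); lexicographic
    tie-break."""
    m = np.asarray(marker_2d, dtype=bool)
    if m.ndim != 2:
        raise ValueError("central_pixel expects a 2D marker")
    if not m.any():
        raise ValueError("central_pixel of an empty marker")
    padded = np.pad(m, 1, constant_values=False)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1]
    flat = int(np.argmax(dist))  # argmax returns the first (C-order) maximum
    return np.unravel_index(flat, m.shape)  # type: ignore[return-value]


def _column_envelope(bone: np.ndarray, mode: str, smooth: int = 5) -> np.ndarray:
    """Per-(x, y)-column extreme z of a bone mask, nearest-neighbour
    extrapolated across columns containing no bone.

    The raw per-column extremum is regularized with an in-plane grey
    dilation (``max`` mode) or erosion (``min`` mode) of width ``smooth``,
    so columns that merely graze a bone surface do not punch the envelope
    far beyond the body of the bone.
    """
    nz = bone.shape[2]
    zs = np.arange(nz)[np.newaxis, np.newaxis, :]
    present = bone.any(axis=2)
    if not present.any():
        raise ValueError("empty envelope: no bone voxels")
    if mode == "min":
        env = np.where(bone, zs, nz).min(axis=2)
    elif mode == "max":
        env = np.where(bone, zs, -1).max(axis=2)
    else:
        raise ValueError(mode)
    # nearest-neighbour fill for columns without bone
    _, (ix, iy) = ndimage.distance_transform_edt(~present, return_indices=True)
    env = env[ix, iy]
    if smooth > 1:
        fp = np.ones((smooth, smooth), dtype=bool)
        if mode == "max":
            env = ndimage.grey_dilation(env, footprint=fp)
        else:
            env = ndimage.grey_erosion(env, footprint=fp)
    return env


def _support_line(body_a: np.ndarray, body_b: np.ndarray,
                  reference_xz: tuple[float, float]) -> tuple[float, float, float] | None:
    """Lateral support line a*x + b*z + c >= 0 in the coronal (x, z)
    projection.

    The line is a convex-hull bridge edge between the projections of the two
    bodies, touching each tangentially, chosen so that both bodies *and* the
    reference point (the carpal side) lie in the kept half-plane: it trims
    the soft tissue lateral of the ulna/M5 (or radius/M1) line.  Returns
    None when no such bridge edge exists.
    """
    pts_a = np.array(sorted(set(zip(*[c.tolist() for c in np.nonzero(body_a.any(axis=1))]))), dtype=float)
    pts_b = np.array(sorted(set(zip(*[c.tolist() for c in np.nonzero(body_b.any(axis=1))]))), dtype=float)
    if len(pts_a) == 0 or len(pts_b) == 0:
        return None
    pts = np.vstack([pts_a, pts_b])
    from_a = np.zeros(len(pts), dtype=bool)
    from_a[: len(pts_a)] = True
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    rx, rz = reference_xz
    for simplex in sorted(map(tuple, np.sort(hull.simplices, axis=1))):
        i, j = simplex
        if from_a[i] == from_a[j]:
            continue  # not a bridge edge between the two bodies
        (x1, z1), (x2, z2) = pts[i], pts[j]
        a, b = z2 - z1, x1 - x2
        c = -(a * x1 + b * z1)
        s_ref = a * rx + b * rz + c
        if s_ref == 0:
            continue
        s_bodies = a * pts[:, 0] + b * pts[:, 1] + c
        # support edge with the bodies and the carpal reference on one side
        if np.all(s_bodies * np.sign(s_ref) >= -1e-9):
            return (a, b, c) if s_ref > 0 else (-a, -b, -c)
    return None


def carpal_region(
    ulna_radius: np.ndarray,
    metacarpals: np.ndarray,
    hand_mask: np.ndarray,
    radius_label: int = 1,
    ulna_label: int = 2,
    m1_label: int = 3,
    m5_label: int = 7,
) -> np.ndarray:
    """Binary region enclosing the carpals.

    For every (x, y) column the region spans the open z interval between the
    proximal envelope of the metacarpal bases and the distal envelope of the
    ulna/radius (envelopes are nearest-neighbour extrapolated across columns
    without bone).  Laterally the region is clipped by two support planes in
    the coronal projection -- one tangential to the ulna and the fifth
    metacarpal, the other to the radius and the first metacarpal -- extruded
    along the anteroposterior axis, and finally by the hand mask.
    """
    ru = np.asarray(ulna_radius)
    mc = np.asarray(metacarpals)
    mask = np.asarray(hand_mask, dtype=bool)
    if not (ru > 0).any() or not (mc > 0).any():
        raise ValueError("carpal_region needs nonempty ulna/radius and "
                         "metacarpal segmentations")
    ru_env = _column_envelope(ru > 0, "min")   # distal (lowest z) extent of ulna/radius
    mc_env = _column_envelope(mc > 0, "max")   # proximal (highest z) extent of metacarpals
    zs = np.arange(ru.shape[2])[np.newaxis, np.newaxis, :]
    region = (zs > mc_env[:, :, np.newaxis]) & (zs < ru_env[:, :, np.newaxis])
    region &= mask & (ru == 0) & (mc == 0)

    if region.any():
        cx, _, cz = (np.mean(c) for c in np.nonzero(region))
        for pair in ((ru == ulna_label, mc == m5_label),
                     (ru == radius_label, mc == m1_label)):
            line = _support_line(pair[0], pair[1], (cx, cz))
            if line is None:
                warnings.warn("carpal_region: no valid lateral support plane "
                              "found for one bone pair; plane skipped")
                continue
            a, b, c = line
            xs = np.arange(ru.shape[0])[:, np.newaxis, np.newaxis]
            side = a * xs + b * zs + c
            region &= side >= 0
    return region


def finalize_carpal_markers(
    candidates: np.ndarray,
    volume: np.ndarray,
    th_me: int,
    buffer: int = 200,
    n_components: int = 8,
    closing_half_size: int = 1,
) -> list[np.ndarray]:
    """Convert candidate carpal markers into the final eight markers.

    Candidate voxels darker than ``th_me + buffer`` in the original volume
    are dropped; every axial slice is then regularized with a small square
    closing and 2D hole filling; finally only the ``n_components`` largest
    connected components are kept and returned as separate masks (largest
    first).  Fewer surviving components than requested is an error, since the
    watershed needs one marker per carpal.
    """
    cand = np.asarray(candidates, dtype=bool)
    vol = np.asarray(volume)
    if cand.shape != vol.shape:
        raise ValueError("candidates and volume shapes differ")
    bright = cand & (vol > th_me + buffer)
    se = StructuringElement("square", closing_half_size, ndim=2)
    cleaned = np.zeros_like(bright)
    for z in range(bright.shape[2]):
        s = morph(bright[:, :, z], "close", se)
        cleaned[:, :, z] = fill_holes_2d(s)
    labels, sizes = connected_components(cleaned)
    if sizes.size < n_components:
        raise ValueError(
            f"only {sizes.size} carpal marker components survive filtering; "
            f"{n_components} are required")
    order = np.argsort(-sizes, kind="stable")[:n_components]
    return [labels == (i + 1) for i in order]


def match_components(
    components: list[np.ndarray],
    references: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Assign anatomical names to marker components.

    Each component is matched to the reference gray-valued (or binary)
    marker image with which it shares the most mass, using an optimal
    one-to-one assignment.  Components and references must be equinumerous.
    """
    names = list(references.keys())
    if len(components) != len(names):
        raise ValueError(f"{len(components)} components cannot be matched to "
                         f"{len(names)} references")
    score = np.zeros((len(components), len(names)))
    for i, comp in enumerate(components):
        for j, name in enumerate(names):
            score[i, j] = float(np.asarray(references[name], dtype=np.float64)[comp].sum())
    row, col = linear_sum_assignment(-score)
    return {names[j]: components[i] for i, j in zip(row, col)}
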