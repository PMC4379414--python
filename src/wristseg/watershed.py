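"""Watershed-from-markers on a gradient-magnitude relief.

The relief is flooded from the marker voxels with a priority queue ordered by
``(relief value, insertion order)``: at every step the lowest not-yet
processed frontier voxel is expanded and its unlabelled face neighbours
inherit its label.  Insertion order as the tie-break makes the flooding
breadth-first within flat zones and fully deterministic.  By default every
voxel ends up in exactly one catchment basin (first-arrival assignment); an
optional mode leaves one-voxel watershed lines as label 0 instead.

Because the watershed only compares relief values, the result is invariant
under any strictly increasing transform of the relief.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .imaging import gradient_magnitude
from .markers import MarkerSet

__all__ = ["watershed_from_markers", "cortical_dilation", "segment_stage"]

_LINE = -1


@njit(cache=True)
def _flood(relief, labels, shape, emit_lines):
    """Priority-flood kernel.  ``labels`` is modified in place.

    Heap entries are (value, age, flat index); ordering is lexicographic on
    (value, age).  Neighbours are labelled when first pushed; with
    ``emit_lines`` a voxel pushed again from a different basin before being
    popped is demoted to a watershed line and stops propagating.
    """
    nx, ny, nz = shape
    n = nx * ny * nz
    heap_val = np.empty(n, dtype=np.float64)
    heap_age = np.empty(n, dtype=np.int64)
    heap_idx = np.empty(n, dtype=np.int64)
    popped = np.zeros(n, dtype=np.uint8)
    size = 0
    age = 0

    # seed markers in raveled order
    for i in range(n):
        if labels[i] > 0:
            heap_val[size] = relief[i]
            heap_age[size] = age
            heap_idx[size] = i
            size += 1
            age += 1
            # sift up
            c = size - 1
            while c > 0:
                p = (c - 1) >> 1
                if (heap_val[c] < heap_val[p]) or (
                    heap_val[c] == heap_val[p] and heap_age[c] < heap_age[p]
                ):
                    heap_val[c], heap_val[p] = heap_val[p], heap_val[c]
                    heap_age[c], heap_age[p] = heap_age[p], heap_age[c]
                    heap_idx[c], heap_idx[p] = heap_idx[p], heap_idx[c]
                    c = p
                else:
                    break

    while size > 0:
        idx = heap_idx[0]
        # pop root
        size -= 1
        heap_val[0] = heap_val[size]
        heap_age[0] = heap_age[size]
        heap_idx[0] = heap_idx[size]
        p = 0
        while True:
            l = 2 * p + 1
            r = l + 1
            m = p
            if l < size and ((heap_val[l] < heap_val[m]) or (
                    heap_val[l] == heap_val[m] and heap_age[l] < heap_age[m])):
                m = l
            if r < size and ((heap_val[r] < heap_val[m]) or (
                    heap_val[r] == heap_val[m] and heap_age[r] < heap_age[m])):
                m = r
            if m == p:
                break
            heap_val[p], heap_val[m] = heap_val[m], heap_val[p]
            heap_age[p], heap_age[m] = heap_age[m], heap_age[p]
            heap_idx[p], heap_idx[m] = heap_idx[m], heap_idx[p]
            p = m

        if popped[idx]:
            continue
        popped[idx] = 1
        lab = labels[idx]
        if lab <= 0:  # demoted to a line while waiting in the heap
            continue

        x = idx // (ny * nz)
        rem = idx % (ny * nz)
        y = rem // nz
        z = rem % nz
        for d in range(6):
            if d == 0:
                if x == 0:
                    continue
                nb = idx - ny * nz
            elif d == 1:
                if x == nx - 1:
                    continue
                nb = idx + ny * nz
            elif d == 2:
                if y == 0:
                    continue
                nb = idx - nz
            elif d == 3:
                if y == ny - 1:
                    continue
                nb = idx + nz
            elif d == 4:
                if z == 0:
                    continue
                nb = idx - 1
            else:
                if z == nz - 1:
                    continue
                nb = idx + 1
            if labels[nb] == 0:
                labels[nb] = lab
                heap_val[size] = relief[nb]
                heap_age[size] = age
                heap_idx[size] = nb
                size += 1
                age += 1
                c = size - 1
                while c > 0:
                    pp = (c - 1) >> 1
                    if (heap_val[c] < heap_val[pp]) or (
                        heap_val[c] == heap_val[pp] and heap_age[c] < heap_age[pp]
                    ):
                        heap_val[c], heap_val[pp] = heap_val[pp], heap_val[c]
                        heap_age[c], heap_age[pp] = heap_age[pp], heap_age[c]
                        heap_idx[c], heap_idx[pp] = heap_idx[pp], heap_idx[c]
                        c = pp
                    else:
                        break
            elif emit_lines and labels[nb] != lab and labels[nb] > 0 and not popped[nb]:
                labels[nb] = _LINE


def watershed_from_markers(
    relief: np.ndarray,
    markers: np.ndarray | MarkerSet,
    emit_lines: bool = False,
) -> np.ndarray:
    """Flood a relief from labelled markers; returns an int32 label map.

    ``markers`` is either an integer seed map (0 = unset) or a
    :class:`~wristseg.markers.MarkerSet` (object markers get labels 1..K in
    insertion order, the background marker gets K+1).
    """
    relief = np.asarray(relief, dtype=np.float64)
    if isinstance(markers, MarkerSet):
        markers = markers.to_labelmap()
    seeds = np.asarray(markers)
    if seeds.shape != relief.shape:
        raise ValueError("relief and marker shapes differ")
    if not (seeds > 0).any():
        raise ValueError("marker set is empty")
    if relief.ndim == 2:
        relief = relief[:, :, np.newaxis]
        seeds = seeds[:, :, np.newaxis]
        squeeze = True
    elif relief.ndim == 3:
        squeeze = False
    else:
        raise ValueError("watershed supports 2D and 3D inputs")
    labels = np.ascontiguousarray(seeds, dtype=np.int32).ravel().copy()
    _flood(np.ascontiguousarray(relief).ravel(), labels, relief.shape, emit_lines)
    out = labels.reshape(relief.shape)
    out[out == _LINE] = 0
    return out[:, :, 0] if squeeze else out


def cortical_dilation(
    labelmap: np.ndarray,
    relief: np.ndarray,
    half_size: int = 1,
    protected: np.ndarray | None = None,
) -> np.ndarray:
    """Expand each labelled bone by a unit-diamond dilation (repeated
    ``half_size`` times) to re-include the dark cortical shell.

    A background voxel claimed by several adjacent bones is resolved
    deterministically: it takes the label of its face neighbour with the
    lowest relief value (lowest label on ties).  Voxels in ``protected``
    (e.g. the background marker) are never claimed.
    """
    out = np.asarray(labelmap).astype(np.int32, copy=True)
    relief = np.asarray(relief, dtype=np.float64)
    if relief.shape != out.shape:
        raise ValueError("labelmap and relief shapes differ")
    prot = np.zeros(out.shape, dtype=bool) if protected is None else np.asarray(protected, dtype=bool)
    for _ in range(half_size):
        nbr_val = np.full(out.shape, np.inf)
        nbr_lab = np.zeros(out.shape, dtype=np.int32)
        for axis in range(out.ndim):
            for shift in (-1, 1):
                lab_sh = np.roll(out, shift, axis=axis)
                val_sh = np.roll(relief, shift, axis=axis)
                # zero out the wrapped border
                edge = [slice(None)] * out.ndim
                edge[axis] = 0 if shift == 1 else -1
                lab_sh[tuple(edge)] = 0
                better = (lab_sh > 0) & (
                    (val_sh < nbr_val)
                    | ((val_sh == nbr_val) & ((nbr_lab == 0) | (lab_sh < nbr_lab)))
                )
                nbr_val[better] = val_sh[better]
                nbr_lab[better] = lab_sh[better]
        claim = (out == 0) & (nbr_lab > 0) & ~prot
        out[claim] = nbr_lab[claim]
    return out


def segment_stage(
    volume: np.ndarray,
    markers: MarkerSet,
    region: np.ndarray | None = None,
    dilation_half_size: int = 1,
    relief: np.ndarray | None = None,
) -> np.ndarray:
    """One watershed stage: relief, flooding, background removal, dilation.

    Returns a label map with the marker objects numbered 1..K in the marker
    set's insertion order; the background basin is dropped.  If ``region`` is
    given, everything outside it is pre-assigned to the background marker
    before flooding.
    """
    if relief is None:
        relief = gradient_magnitude(volume)
    seeds = markers.to_labelmap()
    n_obj = len(markers.markers)
    bg_label = n_obj + 1
    if region is not None:
        region = np.asarray(region, dtype=bool)
        outside = ~region & (seeds == 0)
        seeds = seeds.copy()
        seeds[outside] = bg_label
    labels = watershed_from_markers(relief, seeds)
    labels[labels == bg_label] = 0
    if dilation_half_size > 0:
        labels = cortical_dilation(labels, relief, half_size=dilation_half_size,
                                   protected=markers.background)
    return labels
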