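"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately naive, definition-level implementations
used to cross-check the package: shift-based Minkowski morphology, a linear
scan flooding for the watershed, direct-sum entropy for the threshold, and a
heap-free best-first search for marker growth.
"""

from __future__ import annotations

import numpy as np
import pytest

from wristseg.phantom import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# oracle: Minkowski morphology by explicit shifting

def diamond_offsets(n: int, ndim: int) -> list[tuple[int, ...]]:
    """All integer offsets with city-block norm <= n."""
    out = []
    rng = range(-n, n + 1)
    if ndim == 2:
        for dx in rng:
            for dy in rng:
                if abs(dx) + abs(dy) <= n:
                    out.append((dx, dy))
    else:
        for dx in rng:
            for dy in rng:
                for dz in rng:
                    if abs(dx) + abs(dy) + abs(dz) <= n:
                        out.append((dx, dy, dz))
    return out


def shift_mask(mask: np.ndarray, offset: tuple[int, ...]) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for size, o in zip(mask.shape, offset):
        src.append(slice(max(0, -o), min(size, size - o)))
        dst.append(slice(max(0, o), min(size, size + o)))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def erode_oracle(mask: np.ndarray, n: int) -> np.ndarray:
    out = np.ones_like(mask)
    for off in diamond_offsets(n, mask.ndim):
        out &= shift_mask(mask, tuple(-o for o in off))
    return out


def dilate_oracle(mask: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros_like(mask)
    for off in diamond_offsets(n, mask.ndim):
        out |= shift_mask(mask, off)
    return out


def opening_oracle(mask: np.ndarray, n: int) -> np.ndarray:
    return dilate_oracle(erode_oracle(mask, n), n)


def pattern_spectrum_oracle(mask: np.ndarray) -> dict[int, int]:
    """Pattern spectrum by direct application of its definition."""
    spectrum = {}
    prev = opening_oracle(mask, 0)
    n = 0
    while prev.any():
        n += 1
        cur = opening_oracle(mask, n)
        diff = int(prev.sum()) - int(cur.sum())
        if diff:
            spectrum[n] = diff
        prev = cur
    return spectrum


def mad_oracle(a: np.ndarray, b: np.ndarray) -> float:
    spec = pattern_spectrum_oracle(a ^ b)
    total = sum(spec.values())
    if total == 0:
        return 0.0
    return sum(k * v for k, v in spec.items()) / total


# ---------------------------------------------------------------------------
# oracle: naive ordered flooding (watershed)

def watershed_oracle(relief: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Flood by repeatedly expanding the (value, age)-smallest frontier
    voxel; labels assigned on first arrival.  No heap, linear scans only."""
    relief = np.asarray(relief, dtype=np.float64)
    out = np.array(markers, dtype=np.int64)
    nd = relief.ndim
    offsets = []
    for ax in range(nd):
        for d in (-1, 1):
            off = [0] * nd
            off[ax] = d
            offsets.append(tuple(off))
    frontier: list[tuple[float, int, tuple[int, ...]]] = []
    age = 0
    for idx in sorted(zip(*np.nonzero(out))):
        frontier.append((relief[idx], age, idx))
        age += 1
    while frontier:
        best = min(range(len(frontier)),
                   key=lambda i: (frontier[i][0], frontier[i][1]))
        _, _, idx = frontier.pop(best)
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(c < 0 or c >= s for c, s in zip(nb, relief.shape)):
                continue
            if out[nb] == 0:
                out[nb] = out[idx]
                frontier.append((relief[nb], age, nb))
                age += 1
    return out


# ---------------------------------------------------------------------------
# oracle: maximum-entropy threshold by direct summation

def kapur_oracle(hist: np.ndarray) -> int:
    import math
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_t, best = -1, -np.inf
    for t in range(len(hist) - 1):
        pb = hist[: t + 1].sum() / total
        pf = hist[t + 1 :].sum() / total
        if pb <= 0 or pf <= 0:
            continue
        hb = -sum(p / total / pb * math.log(p / total / pb)
                  for p in hist[: t + 1] if p > 0)
        hf = -sum(p / total / pf * math.log(p / total / pf)
                  for p in hist[t + 1 :] if p > 0)
        if hb + hf > best:
            best, best_t = hb + hf, t
    return best_t


# ---------------------------------------------------------------------------
# oracle: naive best-first marker growth

def grow_oracle(volume: np.ndarray, seed: tuple[int, int, int],
                depth: int, direction: str) -> np.ndarray:
    vol = np.asarray(volume, dtype=np.float64)
    step = 1 if direction == "proximal" else -1
    sx, sy, sz = seed
    pred = {(sx, sy, sz): None}
    frontier = [(vol[sx, sy, sz], 0, (sx, sy, sz))]
    age = 1
    stop = None
    deepest = (sx, sy, sz)
    while frontier:
        # highest intensity first, FIFO on ties
        best = min(range(len(frontier)),
                   key=lambda i: (-frontier[i][0], frontier[i][1]))
        _, _, v = frontier.pop(best)
        if abs(v[2] - sz) > abs(deepest[2] - sz):
            deepest = v
        if abs(v[2] - sz) >= depth:
            stop = v
            break
        x, y, z = v
        for nb in ((x - 1, y, z), (x + 1, y, z), (x, y - 1, z),
                   (x, y + 1, z), (x, y, z - 1), (x, y, z + 1)):
            if nb in pred:
                continue
            if not all(0 <= c < s for c, s in zip(nb, vol.shape)):
                continue
            if (nb[2] - sz) * step < 0:
                continue
            pred[nb] = v
            frontier.append((vol[nb], age, nb))
            age += 1
    if stop is None:
        stop = deepest
    out = np.zeros(vol.shape, dtype=bool)
    cur = stop
    while cur is not None:
        out[cur] = True
        cur = pred[cur]
    return out


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_phantom():
    """One corpus-scale phantom with ground truth (cached per session)."""
    spec = PhantomSpec(shape=(96, 96, 72), seed=3)
    volume, labels = generate_phantom(spec)
    return spec, volume, labels


@pytest.fixture(scope="session")
def phantom_slice(small_phantom):
    """A radioulnar-zone axial slice of the session phantom."""
    _, volume, _ = small_phantom
    return volume[:, :, 62].astype(np.float64)
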