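"""Segmentation-quality metrics: three-point ROC area, mean similarity and
granulometric mean absolute distance, plus the majority-voting consensus.

All three metrics compare a binary segmentation against a binary ground
truth.  AUC is the area under the three-point ROC polyline
``{(0,0), (FPR,TPR), (1,1)}``; MS is the Jaccard overlap of the two masks;
MAD is the size-weighted mean of the granulometric pattern spectrum of their
symmetric difference, computed with unit-diamond openings, and estimates the
mean boundary offset in voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import BONE_NAMES, group_of

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "auc",
    "mean_similarity",
    "xor_mask",
    "pattern_spectrum",
    "mad",
    "majority_vote",
    "MetricsReport",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise 2x2 contingency between a ground truth and a segmentation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def fpr(self) -> float:
        denom = self.fp + self.tn
        if denom == 0:
            raise ValueError("FPR undefined: no negative-class voxels")
        return self.fp / denom

    @property
    def tpr(self) -> float:
        denom = self.tp + self.fn
        if denom == 0:
            raise ValueError("TPR undefined: no positive-class voxels")
        return self.tp / denom


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def confusion_counts(ground_truth: np.ndarray, segmentation: np.ndarray) -> ConfusionCounts:
    gt, seg = _check_shapes(ground_truth, segmentation)
    tp = int(np.count_nonzero(gt & seg))
    fp = int(np.count_nonzero(~gt & seg))
    fn = int(np.count_nonzero(gt & ~seg))
    tn = gt.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def auc(counts: ConfusionCounts | None = None, *, fpr: float | None = None,
        tpr: float | None = None) -> float:
    """Area under the three-point ROC ``{(0,0), (FPR,TPR), (1,1)}``.

    ``AUC = FPR*TPR/2 + (1-FPR)*(1+TPR)/2``.  Equals 1 for an ideal
    classifier (FPR=0, TPR=1) and 0.5 anywhere on the chance diagonal
    FPR=TPR.  Either a :class:`ConfusionCounts` or explicit rates may be
    given.
    """
    if counts is not None:
        fpr, tpr = counts.fpr, counts.tpr
    if fpr is None or tpr is None:
        raise ValueError("provide either counts or both fpr and tpr")
    if not (0.0 <= fpr <= 1.0 and 0.0 <= tpr <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    return fpr * tpr / 2.0 + (1.0 - fpr) * (1.0 + tpr) / 2.0


def mean_similarity(ground_truth: np.ndarray, segmentation: np.ndarray) -> float:
    """Jaccard overlap |gt ∩ seg| / |gt ∪ seg| of two binary masks."""
    gt, seg = _check_shapes(ground_truth, segmentation)
    union = int(np.count_nonzero(gt | seg))
    if union == 0:
        raise ValueError("mean similarity undefined: both masks are empty")
    inter = int(np.count_nonzero(gt & seg))
    return inter / union


def xor_mask(ground_truth: np.ndarray, segmentation: np.ndarray) -> np.ndarray:
    """Symmetric difference of two binary masks."""
    gt, seg = _check_shapes(ground_truth, segmentation)
    return gt ^ seg


def _unit_diamond(ndim: int) -> np.ndarray:
    return ndimage.generate_binary_structure(ndim, 1)


def opening_by_diamond(mask: np.ndarray, n: int, method: str = "iterated") -> np.ndarray:
    """Morphological opening by the size-n diamond (n-fold city-block ball).

    ``method='iterated'`` performs n unit erosions then n unit dilations;
    ``method='structuring'`` builds the size-n element explicitly and applies
    a single erosion/dilation pair.  Both are equivalent for diamond elements.
    """
    mask = np.asarray(mask, dtype=bool)
    if n == 0:
        return mask.copy()
    unit = _unit_diamond(mask.ndim)
    if method == "iterated":
        eroded = ndimage.binary_erosion(mask, structure=unit, iterations=n, border_value=0)
        if not eroded.any():
            return eroded
        return ndimage.binary_dilation(eroded, structure=unit, iterations=n, border_value=0)
    if method == "structuring":
        se = ndimage.iterate_structure(unit, n)
        eroded = ndimage.binary_erosion(mask, structure=se, border_value=0)
        if not eroded.any():
            return eroded
        return ndimage.binary_dilation(eroded, structure=se, border_value=0)
    raise ValueError(f"unknown opening method: {method!r}")


def pattern_spectrum(mask: np.ndarray) -> dict[int, int]:
    """Granulometric pattern spectrum from successive unit-diamond openings.

    ``PS(n) = |opening_{n-1}(mask)| - |opening_n(mask)|`` for n >= 1, with
    opening_0 the identity.  For a bounded mask every pixel disappears at a
    finite opening size, so the spectrum masses sum to ``|mask|``.
    """
    mask = np.asarray(mask, dtype=bool)
    spectrum: dict[int, int] = {}
    prev_count = int(np.count_nonzero(mask))
    if prev_count == 0:
        return spectrum
    unit = _unit_diamond(mask.ndim)
    eroded = mask
    n = 0
    while prev_count > 0:
        n += 1
        eroded = ndimage.binary_erosion(eroded, structure=unit, border_value=0)
        if eroded.any():
            opened = ndimage.binary_dilation(eroded, structure=unit, iterations=n,
                                             border_value=0)
            count = int(np.count_nonzero(opened))
        else:
            count = 0
        if prev_count - count:
            spectrum[n] = prev_count - count
        prev_count = count
    return spectrum


def _spectrum_mean(spectrum: dict[int, int]) -> float:
    total = sum(spectrum.values())
    if total == 0:
        return 0.0
    return sum(n * m for n, m in spectrum.items()) / total


def mad(ground_truth: np.ndarray, segmentation: np.ndarray, mode: str = "3d") -> float:
    """Granulometric mean absolute distance between two binary masks.

    The size-weighted mean of the pattern spectrum of the XOR mask; 0 when
    the masks are identical (the spectrum is then empty and the 0/0 ratio is
    resolved as perfect accuracy).  ``mode='3d'`` (default) computes the
    granulometry on the full XOR volume; ``mode='per-slice'`` computes 2D
    spectra per axial slice and pools them before taking the mean.
    """
    gt, seg = _check_shapes(ground_truth, segmentation)
    diff = gt ^ seg
    if not diff.any():
        return 0.0
    if mode == "3d" or diff.ndim == 2:
        return _spectrum_mean(pattern_spectrum(diff))
    if mode == "per-slice":
        pooled: dict[int, int] = {}
        for z in range(diff.shape[2]):
            for n, m in pattern_spectrum(diff[:, :, z]).items():
                pooled[n] = pooled.get(n, 0) + m
        return _spectrum_mean(pooled)
    raise ValueError(f"unknown mad mode: {mode!r}")


def majority_vote(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise majority vote over a stack of binary masks."""
    if len(masks) == 0:
        raise ValueError("majority_vote requires at least one mask")
    arrs = [np.asarray(m, dtype=bool) for m in masks]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all masks must share a shape")
    if len(arrs) % 2 == 0:
        warnings.warn("majority_vote with an even number of masks; strict "
                      "majority is required so exact ties go to background")
    votes = np.zeros(shape, dtype=np.int32)
    for a in arrs:
        votes += a
    return votes * 2 > len(arrs)


@dataclass
class MetricsReport:
    """Per-bone metric table plus group/overall aggregates.

    ``per_label`` has one row per bone (columns: label, name, group, auc, ms,
    mad, missing); ``aggregates`` holds mean and standard deviation of each
    metric per group and overall, over non-missing bones.
    """

    per_label: pd.DataFrame
    aggregates: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_label.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "per_label": self.per_label.to_dict(orient="records"),
            "aggregates": self.aggregates.reset_index().to_dict(orient="records"),
        }


def _joint_bbox(a: np.ndarray, b: np.ndarray, pad: int = 1) -> tuple[slice, ...]:
    union = a | b
    coords = np.nonzero(union)
    slices = []
    for axis, c in enumerate(coords):
        lo = max(int(c.min()) - pad, 0)
        hi = min(int(c.max()) + pad + 1, union.shape[axis])
        slices.append(slice(lo, hi))
    return tuple(slices)


def evaluate(
    ground_truth: np.ndarray,
    segmentation: np.ndarray,
    names: dict[int, str] | None = None,
    mad_mode: str = "3d",
) -> MetricsReport:
    """Per-bone one-vs-rest comparison of two label maps.

    For each label the binary masks are compared with AUC, MS and MAD.  True
    negatives for AUC are counted inside the joint bounding box of the two
    masks (padded by one voxel) rather than over the whole field of view, so
    the ROC is not dominated by empty background.  A label present in only
    one of the maps yields a row flagged ``missing`` instead of an error.
    """
    gt = np.asarray(ground_truth)
    seg = np.asarray(segmentation)
    if gt.shape != seg.shape:
        raise ValueError(f"label map shapes differ: {gt.shape} vs {seg.shape}")
    if names is None:
        names = BONE_NAMES
    labels = sorted(set(np.unique(gt)) | set(np.unique(seg)) - {0})
    labels = [int(l) for l in labels if l != 0]

    rows = []
    for label in labels:
        name = names.get(label, str(label))
        try:
            group = group_of(name)
        except KeyError:
            group = "other"
        g = gt == label
        s = seg == label
        if not g.any() or not s.any():
            rows.append(dict(label=label, name=name, group=group,
                             auc=np.nan, ms=np.nan, mad=np.nan, missing=True))
            continue
        box = _joint_bbox(g, s)
        counts = confusion_counts(g[box], s[box])
        rows.append(dict(
            label=label, name=name, group=group,
            auc=auc(counts),
            ms=mean_similarity(g, s),
            mad=mad(g, s, mode=mad_mode),
            missing=False,
        ))
    per_label = pd.DataFrame(rows, columns=["label", "name", "group",
                                            "auc", "ms", "mad", "missing"])

    detected = per_label[~per_label["missing"]]
    agg_rows = {}
    for group, sub in detected.groupby("group"):
        agg_rows[group] = {
            "auc_mean": sub["auc"].mean(), "auc_std": sub["auc"].std(ddof=0),
            "ms_mean": sub["ms"].mean(), "ms_std": sub["ms"].std(ddof=0),
            "mad_mean": sub["mad"].mean(), "mad_std": sub["mad"].std(ddof=0),
            "n": len(sub),
        }
    if len(detected):
        agg_rows["overall"] = {
            "auc_mean": detected["auc"].mean(), "auc_std": detected["auc"].std(ddof=0),
            "ms_mean": detected["ms"].mean(), "ms_std": detected["ms"].std(ddof=0),
            "mad_mean": detected["mad"].mean(), "mad_std": detected["mad"].std(ddof=0),
            "n": len(detected),
        }
    aggregates = pd.DataFrame.from_dict(agg_rows, orient="index")
    return MetricsReport(per_label=per_label, aggregates=aggregates)
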