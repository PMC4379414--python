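"""Atlas-to-case registration and marker propagation.

Each registration runs a staged chain -- rigid, affine, then a coarse-grid
and a fine-grid free-form (B-spline) deformation -- minimizing the
mean-squares intensity metric with a regular-step gradient-descent
optimizer and linear interpolation, every stage initialized from the
previous one.  The resulting spatial mapping (fixed image space to moving
image space) is then used to resample atlas marker images into the case
space; interpolation makes the propagated markers gray-valued, so they are
re-binarized by thresholding and capped at the expected component count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .imaging import keep_largest

__all__ = [
    "AtlasSlice",
    "AtlasVolume",
    "AtlasBundle",
    "RegistrationSettings",
    "TransformChain",
    "orient_atlas",
    "register",
    "propagate_markers",
    "binarize_candidates",
]

MARKER_FOREGROUND = 255  # atlas markers are stored 8-bit-style


# ---------------------------------------------------------------------------
# atlas bundle containers

@dataclass
class AtlasSlice:
    """A 2D atlas cross section with aligned binary marker images.

    ``source_slice`` records which axial slice of the source case the cross
    section was taken from, when known.
    """

    image: np.ndarray
    markers: dict[str, np.ndarray]
    source_slice: int | None = None


@dataclass
class AtlasVolume:
    """A 3D atlas region with aligned binary marker images."""

    image: np.ndarray
    markers: dict[str, np.ndarray]


@dataclass
class AtlasBundle:
    """Atlas images for the three registration stages.

    ``radioulnar``/``metacarpal`` are axial slices with 2 and 5 markers;
    ``carpal`` is a 3D region with 8 markers; ``orientation`` records the
    handedness of the source case.
    """

    radioulnar: AtlasSlice
    metacarpal: AtlasSlice
    carpal: AtlasVolume
    orientation: str = "right"

    def __post_init__(self) -> None:
        if self.orientation not in ("left", "right"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")


def _flip(arr: np.ndarray) -> np.ndarray:
    return arr[::-1].copy()


def orient_atlas(bundle: AtlasBundle, case_orientation: str) -> AtlasBundle:
    """Mirror-flip the atlas along the radial-ulnar axis when the case
    handedness differs; identity otherwise."""
    if case_orientation not in ("left", "right"):
        raise ValueError(f"unknown orientation: {case_orientation!r}")
    if case_orientation == bundle.orientation:
        return bundle
    return AtlasBundle(
        radioulnar=AtlasSlice(
            image=_flip(bundle.radioulnar.image),
            markers={k: _flip(v) for k, v in bundle.radioulnar.markers.items()}),
        metacarpal=AtlasSlice(
            image=_flip(bundle.metacarpal.image),
            markers={k: _flip(v) for k, v in bundle.metacarpal.markers.items()}),
        carpal=AtlasVolume(
            image=_flip(bundle.carpal.image),
            markers={k: _flip(v) for k, v in bundle.carpal.markers.items()}),
        orientation=case_orientation,
    )


# ---------------------------------------------------------------------------
# numpy <-> SimpleITK

def to_sitk(arr: np.ndarray, spacing: tuple[float, ...]) -> sitk.Image:
    """Convert an ``[x, y(, z)]``-indexed array to a SimpleITK image."""
    arr = np.asarray(arr, dtype=np.float64)
    img = sitk.GetImageFromArray(arr.T)  # sitk expects [z, y, x] memory order
    img.SetSpacing(tuple(float(s) for s in spacing[: arr.ndim]))
    return img


def from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


# ---------------------------------------------------------------------------
# staged registration

@dataclass(frozen=True)
class RegistrationSettings:
    """Knobs for the staged registration.

    ``coarse_mesh``/``fine_mesh`` are B-spline mesh sizes (cells per axis);
    with cubic splines mesh sizes 1 and 5 give about 4 and 8 control points
    per axis, a 2x refinement between the two deformable stages.
    ``min_step`` is the regular-step optimizer's stopping step length
    relative to ``learning_rate``.
    """

    stages: tuple[str, ...] = ("rigid", "affine", "bspline_coarse", "bspline_fine")
    iterations: int = 200
    #: iteration cap for the deformable stages (defaults to ``iterations``)
    bspline_iterations: int | None = None
    learning_rate: float = 2.0
    affine_learning_rate: float = 1.0
    bspline_learning_rate: float = 1.0
    min_step: float = 1e-4
    relaxation: float = 0.6
    coarse_mesh: int = 1
    fine_mesh: int = 5
    pyramid: bool = True
    shrink_factors: tuple[int, ...] = (2, 1)
    smoothing_sigmas: tuple[float, ...] = (1.0, 0.0)
    #: evaluate the metric only where the fixed image is nonzero (useful for
    #: region-masked images whose zero background carries no information)
    mask_fixed: bool = False
    #: "geometry" aligns image centers, "moments" intensity centroids
    rigid_init: str = "geometry"


@dataclass
class TransformChain:
    """Composed fixed-to-moving spatial mapping with per-stage diagnostics."""

    transform: sitk.CompositeTransform
    stage_names: list[str] = field(default_factory=list)
    stage_metrics: list[float] = field(default_factory=list)
    initial_metric: float = float("nan")

    @property
    def final_metric(self) -> float:
        return self.stage_metrics[-1] if self.stage_metrics else float("nan")

    def to_json(self) -> str:
        stages = []
        n = self.transform.GetNumberOfTransforms()
        # transforms are stored innermost-last; report in stage order
        for i, name in enumerate(self.stage_names):
            t = self.transform.GetNthTransform(n - 1 - i)
            stages.append({
                "stage": name,
                "class": t.GetName(),
                "fixed_parameters": list(t.GetFixedParameters()),
                "parameters": list(t.GetParameters()),
                "metric": self.stage_metrics[i],
            })
        return json.dumps({"initial_metric": self.initial_metric, "stages": stages},
                          indent=2)


def _mean_squares(fixed: sitk.Image, moving: sitk.Image,
                  transform: sitk.Transform, masked: bool = False) -> float:
    resampled = sitk.Resample(moving, fixed, transform, sitk.sitkLinear, 0.0,
                              sitk.sitkFloat64)
    f = sitk.GetArrayViewFromImage(fixed)
    diff = f - sitk.GetArrayViewFromImage(resampled)
    if masked:
        sel = f != 0
        if sel.any():
            return float(np.mean(diff[sel] ** 2))
    return float(np.mean(diff * diff))


def _initial_stage_transform(name: str, fixed: sitk.Image, moving: sitk.Image,
                             settings: RegistrationSettings) -> sitk.Transform:
    dim = fixed.GetDimension()
    if name == "rigid":
        base = sitk.Euler2DTransform() if dim == 2 else sitk.Euler3DTransform()
        mode = (sitk.CenteredTransformInitializerFilter.MOMENTS
                if settings.rigid_init == "moments"
                else sitk.CenteredTransformInitializerFilter.GEOMETRY)
        return sitk.CenteredTransformInitializer(fixed, moving, base, mode)
    if name == "affine":
        t = sitk.AffineTransform(dim)
        center = fixed.TransformContinuousIndexToPhysicalPoint(
            [(s - 1) / 2.0 for s in fixed.GetSize()])
        t.SetCenter(center)
        return t
    if name == "bspline_coarse":
        return sitk.BSplineTransformInitializer(fixed, [settings.coarse_mesh] * dim)
    if name == "bspline_fine":
        return sitk.BSplineTransformInitializer(fixed, [settings.fine_mesh] * dim)
    raise ValueError(f"unknown registration stage: {name!r}")


def register(
    fixed: np.ndarray,
    moving: np.ndarray,
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0),
    settings: RegistrationSettings = RegistrationSettings(),
) -> TransformChain:
    """Register ``moving`` onto ``fixed`` (both ``[x, y(, z)]`` arrays).

    Returns the composed fixed-to-moving :class:`TransformChain`.  Constant
    (degenerate) images are rejected; an optimizer that stops on its
    iteration cap is reported with a warning but the best-found chain is
    still returned.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.ndim != moving.ndim:
        raise ValueError("fixed and moving images must have the same rank")
    if np.ptp(fixed) == 0 or np.ptp(moving) == 0:
        raise ValueError("cannot register constant images")
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)  # reproducibility

    f_img = to_sitk(fixed, spacing)
    m_img = to_sitk(moving, spacing)
    dim = f_img.GetDimension()

    composite = sitk.CompositeTransform(dim)
    chain = TransformChain(transform=composite)
    chain.initial_metric = _mean_squares(f_img, m_img,
                                         sitk.Transform(dim, sitk.sitkIdentity),
                                         masked=settings.mask_fixed)

    # The optimized stage transform composes innermost (it is applied to the
    # fixed-domain point first, the already-optimized chain after it), so
    # stages are appended to the composite in order.  Once the chain contains
    # a B-spline it can no longer serve as a moving initial transform (its
    # position Jacobian is unavailable); from then on the moving image is
    # resampled through the chain and the next stage is optimized alone.
    chain_has_bspline = False
    for name in settings.stages:
        stage_t = _initial_stage_transform(name, f_img, m_img, settings)
        is_bspline = name.startswith("bspline")
        if is_bspline:
            lr = settings.bspline_learning_rate
        elif name == "affine":
            lr = settings.affine_learning_rate
        else:
            lr = settings.learning_rate
        R = sitk.ImageRegistrationMethod()
        R.SetMetricAsMeanSquares()
        R.SetInterpolator(sitk.sitkLinear)
        iters = settings.iterations
        if is_bspline and settings.bspline_iterations is not None:
            iters = settings.bspline_iterations
        R.SetOptimizerAsRegularStepGradientDescent(
            learningRate=lr,
            minStep=settings.min_step * lr,
            numberOfIterations=iters,
            relaxationFactor=settings.relaxation,
            gradientMagnitudeTolerance=1e-8,
        )
        R.SetOptimizerScalesFromPhysicalShift()
        if settings.mask_fixed:
            R.SetMetricFixedMask(sitk.Cast(f_img != 0, sitk.sitkUInt8))
        if settings.pyramid and dim == 3:
            R.SetShrinkFactorsPerLevel(list(settings.shrink_factors))
            R.SetSmoothingSigmasPerLevel(list(settings.smoothing_sigmas))
            R.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        moving_for_stage = m_img
        if composite.GetNumberOfTransforms() > 0:
            if chain_has_bspline:
                moving_for_stage = sitk.Resample(m_img, f_img, composite,
                                                 sitk.sitkLinear, 0.0,
                                                 sitk.sitkFloat64)
            else:
                R.SetMovingInitialTransform(composite)
        R.SetInitialTransform(stage_t, inPlace=True)
        try:
            R.Execute(f_img, moving_for_stage)
        except RuntimeError as exc:  # optimizer failure: keep best found so far
            warnings.warn(f"registration stage {name!r} failed: {exc}")
            continue
        # accept the stage only if it does not degrade the composed metric
        candidate = sitk.CompositeTransform(composite)
        candidate.AddTransform(stage_t)
        metric = _mean_squares(f_img, m_img, candidate, masked=settings.mask_fixed)
        prev = chain.stage_metrics[-1] if chain.stage_metrics else chain.initial_metric
        if metric > prev * (1 + 1e-9) + 1e-12:
            warnings.warn(f"registration stage {name!r} did not improve the "
                          f"metric ({prev:.3g} -> {metric:.3g}); stage dropped")
            continue
        composite.AddTransform(stage_t)
        chain_has_bspline = chain_has_bspline or is_bspline
        chain.stage_names.append(name)
        chain.stage_metrics.append(metric)
    chain.transform = composite
    return chain


def propagate_markers(
    marker_image: np.ndarray,
    chain: TransformChain,
    fixed_shape: tuple[int, ...],
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Resample a (binary or gray) atlas marker image into fixed space.

    Binary inputs are scaled to the 8-bit foreground value first; linear
    interpolation makes the output gray-valued in ``[0, 255]``.
    """
    marker = np.asarray(marker_image, dtype=np.float64)
    if marker.ndim != len(fixed_shape):
        raise ValueError("marker rank does not match the fixed domain")
    if marker.dtype == bool or marker.max() <= 1.0:
        marker = marker * float(MARKER_FOREGROUND)
    m_img = to_sitk(marker, spacing)
    ref = to_sitk(np.zeros(fixed_shape), spacing)
    out = sitk.Resample(m_img, ref, chain.transform, sitk.sitkLinear, 0.0,
                        sitk.sitkFloat64)
    return from_sitk(out)


def binarize_candidates(
    gray_markers: np.ndarray,
    threshold: float = 1.0,
    k_components: int | None = None,
) -> np.ndarray:
    """Threshold a propagated gray marker image and cap the component count.

    Foreground is ``gray >= threshold`` (threshold 1 therefore keeps every
    non-negligible value of an 8-bit-scaled marker); if ``k_components`` is
    given only the k largest face-connected components survive.
    """
    gray = np.asarray(gray_markers, dtype=np.float64)
    mask = gray >= threshold
    if not mask.any():
        raise ValueError("no candidate marker voxels above the threshold")
    if k_components is not None:
        mask = keep_largest(mask, k_components)
    return mask
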