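"""End-to-end orchestration of the wrist segmentation.

Stage order: hand mask -> distal ulna/radius -> metacarpal bases -> carpals
-> merged 15-bone label map.  Each stage builds markers (atlas registration
plus marker post-processing) and runs a watershed from markers on the shared
gradient-magnitude relief; later stages consume earlier results (the carpal
region is bounded by the ulna/radius and metacarpal segmentations).  All
parameters live in :class:`PipelineConfig`; every selected threshold, slice
and registration metric is recorded in the provenance log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .hand_mask import MaskParams, background_marker, build_hand_mask, select_mask_threshold
from .imaging import gradient_magnitude, max_entropy_threshold
from .labels import BONE_IDS, BONE_NAMES, CARPALS, METACARPALS
from .markers import (assemble_markers, carpal_region, central_pixel,
                      finalize_carpal_markers, grow_marker, match_components)
from .registration import (AtlasBundle, RegistrationSettings, binarize_candidates,
                           orient_atlas, propagate_markers, register)
from .slice_selection import (SliceSelectionError, axial_profile,
                              select_metacarpal_slice, select_radioulnar_slice)
from .watershed import segment_stage

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, with the deployment defaults.

    The geometric constants (valley search range 200-500 gray levels,
    histogram box 11, closing half-size 5, growth depth 10 slices, cluster
    buffer 200, up to 10 clusters beyond 0.35 of the axial extent, profile
    depth 10% within 15% of the axial extent, marker thresholds 1/1/240,
    component caps 2/5/8, unit cortical dilation) are the pipeline's
    operating point; overriding any of them is logged in the provenance.
    """

    mask: MaskParams = MaskParams()
    growth_depth: int = 10
    buffer: int = 200
    n_keep: int = 10
    x_th_frac: float = 0.35
    min_rel_depth: float = 0.10
    max_dist_frac: float = 0.15
    marker_threshold: float = 1.0
    carpal_marker_threshold: float = 240.0
    n_radioulnar: int = 2
    n_metacarpal: int = 5
    n_carpal: int = 8
    dilation_half_size: int = 1
    carpal_crop_margin: int = 6
    registration_2d: RegistrationSettings = RegistrationSettings(
        iterations=120, pyramid=False)
    registration_3d: RegistrationSettings = RegistrationSettings(
        iterations=80, bspline_iterations=40, pyramid=True,
        shrink_factors=(4,), smoothing_sigmas=(2.0,))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial results."""

    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial


@dataclass
class PipelineResult:
    """Merged label map, per-stage label maps and the provenance log."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=lambda: dict(BONE_NAMES))
    stage_labels: dict[str, np.ndarray] = field(default_factory=dict)
    hand_mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def _seed_of(component: np.ndarray, z: int, method: str) -> tuple[int, int, int]:
    """Seed voxel of a 2D candidate marker at axial slice z."""
    if method == "centroid":
        cx, cy = ndimage.center_of_mass(component)
        px, py = int(round(cx)), int(round(cy))
        if not component[px, py]:  # concave marker: snap to the nearest pixel
            pts = np.argwhere(component)
            d = np.abs(pts - [px, py]).sum(axis=1)
            px, py = pts[int(np.argmin(d))]
        return int(px), int(py), z
    if method == "central_pixel":
        px, py = central_pixel(component)
        return int(px), int(py), z
    raise ValueError(method)


def _named_2d_candidates(
    fixed_slice: np.ndarray,
    atlas_image: np.ndarray,
    atlas_markers: dict[str, np.ndarray],
    spacing2d: tuple[float, float],
    settings: RegistrationSettings,
    threshold: float,
    k: int,
) -> tuple[dict[str, np.ndarray], object]:
    """Register one atlas slice and return named 2D candidate markers."""
    chain = register(fixed_slice, atlas_image, spacing2d, settings)
    gray = {name: propagate_markers(m, chain, fixed_slice.shape, spacing2d)
            for name, m in atlas_markers.items()}
    total = np.sum(list(gray.values()), axis=0)
    cand = binarize_candidates(total, threshold=threshold, k_components=k)
    comp_labels, sizes = _components_of(cand)
    comps = [comp_labels == i for i in range(1, sizes.size + 1)]
    named = match_components(comps, gray)
    return named, chain


def _components_of(mask: np.ndarray):
    from .imaging import connected_components
    return connected_components(mask)


def _stage_to_anatomy(stage_labels: np.ndarray, names: list[str]) -> np.ndarray:
    """Map a stage label map (1..K in marker order) to canonical bone ids."""
    out = np.zeros(stage_labels.shape, dtype=np.uint8)
    for i, name in enumerate(names, start=1):
        out[stage_labels == i] = BONE_IDS[name]
    return out


def run(
    volume: np.ndarray,
    atlas: AtlasBundle,
    config: PipelineConfig = PipelineConfig(),
    spacing: tuple[float, float, float] = (0.75, 0.75, 0.7),
    orientation: str = "right",
    marker_overrides: dict[str, "object"] | None = None,
) -> PipelineResult:
    """Segment all 15 wrist bones of a volume.

    ``marker_overrides`` may map a stage name (``radioulnar``,
    ``metacarpal``, ``carpal``) to a pre-built
    :class:`~wristseg.markers.MarkerSet`, replacing that stage's automatic
    marker construction (the manual-interaction hook).
    """
    vol = np.asarray(volume)
    prov: dict = {"config": {"growth_depth": config.growth_depth,
                             "buffer": config.buffer,
                             "mask": asdict(config.mask)},
                  "spacing": list(spacing), "orientation": orientation}
    result = PipelineResult(labels=np.zeros(vol.shape, dtype=np.uint8),
                            provenance=prov)
    overrides = marker_overrides or {}
    atlas = orient_atlas(atlas, orientation)

    # ---- hand mask ------------------------------------------------------
    try:
        th = select_mask_threshold(vol, config.mask)
        mask = build_hand_mask(vol, th, config.mask)
        bg = background_marker(mask)
        prov["mask_threshold"] = th
    except Exception as exc:
        raise StageError("mask", exc, {"result": result}) from exc
    result.hand_mask = mask

    relief = gradient_magnitude(vol)
    th_me = max_entropy_threshold(np.bincount(vol.ravel().astype(np.int64)))
    prov["max_entropy_threshold"] = th_me

    # ---- distal ulna and radius ----------------------------------------
    try:
        if "radioulnar" in overrides:
            ru_markers = overrides["radioulnar"]
            prov["radioulnar"] = {"override": True}
        else:
            profile = axial_profile(vol, mask)
            try:
                z_ru = select_radioulnar_slice(profile, config.min_rel_depth,
                                               config.max_dist_frac)
                fallback = False
            except SliceSelectionError:
                z_ru = int(np.argmax(profile.values))
                fallback = True
                warnings.warn("radioulnar slice classifier failed; falling "
                              "back to the global profile maximum")
            named2d, chain = _named_2d_candidates(
                vol[:, :, z_ru].astype(np.float64), atlas.radioulnar.image,
                atlas.radioulnar.markers, spacing[:2], config.registration_2d,
                config.marker_threshold, config.n_radioulnar)
            objects = {}
            for name in ("R", "U"):
                seed = _seed_of(named2d[name], z_ru, "centroid")
                objects[name] = grow_marker(vol, seed, config.growth_depth,
                                            direction="proximal")
            ru_markers = assemble_markers(objects, bg, stage="radioulnar")
            prov["radioulnar"] = {"slice": z_ru, "fallback": fallback,
                                  "registration": {"initial": chain.initial_metric,
                                                   "stages": chain.stage_metrics}}
        ru_stage = segment_stage(vol, ru_markers, relief=relief,
                                 dilation_half_size=config.dilation_half_size)
        ru_labels = _stage_to_anatomy(ru_stage, ru_markers.names)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("radioulnar", exc, {"result": result}) from exc
    result.stage_labels["radioulnar"] = ru_labels

    # ---- metacarpal bases ----------------------------------------------
    try:
        if "metacarpal" in overrides:
            mc_markers = overrides["metacarpal"]
            prov["metacarpal"] = {"override": True}
        else:
            z_mc = select_metacarpal_slice(vol, th_me, config.buffer,
                                           config.n_keep, config.x_th_frac)
            named2d, chain = _named_2d_candidates(
                vol[:, :, z_mc].astype(np.float64), atlas.metacarpal.image,
                atlas.metacarpal.markers, spacing[:2], config.registration_2d,
                config.marker_threshold, config.n_metacarpal)
            objects = {}
            for name in METACARPALS:
                seed = _seed_of(named2d[name], z_mc, "central_pixel")
                objects[name] = grow_marker(vol, seed, config.growth_depth,
                                            direction="distal")
            mc_markers = assemble_markers(objects, bg, stage="metacarpal")
            prov["metacarpal"] = {"slice": z_mc,
                                  "registration": {"initial": chain.initial_metric,
                                                   "stages": chain.stage_metrics}}
        mc_stage = segment_stage(vol, mc_markers, relief=relief,
                                 dilation_half_size=config.dilation_half_size)
        mc_labels = _stage_to_anatomy(mc_stage, mc_markers.names)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("metacarpal", exc, {"result": result}) from exc
    result.stage_labels["metacarpal"] = mc_labels

    # ---- carpals --------------------------------------------------------
    try:
        region = carpal_region(ru_labels, mc_labels, mask)
        if "carpal" in overrides:
            ca_markers = overrides["carpal"]
            prov["carpal"] = {"override": True}
        else:
            if not region.any():
                raise RuntimeError("empty carpal region")
            nz = np.nonzero(region)
            box = tuple(slice(max(int(c.min()) - config.carpal_crop_margin, 0),
                              min(int(c.max()) + config.carpal_crop_margin + 1,
                                  vol.shape[i]))
                        for i, c in enumerate(nz))
            fixed_sub = vol[box].astype(np.float64)
            chain = register(fixed_sub, np.asarray(atlas.carpal.image, np.float64),
                             spacing, config.registration_3d)
            gray_full: dict[str, np.ndarray] = {}
            total_full = np.zeros(vol.shape)
            for name in CARPALS:
                g = propagate_markers(atlas.carpal.markers[name], chain,
                                      fixed_sub.shape, spacing)
                full = np.zeros(vol.shape)
                full[box] = g
                gray_full[name] = full
                total_full += full
            cand = binarize_candidates(total_full,
                                       threshold=config.carpal_marker_threshold)
            comps = finalize_carpal_markers(cand, vol, th_me, config.buffer,
                                            n_components=config.n_carpal)
            named = match_components(comps, gray_full)
            named = {name: named[name] for name in CARPALS}
            ca_markers = assemble_markers(named, ~region, stage="carpal")
            prov["carpal"] = {"crop": [[s.start, s.stop] for s in box],
                              "registration": {"initial": chain.initial_metric,
                                               "stages": chain.stage_metrics}}
        ca_stage = segment_stage(vol, ca_markers, relief=relief,
                                 dilation_half_size=config.dilation_half_size)
        ca_labels = _stage_to_anatomy(ca_stage, ca_markers.names)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("carpal", exc, {"result": result}) from exc
    result.stage_labels["carpal"] = ca_labels

    # ---- merge (earlier stages win on conflicts) ------------------------
    merged = np.zeros(vol.shape, dtype=np.uint8)
    conflicts = 0
    for stage_map in (ru_labels, mc_labels, ca_labels):
        claim = (stage_map > 0)
        overlap = claim & (merged > 0)
        conflicts += int(overlap.sum())
        place = claim & (merged == 0)
        merged[place] = stage_map[place]
    prov["merge_conflict_voxels"] = conflicts
    result.labels = merged
    return result
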