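"""Synthetic wrist phantom: MR-like volumes with 15-bone ground truth.

The phantom emulates the structure a low-field T1 wrist acquisition presents
to the segmentation pipeline, not anatomical shape detail: a dark air
background, a bright-skinned soft-tissue column, and 15 bone bodies -- two
elongated proximal shafts with bulged distal ends (radius, ulna) separated
by a joint gap from two rows of four carpal ellipsoids, and five distal
metacarpal bars with bulged bases.  Every bone is a bright marrow core
wrapped in a one-voxel dark cortical shell.  Skin and marrow share an
intensity band on purpose: that overlap is the central difficulty the
marker-based watershed is designed to survive.

Bodies are defined implicitly and rasterized at coordinates displaced by a
smooth random warp, so each seed yields a plausibly deformed individual
with exact ground-truth labels and no resampling artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import BONE_IDS, BONE_NAMES, CARPALS
from .registration import AtlasBundle, AtlasSlice, AtlasVolume

__all__ = ["PhantomSpec", "generate_phantom", "derive_atlas", "hand_mask_truth",
           "REGRESSION_SEEDS", "CORPUS_SHAPE", "ATLAS_SEED", "ATLAS_WARP_SEED",
           "corpus_atlas"]

#: the fixed 20-phantom regression corpus (seeds) and its grid
REGRESSION_SEEDS: tuple[int, ...] = tuple(range(1, 21))
CORPUS_SHAPE: tuple[int, int, int] = (96, 96, 72)
ATLAS_SEED: int = 100
ATLAS_WARP_SEED: int = 101


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity model and randomness of one synthetic wrist.

    Intensities are (mean, sd) pairs in 16-bit gray levels, ordered
    background < cortical < soft tissue < marrow = skin; the soft-tissue /
    marrow contrast and the shared skin/marrow band are calibrated so that
    the pipeline's printed constants (valley search in [200, 500] gray
    levels, maximum-entropy threshold + 200) separate the classes.

    The axial axis is 2; z increases from distal (metacarpals) to proximal
    (radius/ulna).  ``deformation_amplitude`` is the peak random-warp
    displacement in voxels.
    """

    shape: tuple[int, int, int] = (160, 160, 120)
    spacing: tuple[float, float, float] = (0.75, 0.75, 0.7)
    background: tuple[float, float] = (80.0, 45.0)
    soft_tissue: tuple[float, float] = (430.0, 45.0)
    cortical: tuple[float, float] = (280.0, 50.0)
    marrow: tuple[float, float] = (980.0, 55.0)
    skin: tuple[float, float] = (980.0, 55.0)
    deformation_amplitude: float = 2.0
    deformation_grid: tuple[int, int, int] = (5, 5, 4)
    handedness: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape):
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        order = (self.background[0], self.cortical[0], self.soft_tissue[0],
                 self.marrow[0])
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError("intensity means must be ordered "
                             "background < cortical < soft tissue < marrow")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")


# ---------------------------------------------------------------------------
# canonical geometry (fractions of the grid; right-handed layout)

_SOFT = dict(cx=0.50, cy=0.50, rx=0.42, ry=0.36)

# radius/ulna: shafts from Z0 to the proximal edge, bulged distal ends
_RU = {
    "R": dict(cx=0.36, cy=0.50, rx=0.110, ry=0.095, z0=0.80, bulge=1.25),
    "U": dict(cx=0.62, cy=0.48, rx=0.075, ry=0.065, z0=0.80, bulge=1.20),
}

# metacarpal bars: shafts from the distal edge to Z1, bulged proximal bases
_MC = {
    "M1": dict(cx=0.22, cy=0.52, r=0.045, z1=0.45, bulge=1.25),
    "M2": dict(cx=0.36, cy=0.48, r=0.045, z1=0.45, bulge=1.25),
    "M3": dict(cx=0.50, cy=0.46, r=0.045, z1=0.45, bulge=1.25),
    "M4": dict(cx=0.64, cy=0.48, r=0.045, z1=0.45, bulge=1.25),
    "M5": dict(cx=0.78, cy=0.52, r=0.045, z1=0.45, bulge=1.25),
}

# carpal ellipsoids, 8-14 mm bodies in two rows: proximal A-D, distal E-H
_CARPAL = {
    "A": dict(cx=0.30, cy=0.50, cz=0.675, rx=0.055, ry=0.060, rz=0.045),
    "B": dict(cx=0.44, cy=0.49, cz=0.675, rx=0.050, ry=0.060, rz=0.045),
    "C": dict(cx=0.57, cy=0.50, cz=0.675, rx=0.048, ry=0.058, rz=0.045),
    "D": dict(cx=0.69, cy=0.53, cz=0.675, rx=0.045, ry=0.052, rz=0.042),
    "E": dict(cx=0.28, cy=0.52, cz=0.555, rx=0.048, ry=0.056, rz=0.045),
    "F": dict(cx=0.41, cy=0.50, cz=0.555, rx=0.045, ry=0.056, rz=0.045),
    "G": dict(cx=0.54, cy=0.49, cz=0.555, rx=0.050, ry=0.060, rz=0.045),
    "H": dict(cx=0.68, cy=0.51, cz=0.555, rx=0.050, ry=0.058, rz=0.045),
}


def _warp_fields(spec: PhantomSpec, rng: np.random.Generator,
                 amplitude: float | None = None) -> tuple[np.ndarray, ...]:
    """Smooth per-axis displacement fields (voxels), zero-mean, peak-scaled."""
    amp = spec.deformation_amplitude if amplitude is None else amplitude
    axes = [np.linspace(0, g - 1, s) for g, s in zip(spec.deformation_grid, spec.shape)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"))
    fields = []
    for _ in range(3):
        coarse = rng.normal(0.0, 1.0, spec.deformation_grid)
        f = ndimage.map_coordinates(coarse, mesh, order=3, mode="nearest")
        peak = np.abs(f).max()
        if peak > 0:
            f *= amp / peak
        fields.append(f)
    return tuple(fields)


def _warped_coords(spec: PhantomSpec, rng: np.random.Generator,
                   amplitude: float | None = None) -> tuple[np.ndarray, ...]:
    nx, ny, nz = spec.shape
    X, Y, Z = np.meshgrid(np.arange(nx, dtype=np.float64),
                          np.arange(ny, dtype=np.float64),
                          np.arange(nz, dtype=np.float64), indexing="ij")
    ux, uy, uz = _warp_fields(spec, rng, amplitude)
    return X + ux, Y + uy, Z + uz


def _rasterize_bodies(spec: PhantomSpec, X, Y, Z) -> dict[str, np.ndarray]:
    """Evaluate the implicit bone bodies at the (warped) coordinates."""
    nx, ny, nz = spec.shape
    bodies: dict[str, np.ndarray] = {}

    for name, g in _RU.items():
        cx, cy = g["cx"] * nx, g["cy"] * ny
        z0 = g["z0"] * nz
        # bulge factor decays proximally from the distal end of the shaft
        width = 0.06 * nz
        b = 1.0 + (g["bulge"] - 1.0) * np.exp(-((Z - z0) / width) ** 2 * (Z >= z0))
        rx, ry = g["rx"] * nx * b, g["ry"] * ny * b
        radial = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2
        shaft = (radial <= 1.0) & (Z >= z0)
        cap = (((X - cx) / (g["rx"] * nx * g["bulge"])) ** 2
               + ((Y - cy) / (g["ry"] * ny * g["bulge"])) ** 2
               + ((Z - z0) / (0.035 * nz)) ** 2 <= 1.0)
        bodies[name] = shaft | cap

    for name, g in _MC.items():
        cx, cy = g["cx"] * nx, g["cy"] * ny
        z1 = g["z1"] * nz
        width = 0.06 * nz
        b = 1.0 + (g["bulge"] - 1.0) * np.exp(-((Z - z1) / width) ** 2 * (Z <= z1))
        r_x, r_y = g["r"] * nx * b, g["r"] * nx * b
        radial = ((X - cx) / r_x) ** 2 + ((Y - cy) / r_y) ** 2
        shaft = (radial <= 1.0) & (Z <= z1)
        cap = (((X - cx) / (g["r"] * nx * g["bulge"])) ** 2
               + (((Y - cy) / (g["r"] * nx * g["bulge"])) ** 2)
               + ((Z - z1) / (0.030 * nz)) ** 2 <= 1.0)
        bodies[name] = shaft | cap

    for name, g in _CARPAL.items():
        bodies[name] = (((X - g["cx"] * nx) / (g["rx"] * nx)) ** 2
                        + ((Y - g["cy"] * ny) / (g["ry"] * ny)) ** 2
                        + ((Z - g["cz"] * nz) / (g["rz"] * nz)) ** 2 <= 1.0)
    return bodies


def _soft_mask(spec: PhantomSpec, X, Y) -> np.ndarray:
    nx, ny, _ = spec.shape
    return (((X - _SOFT["cx"] * nx) / (_SOFT["rx"] * nx)) ** 2
            + ((Y - _SOFT["cy"] * ny) / (_SOFT["ry"] * ny)) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom; returns ``(volume uint16, labels uint8)``.

    Deterministic in ``spec.seed``.  Raises if the deformed bone bodies
    touch (they must stay pairwise separated by at least one voxel so that
    each keeps a closed cortical shell).
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = _warped_coords(spec, rng)
    bodies = _rasterize_bodies(spec, X, Y, Z)
    soft = _soft_mask(spec, X, Y)

    unit3 = ndimage.generate_binary_structure(3, 1)
    all_bone = np.zeros(spec.shape, dtype=np.int32)
    for name, body in bodies.items():
        dil = ndimage.binary_dilation(body, structure=unit3, border_value=0)
        all_bone += dil
    if int(all_bone.max()) > 1:
        raise ValueError("phantom bone bodies overlap or touch under this "
                         "deformation; reduce the amplitude")

    labels = np.zeros(spec.shape, dtype=np.uint8)
    mean_map = np.full(spec.shape, spec.background[0])
    sd_map = np.full(spec.shape, spec.background[1])

    mean_map[soft] = spec.soft_tissue[0]
    sd_map[soft] = spec.soft_tissue[1]
    # skin: the outer two-voxel in-plane rim of the soft-tissue column
    inplane = np.zeros((3, 3, 1), dtype=bool)
    inplane[1, :, 0] = inplane[:, 1, 0] = True
    skin = soft & ~ndimage.binary_erosion(soft, structure=inplane, iterations=2,
                                          border_value=0)
    mean_map[skin] = spec.skin[0]
    sd_map[skin] = spec.skin[1]

    for name, body in bodies.items():
        marrow = ndimage.binary_erosion(body, structure=unit3, border_value=0)
        shell = body & ~marrow
        mean_map[marrow] = spec.marrow[0]
        sd_map[marrow] = spec.marrow[1]
        mean_map[shell] = spec.cortical[0]
        sd_map[shell] = spec.cortical[1]
        labels[body] = BONE_IDS[name]

    noise = rng.standard_normal(spec.shape)
    volume = np.clip(mean_map + noise * sd_map, 0, 65535).astype(np.uint16)
    if spec.handedness == "left":
        volume = volume[::-1].copy()
        labels = labels[::-1].copy()
    return volume, labels


def hand_mask_truth(spec: PhantomSpec, seed: int | None = None) -> np.ndarray:
    """Ground-truth soft-tissue column of a phantom (same warp as the seed)."""
    s = spec if seed is None else _respec(spec, seed=seed)
    rng = np.random.default_rng(s.seed)
    X, Y, _ = _warped_coords(s, rng)
    mask = _soft_mask(s, X, Y)
    if s.handedness == "left":
        mask = mask[::-1].copy()
    return mask


def _respec(spec: PhantomSpec, **kw) -> PhantomSpec:
    from dataclasses import replace
    return replace(spec, **kw)


def corpus_atlas(shape: tuple[int, int, int] = CORPUS_SHAPE) -> AtlasBundle:
    """The atlas bundle used with the regression corpus: derived from the
    phantom with :data:`ATLAS_SEED`, warped with :data:`ATLAS_WARP_SEED`."""
    spec = PhantomSpec(shape=shape, seed=ATLAS_SEED)
    vol, lab = generate_phantom(spec)
    return derive_atlas(vol, lab, spec, seed=ATLAS_WARP_SEED)


def _erode_marker(mask: np.ndarray, iterations: int) -> np.ndarray:
    if iterations <= 0:
        return np.asarray(mask, dtype=bool).copy()
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure,
                                    iterations=iterations, border_value=0)
    return eroded if eroded.any() else mask


def derive_atlas(
    volume: np.ndarray,
    labels: np.ndarray,
    spec: PhantomSpec,
    warp_amplitude: float = 1.5,
    seed: int = 1000,
    marker_erosion: int = 2,
    carpal_marker_erosion: int = 0,
    carpal_margin: int = 6,
) -> AtlasBundle:
    """Build an atlas bundle from a phantom by warping and intensity jitter.

    Stands in for the expert-prepared atlas of a real deployment.  The
    radioulnar and metacarpal atlas slices are taken where the respective
    bones have the largest axial cross-sectional area; the carpal atlas is
    the subvolume around the eight carpals.  Marker images are the
    ground-truth bodies eroded ``marker_erosion`` times (so they sit well
    inside the bones) at 8-bit foreground value 255.
    """
    rng = np.random.default_rng(seed)
    warp_spec = _respec(spec, deformation_grid=(4, 4, 3))
    ux, uy, uz = _warp_fields(warp_spec, rng, amplitude=warp_amplitude)
    X, Y, Z = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in spec.shape),
                          indexing="ij")
    coords = np.stack([X + ux, Y + uy, Z + uz])

    vol = ndimage.map_coordinates(np.asarray(volume, dtype=np.float64), coords,
                                  order=1, mode="nearest")
    gain = 1.0 + rng.normal(0.0, 0.03)
    offset = rng.normal(0.0, 10.0)
    vol = np.clip(vol * gain + offset, 0, 65535)

    warped_labels = np.zeros(spec.shape, dtype=np.uint8)
    for label in range(1, 16):
        body = ndimage.map_coordinates((np.asarray(labels) == label).astype(np.float64),
                                       coords, order=1, mode="nearest") >= 0.5
        warped_labels[body] = label

    def slice_of_largest_area(names: tuple[str, ...]) -> int:
        sel = np.isin(warped_labels, [BONE_IDS[n] for n in names])
        areas = sel.sum(axis=(0, 1))
        return int(np.argmax(areas))

    z_ru = slice_of_largest_area(("R", "U"))
    z_mc = slice_of_largest_area(("M1", "M2", "M3", "M4", "M5"))

    def slice_markers(z: int, names: tuple[str, ...]) -> dict[str, np.ndarray]:
        return {n: _erode_marker(warped_labels[:, :, z] == BONE_IDS[n], marker_erosion)
                for n in names}

    radioulnar = AtlasSlice(image=vol[:, :, z_ru].copy(),
                            markers=slice_markers(z_ru, ("R", "U")),
                            source_slice=z_ru)
    metacarpal = AtlasSlice(image=vol[:, :, z_mc].copy(),
                            markers=slice_markers(z_mc, ("M1", "M2", "M3", "M4", "M5")),
                            source_slice=z_mc)

    carpal_mask = np.isin(warped_labels, [BONE_IDS[n] for n in CARPALS])
    if not carpal_mask.any():
        raise ValueError("warp removed all carpal voxels from the atlas")
    # the atlas carpal image mirrors the case-side construction: the volume
    # masked to the carpal region (bounded by the ulna/radius and metacarpal
    # envelopes) and cropped to it
    from .hand_mask import MaskParams, build_hand_mask, select_mask_threshold
    from .markers import carpal_region

    vol_u16 = np.clip(vol, 0, 65535).astype(np.uint16)
    params = MaskParams()
    mask = build_hand_mask(vol_u16, select_mask_threshold(vol_u16, params), params)
    ru_map = np.where(np.isin(warped_labels, [BONE_IDS["R"], BONE_IDS["U"]]),
                      warped_labels, 0)
    mc_map = np.where(np.isin(warped_labels, [BONE_IDS[n] for n in
                                              ("M1", "M2", "M3", "M4", "M5")]),
                      warped_labels, 0)
    region = carpal_region(ru_map, mc_map, mask,
                           radius_label=BONE_IDS["R"], ulna_label=BONE_IDS["U"],
                           m1_label=BONE_IDS["M1"], m5_label=BONE_IDS["M5"])
    region |= carpal_mask  # never let envelope quantization clip a carpal
    coords_nz = np.nonzero(region)
    box = tuple(slice(max(int(c.min()) - carpal_margin, 0),
                      min(int(c.max()) + carpal_margin + 1, spec.shape[i]))
                for i, c in enumerate(coords_nz))
    carpal = AtlasVolume(
        image=vol[box].copy(),
        markers={n: _erode_marker(warped_labels[box] == BONE_IDS[n],
                                  carpal_marker_erosion)
                 for n in CARPALS},
    )
    return AtlasBundle(radioulnar=radioulnar, metacarpal=metacarpal, carpal=carpal,
                       orientation=spec.handedness)
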