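"""Volume, label-map and atlas-bundle I/O.

Two volume formats are supported: raw 16-bit unsigned binary with a JSON
sidecar describing the geometry (the export format of the scanner console),
and NIfTI (.nii / .nii.gz) through nibabel.  Arrays keep the package's
``[x, y, z]`` axis convention; NIfTI affines carry the voxel spacing.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .registration import AtlasBundle, AtlasSlice, AtlasVolume

__all__ = [
    "load_raw_volume",
    "save_raw_volume",
    "load_volume",
    "save_volume",
    "write_labelmap",
    "read_labelmap",
    "save_atlas",
    "load_atlas",
]


def load_raw_volume(
    path: str | Path,
    shape: tuple[int, int, int] | None = None,
    spacing: tuple[float, float, float] | None = None,
    byteorder: str | None = None,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a raw uint16 volume; geometry from arguments or a JSON sidecar.

    The sidecar ``<path>.json`` must contain ``shape`` (x, y, z), ``spacing``
    in mm and optionally ``byteorder`` ("little"/"big", default little).
    Raises if the file length disagrees with the declared shape.
    """
    path = Path(path)
    if shape is None or spacing is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw volume needs geometry: missing {sidecar}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"]) if shape is None else shape
        spacing = tuple(meta["spacing"]) if spacing is None else spacing
        byteorder = byteorder or meta.get("byteorder", "little")
    byteorder = byteorder or "little"
    dtype = np.dtype(np.uint16).newbyteorder("<" if byteorder == "little" else ">")
    data = np.fromfile(path, dtype=dtype)
    expected = int(np.prod(shape))
    if data.size != expected:
        raise ValueError(f"raw file holds {data.size} voxels but geometry "
                         f"declares {expected}")
    # raw files are written z-slowest (slice after slice)
    vol = data.reshape(shape[::-1]).T.astype(np.uint16)
    return np.ascontiguousarray(vol), tuple(float(s) for s in spacing)


def save_raw_volume(
    path: str | Path,
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    byteorder: str = "little",
) -> None:
    path = Path(path)
    vol = np.asarray(volume, dtype=np.uint16)
    dtype = np.dtype(np.uint16).newbyteorder("<" if byteorder == "little" else ">")
    vol.T.astype(dtype).tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "shape": list(vol.shape), "spacing": list(spacing), "byteorder": byteorder,
    }))


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def load_volume(path: str | Path, **raw_kwargs):
    """Load a volume in either supported format.

    Returns ``(data, spacing)``.
    """
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return data, spacing
    return load_raw_volume(path, **raw_kwargs)


def save_volume(path: str | Path, volume: np.ndarray,
                spacing: tuple[float, float, float]) -> None:
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([*spacing, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))
        return
    save_raw_volume(path, volume, spacing)


def write_labelmap(path: str | Path, labelmap: np.ndarray,
                   spacing: tuple[float, float, float],
                   names: dict[int, str] | None = None) -> None:
    """Write a label volume plus a JSON label table next to it."""
    path = Path(path)
    save_volume(path, np.asarray(labelmap, dtype=np.uint8), spacing)
    if names is not None:
        table = path.with_suffix("").with_suffix("")  # strip .nii.gz
        Path(str(table) + ".labels.json").write_text(
            json.dumps({str(k): v for k, v in names.items()}, indent=2))


def read_labelmap(path: str | Path) -> tuple[np.ndarray, dict[int, str] | None]:
    data, _ = load_volume(path)
    table_path = Path(str(Path(path)).removesuffix(".nii.gz").removesuffix(".nii")
                      + ".labels.json")
    names = None
    if table_path.exists():
        names = {int(k): v for k, v in json.loads(table_path.read_text()).items()}
    return np.asarray(data), names


# ---------------------------------------------------------------------------
# atlas bundles: a directory of NIfTI images plus a manifest

def save_atlas(directory: str | Path, bundle: AtlasBundle,
               spacing: tuple[float, float, float]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"orientation": bundle.orientation, "spacing": list(spacing),
                "stages": {}}

    def put(stage: str, image: np.ndarray, markers: dict[str, np.ndarray]) -> None:
        img_name = f"{stage}_image.nii.gz"
        save_volume(directory / img_name, np.asarray(image, dtype=np.float64), spacing)
        marker_names = {}
        for name, m in markers.items():
            m_name = f"{stage}_marker_{name}.nii.gz"
            save_volume(directory / m_name, np.asarray(m, dtype=np.uint8), spacing)
            marker_names[name] = m_name
        manifest["stages"][stage] = {"image": img_name, "markers": marker_names}

    put("radioulnar", bundle.radioulnar.image, bundle.radioulnar.markers)
    put("metacarpal", bundle.metacarpal.image, bundle.metacarpal.markers)
    put("carpal", bundle.carpal.image, bundle.carpal.markers)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_atlas(directory: str | Path) -> tuple[AtlasBundle, tuple[float, ...]]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"not an atlas bundle: missing {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
        orientation = manifest["orientation"]
        stages = manifest["stages"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"corrupted atlas manifest {manifest_path}: {exc}") from exc

    def get(stage: str):
        entry = stages[stage]
        image, _ = load_volume(directory / entry["image"])
        markers = {}
        for name, fname in entry["markers"].items():
            m, _ = load_volume(directory / fname)
            markers[name] = np.asarray(m) > 0
        return np.asarray(image), markers

    ru_img, ru_m = get("radioulnar")
    mc_img, mc_m = get("metacarpal")
    ca_img, ca_m = get("carpal")
    bundle = AtlasBundle(
        radioulnar=AtlasSlice(image=ru_img, markers=ru_m),
        metacarpal=AtlasSlice(image=mc_img, markers=mc_m),
        carpal=AtlasVolume(image=ca_img, markers=ca_m),
        orientation=orientation,
    )
    return bundle, tuple(manifest.get("spacing", (1.0, 1.0, 1.0)))
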