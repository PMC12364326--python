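"""Volume, composite and preview file formats.

MetaImage (.mhd + .raw) is read and written with a small native parser
(header keys limited to what uncompressed single-volume files use);
NIfTI goes through nibabel.  Preprocessed composites travel as NPZ
archives; PNG previews are for humans only and are never read back.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .preprocessing import PseudoColorImage, WindowSpec, window_hu

__all__ = ["read_volume", "write_volume", "export_composite",
           "import_composite", "write_preview_png", "write_mask_png"]

_MET_TYPES = {
    "MET_UCHAR": np.uint8, "MET_CHAR": np.int8,
    "MET_SHORT": np.int16, "MET_USHORT": np.uint16,
    "MET_INT": np.int32, "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
}
_TYPE_NAMES = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a volume as ``(data (slice, row, col), spacing (slice, row, col))``."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file")
    name = path.name.lower()
    if name.endswith(".mhd"):
        return _read_metaimage(path)
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)  # (x, y, z)
        zooms = img.header.get_zooms()[:3]
        return data.T.astype(np.float64), (float(zooms[2]), float(zooms[1]),
                                           float(zooms[0]))
    raise IOError(f"{path}: unsupported volume format (use .mhd or .nii[.gz])")


def _read_metaimage(path: Path):
    header: dict[str, str] = {}
    try:
        for line in path.read_text().splitlines():
            if "=" in line:
                key, value = line.split("=", 1)
                header[key.strip()] = value.strip()
    except UnicodeDecodeError as exc:
        raise IOError(f"{path}: not a text MetaImage header ({exc})") from exc
    for required in ("DimSize", "ElementType", "ElementDataFile"):
        if required not in header:
            raise IOError(f"{path}: missing MetaImage key {required}")
    dims = [int(v) for v in header["DimSize"].split()]  # x y z
    dtype = _MET_TYPES.get(header["ElementType"])
    if dtype is None:
        raise IOError(f"{path}: unsupported ElementType {header['ElementType']}")
    raw_path = path.parent / header["ElementDataFile"]
    if not raw_path.exists():
        raise IOError(f"{path}: companion raw file {raw_path.name} is missing")
    data = np.fromfile(raw_path, dtype=dtype)
    expected = int(np.prod(dims))
    if data.size != expected:
        raise IOError(f"{raw_path}: expected {expected} voxels, got {data.size}")
    volume = data.reshape(dims[::-1])  # (z, y, x)
    spacing_xyz = [float(v) for v in header.get(
        "ElementSpacing", "1 1 1").split()]
    spacing = tuple(spacing_xyz[::-1])
    return volume.astype(np.float64), spacing


def write_volume(volume: np.ndarray, path,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 dtype=np.float64) -> Path:
    """Write ``(slice, row, col)`` data; format chosen by extension."""
    path = Path(path)
    volume = np.asarray(volume).astype(dtype)
    name = path.name.lower()
    if name.endswith(".mhd"):
        raw_name = path.with_suffix(".raw").name
        dims = volume.shape[::-1]
        header = "\n".join([
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            f"DimSize = {dims[0]} {dims[1]} {dims[2]}",
            f"ElementSpacing = {spacing[2]} {spacing[1]} {spacing[0]}",
            f"ElementType = {_TYPE_NAMES[np.dtype(dtype)]}",
            f"ElementDataFile = {raw_name}",
        ]) + "\n"
        path.write_text(header)
        volume.tofile(path.parent / raw_name)
        return path
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
        nib.save(nib.Nifti1Image(volume.T, affine), str(path))
        return path
    raise IOError(f"{path}: unsupported volume format (use .mhd or .nii[.gz])")


_COMPOSITE_FIELDS = ("image", "mask", "mask_pyramid", "edge_pyramid")


def export_composite(sample: dict, path, provenance: dict | None = None) -> Path:
    """Archive one preprocessed sample (image, mask, both pyramids) as NPZ."""
    missing = [f for f in _COMPOSITE_FIELDS
               if f not in sample or sample[f] is None]
    if missing:
        raise ValueError(f"incomplete sample, missing fields: {missing}")
    path = Path(path)
    image = sample["image"]
    pixels = image.pixels if isinstance(image, PseudoColorImage) else image
    arrays = {"image": np.asarray(pixels), "mask": np.asarray(sample["mask"])}
    for prefix, pyramid in (("yd", sample["mask_pyramid"]),
                            ("yg", sample["edge_pyramid"])):
        levels = getattr(pyramid, "levels", pyramid)
        for k, level in enumerate(levels, start=1):
            arrays[f"{prefix}_{k}"] = np.asarray(level)
    arrays["provenance"] = np.array(json.dumps(provenance or {}))
    np.savez(path, **arrays)
    return path


def import_composite(path) -> dict:
    with np.load(Path(path), allow_pickle=False) as npz:
        out = {
            "image": npz["image"],
            "mask": npz["mask"],
            "mask_pyramid": [npz[k] for k in sorted(npz.files)
                             if k.startswith("yd_")],
            "edge_pyramid": [npz[k] for k in sorted(npz.files)
                             if k.startswith("yg_")],
            "provenance": json.loads(str(npz["provenance"])),
        }
    return out


def write_preview_png(image, path) -> Path:
    """8-bit RGB preview of a composite, channels (prev, cur, next)."""
    pixels = image.pixels if isinstance(image, PseudoColorImage) else image
    data = (np.clip(pixels, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(data, mode="RGB").save(path)
    return Path(path)


def write_mask_png(mask: np.ndarray, path) -> Path:
    Image.fromarray((np.asarray(mask) * 255).astype(np.uint8), mode="L").save(path)
    return Path(path)


def write_slice_previews(volume_hu: np.ndarray, out_dir,
                         spec: WindowSpec = WindowSpec()) -> list[Path]:
    """Windowed 8-bit grayscale PNG per slice."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol01 = window_hu(volume_hu, spec)
    paths = []
    for i, sl in enumerate(vol01):
        p = out_dir / f"slice_{i:03d}.png"
        Image.fromarray((sl * 255).round().astype(np.uint8), mode="L").save(p)
        paths.append(p)
    return paths
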