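"""File formats: NIfTI/MetaImage volumes, displacement fields, landmark
tables, configuration and run manifests.

Axis conventions: array index order (i, j, k) as stored on disk; world
position = origin + index * spacing (axis-aligned grids only).  Landmark
files default to 1-based voxel indices (the common thoracic-landmark
dialect) and are converted to mm with a reference volume; an explicit
``unit=mm`` header (or flag) switches to millimetre input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import nibabel as nib

from .fields import DisplacementField, ImageVolume, LabelVolume

__all__ = ["read_volume", "write_volume", "read_keypoints", "write_keypoints",
           "read_field", "write_field", "write_manifest"]

_NIFTI_EXTS = (".nii", ".nii.gz")
_META_EXTS = (".mha", ".mhd")


def _ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _load_raw(path: Path):
    ext = _ext(path)
    if ext in _NIFTI_EXTS:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        origin = aff[:3, 3]
        return data, spacing, origin
    if ext in _META_EXTS:
        try:
            import SimpleITK as sitk
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading MetaImage requires SimpleITK") from exc
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).T  # sitk returns (z,y,x)
        spacing = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin())
        return data, spacing, origin
    raise ValueError(f"unsupported volume format: {path}")


def read_volume(path, as_labels: bool = False):
    """Load a 3D scalar volume (NIfTI or MetaImage)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data, spacing, origin = _load_raw(path)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"unreadable volume file {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if as_labels:
        if not np.allclose(data, np.rint(data)):
            raise ValueError(f"{path}: non-integer values in a label volume")
        return LabelVolume(np.rint(data).astype(np.int32), spacing, origin)
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(path, vol):
    path = Path(path)
    ext = _ext(path)
    data = vol.data
    if ext in _NIFTI_EXTS:
        dtype = np.int16 if isinstance(vol, LabelVolume) else np.float32
        img = nib.Nifti1Image(np.asarray(data, dtype=dtype),
                              _affine(vol.spacing, vol.origin))
        nib.save(img, str(path))
        return
    if ext in _META_EXTS:
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(np.asarray(data).T)
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path}")


def read_keypoints(path, reference=None, unit: str | None = None) -> np.ndarray:
    """Read an (N, 3) landmark table and return points in mm.

    Whitespace- or comma-separated, one point per line; lines starting with
    ``#`` are comments and may declare ``# unit=mm`` or ``# unit=voxel``.
    Voxel input (the default) is 1-based and converted with the reference
    volume's spacing/origin to mm.
    """
    path = Path(path)
    rows = []
    file_unit = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "unit=" in s:
                    file_unit = s.split("unit=")[1].strip().lower()
                continue
            if ln == 1 and any(c.isalpha() for c in s):
                continue  # header row like "x,y,z"
            parts = s.replace(",", " ").split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric entry") from exc
    pts = np.asarray(rows, dtype=np.float64)
    unit = unit or file_unit or "voxel"
    if unit == "mm":
        return pts
    if unit != "voxel":
        raise ValueError(f"unknown landmark unit {unit!r}")
    if reference is None:
        raise ValueError("voxel-unit landmarks need a reference volume")
    return (pts - 1.0) * reference.spacing + reference.origin


def write_keypoints(path, pts_mm: np.ndarray):
    pts_mm = np.asarray(pts_mm, dtype=np.float64)
    with open(path, "w") as fh:
        fh.write("# unit=mm\n")
        for p in pts_mm:
            fh.write(f"{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}\n")


def write_field(path, field: DisplacementField):
    """Store a displacement field as 4D NIfTI, 3 components in the last
    dimension, voxel units recorded in the header description."""
    data = np.moveaxis(field.data, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(field.spacing, field.origin))
    img.header["descrip"] = f"disp;unit=voxel;level={field.level}".encode()
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: displacement field must be 4D with 3 components, "
            f"got shape {data.shape}")
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    level = 1
    descrip = img.header["descrip"].tobytes().decode(errors="ignore")
    for token in descrip.split(";"):
        if token.startswith("level="):
            try:
                level = int(token.split("=")[1].rstrip("\x00"))
            except ValueError:
                pass
    return DisplacementField(np.moveaxis(data, -1, 0).astype(np.float64),
                             spacing, origin, level=level)


def write_manifest(path, config: dict):
    """Record the run configuration (seeds included) for reproducibility."""
    from . import __version__
    payload = {"lungreg_version": __version__, **config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
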