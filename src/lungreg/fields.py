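"""Core geometric types and operations: grids, images, displacement fields,
warping, composition, prolongation, and Jacobian determinants.

Conventions
-----------
* Voxel indices are 0-based; world position of index (i,j,k) is
  ``origin + index * spacing`` (axis-aligned grids only, no orientation
  matrices).
* Displacements are stored in **voxel units** of their own grid as a
  ``[3, D, H, W]`` array; the deformation is ``y(x) = x + u(x)``.
  Millimetre conversions happen only at keypoint boundaries.
* Out-of-domain samples are clamped to the boundary (edge replication).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _diffops as dops
from .autodiff import Tensor

__all__ = [
    "ImageVolume", "LabelVolume", "DisplacementField", "OneHotMask",
    "JacobianMap", "warp_image", "warp_label", "warp_onehot", "compose",
    "prolong", "restrict", "jacobian_determinant", "displace_points",
    "identity_field", "resample_volume", "points_mm_to_voxel",
    "points_voxel_to_mm",
]


def _as3(v) -> np.ndarray:
    a = np.asarray(v, dtype=np.float64).reshape(-1)
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3:
        raise ValueError("expected a 3-vector")
    return a


@dataclass
class ImageVolume:
    """A 3D scalar image with physical spacing (mm/voxel) and origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = _as3(self.spacing)
        self.origin = _as3(self.origin)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("each axis must have >= 2 voxels")
        if not np.all(self.spacing > 0):
            raise ValueError("spacing components must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image values must be finite")

    @property
    def shape(self):
        return self.data.shape

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))


@dataclass
class LabelVolume:
    """Integer label volume (0 = background, 1..k = foreground labels)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.rint(arr)):
                raise ValueError("label volume must hold integer values")
            arr = np.rint(arr).astype(np.int32)
        self.data = arr.astype(np.int32)
        self.spacing = _as3(self.spacing)
        self.origin = _as3(self.origin)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume data must be 3D")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self):
        return self.data.shape

    @property
    def k(self) -> int:
        return int(self.data.max())

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def to_onehot(self, k: int | None = None) -> "OneHotMask":
        k = self.k if k is None else k
        data = np.stack([(self.data == lab).astype(np.float64)
                         for lab in range(1, k + 1)])
        return OneHotMask(data, self.spacing.copy(), self.origin.copy())


@dataclass
class OneHotMask:
    """k-channel soft mask, channels-first [k, D, H, W], values in [0, 1]."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = _as3(self.spacing)
        self.origin = _as3(self.origin)
        if self.data.ndim != 4:
            raise ValueError("OneHotMask data must be [k, D, H, W]")

    @property
    def k(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape[1:]


@dataclass
class DisplacementField:
    """Per-voxel displacement u, voxel units, [3, D, H, W]; y(x) = x + u(x)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    level: int = 1

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = _as3(self.spacing)
        self.origin = _as3(self.origin)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError("DisplacementField data must be [3, D, H, W]")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacements must be finite")

    @property
    def shape(self):
        return self.data.shape[1:]

    def same_grid(self, other) -> bool:
        return (self.shape == (other.shape if isinstance(other.shape, tuple)
                               else tuple(other.shape))
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def magnitude_mm(self) -> np.ndarray:
        return np.sqrt(((self.data * self.spacing[:, None, None, None]) ** 2).sum(0))


@dataclass
class JacobianMap:
    """det grad(y) per voxel (dimensionless; 1 for the identity)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))


def identity_field(shape, spacing=1.0, origin=0.0, level: int = 1) -> DisplacementField:
    return DisplacementField(np.zeros((3,) + tuple(shape)), spacing, origin, level)


def _check_same_grid(a, b, what: str):
    if tuple(a.shape if isinstance(a.shape, tuple) else a.shape) != tuple(b.shape):
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise ValueError(f"{what}: spacing/origin mismatch")


def warp_image(M: ImageVolume, y: DisplacementField, mode: str = "linear") -> ImageVolume:
    """Resample M at x + u(x) on y's (fixed-image) grid: returns M o y."""
    _check_same_grid(M, y, "warp_image")
    coords = y.data + dops.base_grid(y.shape)
    if mode == "linear":
        warped = dops.trilinear_sample(M.data, coords).value
    elif mode == "nearest":
        warped = dops.nearest_sample(M.data, coords)
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return ImageVolume(warped, y.spacing.copy(), y.origin.copy())


def warp_label(L: LabelVolume, y: DisplacementField) -> LabelVolume:
    _check_same_grid(L, y, "warp_label")
    coords = y.data + dops.base_grid(y.shape)
    return LabelVolume(dops.nearest_sample(L.data, coords),
                       y.spacing.copy(), y.origin.copy())


def warp_onehot(b: OneHotMask, y: DisplacementField) -> OneHotMask:
    """Warp each channel with linear interpolation (probabilistic values)."""
    if tuple(b.shape) != tuple(y.shape):
        raise ValueError("warp_onehot: grid mismatch")
    warped = dops.warp_channels(b.data, y.data).value
    return OneHotMask(np.clip(warped, 0.0, 1.0), y.spacing.copy(), y.origin.copy())


def compose(y_coarse: DisplacementField, y_fine: DisplacementField) -> DisplacementField:
    """Functional composition x -> y_coarse(y_fine(x)) on a common grid:
    u(x) = u_fine(x) + u_coarse(x + u_fine(x))."""
    _check_same_grid(y_coarse, y_fine, "compose")
    coords = y_fine.data + dops.base_grid(y_fine.shape)
    sampled = dops.warp_channels(y_coarse.data, y_fine.data).value
    return DisplacementField(y_fine.data + sampled, y_fine.spacing.copy(),
                             y_fine.origin.copy(), level=y_fine.level)


def prolong(u: DisplacementField, target_shape) -> DisplacementField:
    """Linear upsampling to a finer grid, preserving physical displacement.

    Component a (stored in source voxel units) is scaled by
    target_shape[a] / source_shape[a] so the represented mm displacement is
    unchanged; spacing is scaled by the inverse ratio.
    """
    target_shape = tuple(int(s) for s in target_shape)
    src_shape = u.shape
    ratios = np.array([t / s for t, s in zip(target_shape, src_shape)])
    # align-corners sampling positions on the source grid
    coords = np.stack(np.meshgrid(
        *[np.linspace(0.0, s - 1.0, t) for s, t in zip(src_shape, target_shape)],
        indexing="ij"))
    comps = [dops.trilinear_sample(u.data[a], coords).value * ratios[a]
             for a in range(3)]
    return DisplacementField(np.stack(comps), u.spacing / ratios, u.origin.copy(),
                             level=max(u.level - 1, 1))


def restrict(u: DisplacementField, target_shape) -> DisplacementField:
    """Linear downsampling counterpart of prolong (used in round-trip tests)."""
    return prolong(u, target_shape)


def jacobian_determinant(y: DisplacementField) -> JacobianMap:
    """det grad(y) per voxel, finite differences in voxel units."""
    det = dops.jacobian_det(y.data).value
    return JacobianMap(det, y.spacing.copy(), y.origin.copy())


def resample_volume(I, target_shape, mode: str = "linear"):
    """Linear (or nearest, for labels) resampling to a new grid covering the
    same physical extent; used to bring inputs onto a pyramid-compatible shape.
    Target index j samples source position j * (source_shape / target_shape)."""
    target_shape = tuple(int(s) for s in target_shape)
    ratios = np.array([s / t for s, t in zip(I.shape, target_shape)])
    coords = np.stack(np.meshgrid(
        *[np.arange(t, dtype=np.float64) * r
          for t, r in zip(target_shape, ratios)], indexing="ij"))
    if mode == "linear":
        data = dops.trilinear_sample(I.data, coords).value
    elif mode == "nearest":
        data = dops.nearest_sample(np.asarray(I.data), coords)
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    new_spacing = I.spacing * ratios
    if isinstance(I, LabelVolume):
        return LabelVolume(np.rint(data).astype(np.int32), new_spacing,
                           I.origin.copy())
    return ImageVolume(data, new_spacing, I.origin.copy())


def points_mm_to_voxel(pts_mm: np.ndarray, spacing, origin) -> np.ndarray:
    return (np.asarray(pts_mm, dtype=np.float64) - _as3(origin)) / _as3(spacing)


def points_voxel_to_mm(pts_vox: np.ndarray, spacing, origin) -> np.ndarray:
    return np.asarray(pts_vox, dtype=np.float64) * _as3(spacing) + _as3(origin)


def displace_points(u: DisplacementField, pts_mm: np.ndarray,
                    as_tensor_out: bool = False):
    """Apply y(p) = p + u(p) to points given in mm; returns points in mm.

    Points outside the physical domain are sampled with clamped coordinates.
    With ``as_tensor_out=True`` and a Tensor-valued field, the result stays in
    the autodiff graph (used by the keypoint loss).
    """
    pts_mm = np.asarray(pts_mm, dtype=np.float64)
    if pts_mm.ndim != 2 or pts_mm.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array in mm")
    vox = points_mm_to_voxel(pts_mm, u.spacing, u.origin).T  # [3, N]
    data = u.data
    comps = []
    for a in range(3):
        comp = data[a] if isinstance(data, Tensor) else data[a]
        s = dops.trilinear_sample(comp, vox)
        comps.append(s * float(u.spacing[a]))
    from .autodiff import concatenate as _cat
    disp_mm = _cat([c.reshape(1, -1) for c in comps], axis=0).transpose((1, 0))
    out = disp_mm + pts_mm
    if as_tensor_out:
        return out
    return out.value


@dataclass
class TensorField:
    """A displacement field whose data is an autodiff Tensor (solver internal)."""

    data: Tensor
    spacing: np.ndarray
    origin: np.ndarray
    level: int = 1

    @property
    def shape(self):
        return self.data.shape[1:]
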