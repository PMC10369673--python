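"""Differentiable geometric primitives shared by warping, losses and solvers.

All functions accept either plain ndarrays or autodiff Tensors and return a
Tensor; callers that only need values take ``.value``.  Coordinates are in
voxel units of the sampled volume's grid, axis order (i, j, k) matching the
array axes.  Out-of-domain coordinates are clamped to the boundary
(edge-replicate sampling); the clamp also zeroes the coordinate gradient
outside the domain.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, gather3


_BASE_GRID_CACHE: dict = {}


def base_grid(shape) -> np.ndarray:
    """Voxel-index grid, shape [3, D, H, W] (cached per shape)."""
    shape = tuple(int(s) for s in shape)
    if shape not in _BASE_GRID_CACHE:
        if len(_BASE_GRID_CACHE) > 16:
            _BASE_GRID_CACHE.clear()
        _BASE_GRID_CACHE[shape] = np.stack(np.meshgrid(
            *[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"))
    return _BASE_GRID_CACHE[shape]


def trilinear_sample(vol, coords) -> Tensor:
    """Sample a 3D volume at fractional voxel coordinates.

    vol: [D, H, W]; coords: [3, ...] (Tensor or ndarray).  Differentiable with
    respect to both the volume values and the coordinates.
    """
    vol = as_tensor(vol)
    shape = vol.shape
    axes = []
    fracs = []
    bases = []
    coords = coords if isinstance(coords, Tensor) else as_tensor(coords)
    for ax in range(3):
        c = coords[ax].clip(0.0, shape[ax] - 1.0)
        i0 = np.minimum(np.floor(c.value), shape[ax] - 2).astype(np.intp)
        i0 = np.maximum(i0, 0)
        bases.append(i0)
        fracs.append(c - i0)
        axes.append(ax)
    out = None
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corner = gather3(vol, bases[0] + di, bases[1] + dj, bases[2] + dk)
                w = (fracs[0] if di else 1.0 - fracs[0]) \
                    * (fracs[1] if dj else 1.0 - fracs[1]) \
                    * (fracs[2] if dk else 1.0 - fracs[2])
                term = corner * w
                out = term if out is None else out + term
    return out


def nearest_sample(vol: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Nearest-neighbour sampling (labels); plain ndarrays only."""
    idx = []
    for ax in range(3):
        c = np.clip(np.rint(coords[ax]), 0, vol.shape[ax] - 1).astype(np.intp)
        idx.append(c)
    return vol[tuple(idx)]


def gradient_axis(t, axis: int) -> Tensor:
    """np.gradient along one axis (unit spacing): central differences in the
    interior, one-sided at the two faces.  Differentiable."""
    t = as_tensor(t)
    n = t.shape[axis]
    if n < 2:
        raise ValueError("axis too short for finite differences")

    def sl(a, b):
        idx = [slice(None)] * t.ndim
        idx[axis] = slice(a, b)
        return tuple(idx)

    first = t[sl(1, 2)] - t[sl(0, 1)]
    last = t[sl(n - 1, n)] - t[sl(n - 2, n - 1)]
    if n == 2:
        return concatenate([first, last], axis=axis)
    interior = (t[sl(2, n)] - t[sl(0, n - 2)]) * 0.5
    return concatenate([first, interior, last], axis=axis)


def laplacian_interior(t, axis_len_check: bool = True) -> Tensor:
    """7-point Laplacian of a 3D scalar field on the common interior
    (all axes restricted to 1:-1), in voxel units."""
    t = as_tensor(t)
    if axis_len_check and min(t.shape) < 3:
        raise ValueError("grid must be >= 3 per axis for the Laplacian stencil")
    core = (slice(1, -1),) * 3
    out = as_tensor(np.zeros(tuple(s - 2 for s in t.shape)))
    for ax in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[ax] = slice(0, -2)
        hi[ax] = slice(2, None)
        out = out + t[tuple(hi)] + t[tuple(lo)]
    return out - 6.0 * t[core]


def jacobian_det(u) -> Tensor:
    """det grad(y) of y(x) = x + u(x), finite differences in voxel units.

    u: [3, D, H, W].  Central differences in the interior, one-sided at the
    faces (np.gradient convention), so the identity gives exactly 1
    independently of grid spacing.
    """
    u = as_tensor(u)
    if min(u.shape[1:]) < 3:
        raise ValueError("field must be >= 3 voxels per axis for the Jacobian")
    J = [[None] * 3 for _ in range(3)]
    for a in range(3):
        comp = u[a]
        for b in range(3):
            g = gradient_axis(comp, b)
            J[a][b] = g + 1.0 if a == b else g
    det = (J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
           - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
           + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0]))
    return det


def warp_channels(channels, u, base: np.ndarray | None = None) -> Tensor:
    """Warp each channel of a [C, D, H, W] stack by displacement u (voxel
    units, [3, D, H, W]) with trilinear interpolation.

    The eight corner weights are built once and shared across channels."""
    channels = as_tensor(channels)
    u = u if isinstance(u, Tensor) else as_tensor(u)
    if base is None:
        base = base_grid(u.shape[1:])
    shape = u.shape[1:]
    bases, fr, one_minus = [], [], []
    for ax in range(3):
        c = (u[ax] + base[ax]).clip(0.0, shape[ax] - 1.0)
        i0 = np.minimum(np.floor(c.value), shape[ax] - 2).astype(np.intp)
        i0 = np.maximum(i0, 0)
        bases.append(i0)
        f = c - i0
        fr.append(f)
        one_minus.append(1.0 - f)
    corner_w = {}
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corner_w[(di, dj, dk)] = ((fr[0] if di else one_minus[0])
                                          * (fr[1] if dj else one_minus[1])
                                          * (fr[2] if dk else one_minus[2]))
    warped = []
    for ch in range(channels.shape[0]):
        out = None
        for (di, dj, dk), w in corner_w.items():
            corner = gather3(channels[ch], bases[0] + di, bases[1] + dj,
                             bases[2] + dk)
            term = corner * w
            out = term if out is None else out + term
        warped.append(out.reshape((1,) + shape))
    return concatenate(warped, axis=0)
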