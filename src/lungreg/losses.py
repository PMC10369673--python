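"""Loss terms of the anatomically constrained registration objective.

The total loss is

    L(F, M, y) = D(F, M(y)) + alpha * R(y) + beta * B(y) + gamma * V(y)
                 + delta * K(y)

with the edge-based normalized-gradient-fields distance D, the second-order
curvature regularizer R, the mask-alignment SSD B on linearly warped one-hot
lobe masks, the volume-change-control penalty V on the Jacobian determinant,
and the least-squares keypoint term K.

Discretization: every integral over the domain is implemented as a **mean**
over the (masked) voxel set, so one weight set stays scale-comparable across
pyramid levels.  Image gradients for D are spacing-aware (mm^-1); the
Laplacian of R and the Jacobian of V are taken in voxel units of the field's
own grid.  The keypoint term is in mm^2 (unnormalized squared distances),
which is why its weight is large (1e7) against the mean-based image terms.

All functionals accept a plain displacement array or an autodiff Tensor and
are differentiable with respect to it (and, for D, with respect to the warped
moving image).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _diffops as dops
from .autodiff import Tensor, as_tensor, where
from .fields import (ImageVolume, LabelVolume, OneHotMask, TensorField,
                     displace_points)

__all__ = [
    "LossWeights", "LossBreakdown", "ngf_distance", "estimate_epsilon",
    "curvature", "psi_hard", "psi_logbarrier", "psi_linear", "vcc_penalty",
    "mask_loss", "keypoint_loss", "total_loss",
]

#: weights used in the reference experiments (delta = 0 on the coarsest level)
DEFAULT_ALPHA = 10.0
DEFAULT_BETA = 1.0
DEFAULT_GAMMA = 0.01
DEFAULT_DELTA = 1e7
DEFAULT_EPSILON = 1.0
DEFAULT_T = 0.2


@dataclass
class LossWeights:
    """Hyper-parameters of the total loss."""

    alpha: float = DEFAULT_ALPHA        # curvature weight
    beta: float = DEFAULT_BETA          # mask-alignment weight
    gamma: float = DEFAULT_GAMMA        # volume-change-control weight
    delta: float = DEFAULT_DELTA        # keypoint weight
    epsilon_ngf: float = DEFAULT_EPSILON  # NGF edge parameter
    t: float = DEFAULT_T                # VCC barrier parameter
    vcc_variant: str = "linear"

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.delta) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epsilon_ngf <= 0:
            raise ValueError("epsilon_ngf must be positive")
        if self.t <= 0:
            raise ValueError("barrier parameter t must be positive")


@dataclass
class LossBreakdown:
    """Individual loss terms and their weighted sum."""

    total: float
    distance: float
    curvature: float
    vcc: float
    mask: float
    keypoint: float

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k))
                for k in ("total", "distance", "curvature", "vcc", "mask", "keypoint")}


def _grad_mm(img, spacing) -> list:
    """Spacing-aware image gradient (central differences, one-sided at faces)."""
    img = as_tensor(img)
    return [dops.gradient_axis(img, ax) * (1.0 / float(spacing[ax]))
            for ax in range(3)]


def ngf_distance(F: ImageVolume, Mw, mask: LabelVolume | None = None,
                 eps: float = DEFAULT_EPSILON) -> Tensor:
    """Normalized-gradient-fields distance between F and the warped moving
    image, averaged over the mask support (whole domain if mask is None).

    Per voxel: 1 - <gMw, gF>_eps^2 / (|gMw|_eps^2 |gF|_eps^2) with
    <f, g>_eps = sum_j f_j g_j + eps^2; the integrand lies in [0, 1].
    """
    if eps <= 0:
        raise ValueError("NGF edge parameter eps must be positive")
    mdat = Mw.data if hasattr(Mw, "data") else Mw
    spacing = F.spacing
    gF = _grad_mm(F.data, spacing)
    gM = _grad_mm(mdat, spacing)
    ip = gF[0] * gM[0] + gF[1] * gM[1] + gF[2] * gM[2] + eps ** 2
    nF = gF[0] * gF[0] + gF[1] * gF[1] + gF[2] * gF[2] + eps ** 2
    nM = gM[0] * gM[0] + gM[1] * gM[1] + gM[2] * gM[2] + eps ** 2
    integrand = 1.0 - (ip * ip) / (nF * nM)
    if mask is None:
        return integrand.mean()
    sel = np.asarray(mask.data if hasattr(mask, "data") else mask) > 0
    if not sel.any():
        raise ValueError("NGF mask is empty")
    return integrand[sel].mean()


def estimate_epsilon(I: ImageVolume, noise_level: float = 1.0) -> float:
    """Edge parameter heuristic: noise level times the mean gradient
    magnitude of the image over its domain (mm^-1)."""
    if noise_level <= 0:
        raise ValueError("noise_level must be positive")
    g = _grad_mm(I.data, I.spacing)
    mag = np.sqrt(g[0].value ** 2 + g[1].value ** 2 + g[2].value ** 2)
    eps = noise_level * float(mag.mean())
    if eps == 0.0:
        warnings.warn("constant image: epsilon heuristic returns 0; "
                      "override with a positive value", stacklevel=2)
    return eps


def curvature(u) -> Tensor:
    """Second-order curvature regularizer: mean over interior voxels of
    sum_j (Laplacian u_j)^2, 7-point stencil in voxel units.

    The Laplacian of the identity map vanishes, so Laplacian(y_j) equals
    Laplacian(u_j); affine fields have zero curvature.
    """
    udat = u.data if hasattr(u, "data") else u
    udat = udat if isinstance(udat, Tensor) else as_tensor(udat)
    total = None
    for a in range(3):
        lap = dops.laplacian_interior(udat[a])
        term = (lap * lap).mean()
        total = term if total is None else total + term
    return total


def psi_hard(z):
    """Volume-change penalty (z-1)^2/z for z > 0, +inf otherwise.

    Minimal at z=1; symmetric under z -> 1/z; an infinite barrier against
    folding (z <= 0)."""
    z = np.asarray(z, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(z > 0, (z - 1.0) ** 2 / np.where(z > 0, z, 1.0), np.inf)
    return val if val.ndim else float(val)


def psi_logbarrier(z, t: float):
    """Parametric log-barrier extension: -(1/t) log z for z >= 1/t^2, and its
    C^1 linear continuation -t z - (1/t) log(1/t^2) + 1/t below."""
    if t <= 0:
        raise ValueError("barrier parameter t must be positive")
    z = np.asarray(z, dtype=np.float64)
    zb = 1.0 / t ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        logz = np.log(np.where(z >= zb, z, 1.0))
    val = np.where(z >= zb, -logz / t, -t * z - np.log(zb) / t + 1.0 / t)
    return val if val.ndim else float(val)


def _psi_linear_tensor(z: Tensor, t: float) -> Tensor:
    hard = (z - 1.0) ** 2 / where(z.value >= t, z, t)  # guard div by z<=0
    lin = (1.0 - 1.0 / t ** 2) * z + 2.0 * (1.0 - t) / t
    return where(z.value >= t, hard, lin)


def psi_linear(z, t: float):
    """Volume-change penalty with a C^1 linear barrier below t:
    (z-1)^2/z for z >= t, else (1 - 1/t^2) z + 2(1-t)/t; 0 < t < 1.

    Halving t steepens the barrier ("barrier raising") while the symmetric
    shrinkage/expansion penalty above t is untouched."""
    if not (0.0 < t < 1.0):
        raise ValueError("psi_linear requires 0 < t < 1")
    if isinstance(z, Tensor):
        return _psi_linear_tensor(z, t)
    z = np.asarray(z, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        hard = (z - 1.0) ** 2 / np.where(z >= t, z, 1.0)
    lin = (1.0 - 1.0 / t ** 2) * z + 2.0 * (1.0 - t) / t
    val = np.where(z >= t, hard, lin)
    return val if val.ndim else float(val)


def vcc_penalty(y, t: float = DEFAULT_T, variant: str = "linear") -> Tensor | float:
    """Volume-change-control term: mean over voxels of psi(det grad y).

    ``linear`` (differentiable, the training variant) and ``logbarrier`` are
    smooth; ``hard`` returns +inf as soon as any voxel folds (det <= 0).
    """
    udat = y.data if hasattr(y, "data") else y
    det = dops.jacobian_det(udat)
    if variant == "linear":
        return _psi_linear_tensor(det, t).mean() if isinstance(det, Tensor) and det.requires_grad \
            else float(np.mean(psi_linear(det.value, t)))
    if variant == "logbarrier":
        if isinstance(det, Tensor) and det.requires_grad:
            zb = 1.0 / t ** 2
            safe = where(det.value >= zb, det, 1.0)
            val = where(det.value >= zb, -safe.log() * (1.0 / t),
                        -t * det - np.log(zb) / t + 1.0 / t)
            return val.mean()
        return float(np.mean(psi_logbarrier(det.value, t)))
    if variant == "hard":
        return float(np.mean(psi_hard(det.value)))
    raise ValueError(f"unknown VCC variant {variant!r}")


def mask_loss(bF: OneHotMask, bMw) -> Tensor:
    """Mask-alignment SSD: (1/2) mean over voxels of the per-channel squared
    difference between the warped moving and fixed one-hot masks."""
    mdat = bMw.data if hasattr(bMw, "data") else bMw
    fdat = bF.data if hasattr(bF, "data") else bF
    mdat = mdat if isinstance(mdat, Tensor) else as_tensor(mdat)
    if mdat.shape[0] != np.asarray(fdat).shape[0]:
        raise ValueError("mask_loss: channel count mismatch")
    diff = mdat - np.asarray(fdat, dtype=np.float64)
    # sum over channels, mean over voxels
    return (diff * diff).sum(axis=0).mean() * 0.5


def keypoint_loss(u, kF_mm: np.ndarray, kM_mm: np.ndarray,
                  base_field=None) -> Tensor:
    """Mean squared Euclidean distance (mm^2) between the moving keypoints and
    the displaced fixed keypoints y(k_F).

    If ``base_field`` (the composition of all preceding coarse-level fields,
    on its own grid) is given, the measured deformation is the chained map
    y_base(y(k_F)): the current field moves the point first, the frozen coarse
    field is then sampled at the moved position.  Differentiable w.r.t. u in
    both cases.
    """
    kF_mm = np.asarray(kF_mm, dtype=np.float64)
    kM_mm = np.asarray(kM_mm, dtype=np.float64)
    if kF_mm.shape != kM_mm.shape or kF_mm.ndim != 2 or kF_mm.shape[0] < 1:
        raise ValueError("keypoint_loss requires matching non-empty (N,3) arrays")
    yk = displace_points(u, kF_mm, as_tensor_out=True)
    if base_field is not None:
        yk = _displace_tensor_points(base_field, yk)
    diff = yk - kM_mm
    return (diff * diff).sum(axis=1).mean()


def _displace_tensor_points(field, pts_mm: Tensor) -> Tensor:
    """y(p) = p + u(p) for Tensor-valued point positions on a constant field."""
    from .autodiff import concatenate as _cat
    spacing = np.asarray(field.spacing, dtype=np.float64)
    origin = np.asarray(field.origin, dtype=np.float64)
    vox = (pts_mm - origin) / spacing          # [N, 3] Tensor
    coords = vox.transpose((1, 0))             # [3, N]
    comps = [dops.trilinear_sample(field.data[a], coords).reshape(1, -1)
             * float(spacing[a]) for a in range(3)]
    disp_mm = _cat(comps, axis=0).transpose((1, 0))
    return pts_mm + disp_mm


def total_loss(F: ImageVolume, M: ImageVolume, u,
               weights: LossWeights,
               bF: OneHotMask | None = None, bM: OneHotMask | None = None,
               kF_mm: np.ndarray | None = None, kM_mm: np.ndarray | None = None,
               ngf_mask: LabelVolume | None = None,
               base_field=None,
               return_tensor: bool = False):
    """Evaluate the full objective for displacement ``u`` on F's grid.

    The moving image (and one-hot moving mask, if beta > 0) are warped by u
    inside this function so the result is differentiable with respect to u.
    Terms whose weight is zero may have their data omitted.
    """
    udat = u.data if hasattr(u, "data") else u
    ut = udat if isinstance(udat, Tensor) else as_tensor(udat)
    spacing = F.spacing
    origin = F.origin
    base = dops.base_grid(F.shape)

    Mw = dops.warp_channels(M.data[None], ut, base=base)[0]
    dist = ngf_distance(F, Mw, mask=ngf_mask, eps=weights.epsilon_ngf)

    curv = curvature(ut) if weights.alpha > 0 else as_tensor(0.0)

    if weights.gamma > 0:
        field_like = TensorField(ut, spacing, origin)
        vcc = vcc_penalty(field_like, t=weights.t, variant=weights.vcc_variant)
        if not isinstance(vcc, Tensor):
            vcc = as_tensor(vcc)
    else:
        vcc = as_tensor(0.0)

    if weights.beta > 0:
        if bF is None or bM is None:
            raise ValueError("beta > 0 requires fixed and moving masks")
        bMw = dops.warp_channels(bM.data, ut, base=base)
        msk = mask_loss(bF, bMw)
    else:
        msk = as_tensor(0.0)

    if weights.delta > 0:
        if kF_mm is None or kM_mm is None:
            raise ValueError("delta > 0 requires paired keypoints")
        field_like = TensorField(ut, spacing, origin)
        kp = keypoint_loss(field_like, kF_mm, kM_mm, base_field=base_field)
    else:
        kp = as_tensor(0.0)

    total = dist + weights.alpha * curv + weights.gamma * vcc \
        + weights.beta * msk + weights.delta * kp
    breakdown = LossBreakdown(total=float(total.value),
                              distance=float(dist.value),
                              curvature=float(curv.value),
                              vcc=float(vcc.value),
                              mask=float(msk.value),
                              keypoint=float(kp.value))
    if return_tensor:
        return total, breakdown
    return breakdown
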