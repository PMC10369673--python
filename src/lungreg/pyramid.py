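"""Gaussian-pyramid construction and the coarse-to-fine multilevel driver.

Registration starts on the coarsest level, where fixed and moving images have
been Gaussian-smoothed and downsampled by 2^(L-1).  On every finer level the
deformations of all preceding levels, combined by functional composition, are
used as the initial guess: the moving image is warped at full resolution with
the composed field, then both images are downsampled to the current level and
the level solver estimates a residual displacement, which is prolonged and
composed into the running field.

The barrier parameter of the volume-change penalty starts at t on the
coarsest level and is halved per finer level (barrier raising); the keypoint
weight is zero on the coarsest level so it can focus on coarse alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .fields import (DisplacementField, ImageVolume, LabelVolume, OneHotMask,
                     compose, identity_field, prolong, warp_image, warp_label,
                     jacobian_determinant)
from .losses import LossWeights

__all__ = ["MultilevelPlan", "LevelSpec", "RegistrationAux", "LevelProblem",
           "RegistrationResult", "gaussian_downsample", "multilevel_register"]


@dataclass
class LevelSpec:
    """Settings for one pyramid level (factor 2^(level-1); level 1 = finest)."""

    level: int
    factor: int
    weights: LossWeights
    iterations: int = 100


@dataclass
class MultilevelPlan:
    """Coarse-to-fine schedule: per-level factors, weights and budgets."""

    levels: list  # LevelSpec, coarsest first

    def __post_init__(self):
        if len(self.levels) < 1:
            raise ValueError("plan needs at least one level")

    @property
    def num_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def default(cls, num_levels: int = 3, weights: LossWeights | None = None,
                t_coarsest: float = 0.2, iterations=(400, 200, 100),
                delta_fine: float | None = None) -> "MultilevelPlan":
        """Reference schedule: t halved per finer level, keypoint weight zero
        on the coarsest level, iteration budgets coarse to fine."""
        base = weights or LossWeights()
        if delta_fine is None:
            delta_fine = base.delta
        if len(iterations) < num_levels:
            iterations = tuple(iterations) + (iterations[-1],) * (
                num_levels - len(iterations))
        levels = []
        for i in range(num_levels):           # i=0 coarsest
            level = num_levels - i            # pyramid level number, finest=1
            t_i = t_coarsest / (2 ** i)
            delta_i = 0.0 if (i == 0 and num_levels > 1) else delta_fine
            w = replace(base, t=t_i, delta=delta_i)
            levels.append(LevelSpec(level=level, factor=2 ** (level - 1),
                                    weights=w, iterations=iterations[i]))
        return cls(levels)


@dataclass
class RegistrationAux:
    """Optional weak supervision: lobe masks and paired keypoints (mm)."""

    lobes_F: LabelVolume | None = None
    lobes_M: LabelVolume | None = None
    kF_mm: np.ndarray | None = None
    kM_mm: np.ndarray | None = None


@dataclass
class LevelProblem:
    """Everything a level solver sees: level-resolution images, masks,
    keypoints and the frozen composition of the coarser levels."""

    F: ImageVolume
    M: ImageVolume
    weights: LossWeights
    iterations: int
    level: int
    bF: OneHotMask | None = None
    bM: OneHotMask | None = None
    ngf_mask: LabelVolume | None = None
    kF_mm: np.ndarray | None = None
    kM_mm: np.ndarray | None = None
    base_field: DisplacementField | None = None


@dataclass
class RegistrationResult:
    field: DisplacementField
    level_fields: list
    history: list                    # per level: list of LossBreakdown
    folding_fraction: float
    det_stats: dict


def gaussian_downsample(I: ImageVolume, factor: int) -> ImageVolume:
    """Smooth (sigma = 1 voxel per halving) and subsample by 2 per step."""
    if factor < 1 or (factor & (factor - 1)) != 0:
        raise ValueError("factor must be a power of two")
    data = I.data
    spacing = I.spacing.copy()
    f = factor
    while f > 1:
        if any(s % 2 for s in data.shape):
            raise ValueError(f"shape {data.shape} not divisible by 2")
        data = gaussian_filter(data, sigma=1.0, mode="nearest")
        data = data[::2, ::2, ::2]
        spacing = spacing * 2
        f //= 2
    return ImageVolume(data.copy(), spacing, I.origin.copy())


def _subsample_label(L: LabelVolume, factor: int) -> LabelVolume:
    return LabelVolume(L.data[::factor, ::factor, ::factor].copy(),
                       L.spacing * factor, L.origin.copy())


def _prolong_to(u: DisplacementField, target_shape) -> DisplacementField:
    out = u
    while tuple(out.shape) != tuple(target_shape):
        nxt = tuple(min(2 * s, t) for s, t in zip(out.shape, target_shape))
        out = prolong(out, nxt)
    return out


def multilevel_register(F: ImageVolume, M: ImageVolume,
                        solver,
                        plan: MultilevelPlan,
                        aux: RegistrationAux | None = None) -> RegistrationResult:
    """Run the coarse-to-fine scheme with a per-level solver.

    ``solver`` is called as ``solver(problem: LevelProblem) -> (u_level,
    history)`` where ``u_level`` is a [3, D, H, W] displacement in voxel units
    of the level grid.  Warping of the moving image happens at the highest
    resolution before each level is built.
    """
    if not F.same_grid(M):
        raise ValueError("fixed and moving image must share a grid")
    aux = aux or RegistrationAux()
    for spec in plan.levels:
        w = spec.weights
        if w.beta > 0 and (aux.lobes_F is None or aux.lobes_M is None):
            raise ValueError(f"level {spec.level}: beta > 0 requires lobe masks")
        if w.delta > 0 and (aux.kF_mm is None or aux.kM_mm is None):
            raise ValueError(f"level {spec.level}: delta > 0 requires keypoints")
        for s, f in zip(F.shape, (spec.factor,) * 3):
            if s % f:
                raise ValueError(f"shape {F.shape} not divisible by factor {f}")

    y_total = identity_field(F.shape, F.spacing, F.origin)
    level_fields = []
    history = []
    k = None
    if aux.lobes_F is not None and aux.lobes_M is not None:
        k = max(aux.lobes_F.k, aux.lobes_M.k)

    for spec in plan.levels:
        f = spec.factor
        # warp moving data at full resolution with the composed field so far
        Mw_full = warp_image(M, y_total)
        F_l = gaussian_downsample(F, f)
        M_l = gaussian_downsample(Mw_full, f)

        bF_l = bM_l = ngf_mask_l = None
        if aux.lobes_F is not None:
            lobes_F_l = _subsample_label(aux.lobes_F, f)
            ngf_mask_l = lobes_F_l
            if spec.weights.beta > 0 and aux.lobes_M is not None:
                lobes_Mw = warp_label(aux.lobes_M, y_total)
                lobes_M_l = _subsample_label(lobes_Mw, f)
                bF_l = lobes_F_l.to_onehot(k)
                bM_l = lobes_M_l.to_onehot(k)

        base = None
        if spec.weights.delta > 0 and np.any(y_total.data):
            base = y_total

        problem = LevelProblem(F=F_l, M=M_l, weights=spec.weights,
                               iterations=spec.iterations, level=spec.level,
                               bF=bF_l, bM=bM_l, ngf_mask=ngf_mask_l,
                               kF_mm=aux.kF_mm, kM_mm=aux.kM_mm,
                               base_field=base)
        try:
            u_l, hist = solver(problem)
        except Exception as exc:
            raise RuntimeError(f"solver failed at level {spec.level}") from exc
        u_l = np.asarray(u_l, dtype=np.float64)
        if u_l.shape != (3,) + F_l.shape:
            raise ValueError(f"solver returned shape {u_l.shape} at level {spec.level}")
        y_l = DisplacementField(u_l, F_l.spacing, F_l.origin, level=spec.level)
        level_fields.append(y_l)
        history.append(hist)

        y_l_full = _prolong_to(y_l, F.shape)
        y_l_full = DisplacementField(y_l_full.data, F.spacing, F.origin,
                                     level=spec.level)
        # new total: coarse-so-far applied after this level's refinement
        y_total = compose(y_total, y_l_full)

    det = jacobian_determinant(y_total).data
    folding = float((det <= 0).mean())
    det_stats = {"min": float(det.min()), "max": float(det.max()),
                 "mean": float(det.mean())}
    return RegistrationResult(field=y_total, level_fields=level_fields,
                              history=history, folding_fraction=folding,
                              det_stats=det_stats)
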