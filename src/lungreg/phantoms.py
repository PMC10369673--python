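"""Seeded lung-like synthetic phantoms with known ground-truth deformations.

A phantom emulates the features the registration method actually relies on:

* an ellipsoidal "lung" subdivided into five smooth lobe-like compartments
  (nearest-seed partition under a smoothly warped metric),
* thin bright tubular structures (vessel analogues, radius 1-3 voxels)
  crossing the compartments,
* paired keypoints placed on the tubes,
* an inhale/exhale pair related by a known smooth fold-free deformation,
  with a multiplicative intensity shift plus noise on the "exhale" image to
  defeat the intensity-constancy assumption (as breathing alters tissue
  density in CT).

Intensities are arbitrary units chosen CT-like in contrast ordering
(background ~0, parenchyma ~100, vessels ~300).  Role assignment avoids field
inversion: the fixed image is the *deformed* copy, F(x) = I(x + u(x)), so that
with M = I the pairing M(y_true(x)) = F(x) and kM = y_true(kF) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .fields import (DisplacementField, ImageVolume, LabelVolume,
                     displace_points, warp_image, warp_label)
from . import _diffops as dops

__all__ = ["PhantomPair", "make_phantom", "make_true_field", "deform_phantom",
           "make_pair"]

BACKGROUND_LEVEL = 0.0
PARENCHYMA_LEVEL = 100.0
TUBE_LEVEL = 300.0

#: default study conditions for the recovery experiments
DEFAULT_SHAPE = (64, 64, 64)
DEFAULT_MAX_DISP = 8.0
DEFAULT_INTENSITY_SHIFT = 0.8
DEFAULT_NOISE_SD = 2.0
N_LOBES = 5


@dataclass
class PhantomPair:
    """Fixed/moving pair with lobes, paired keypoints and the true field."""

    F: ImageVolume
    M: ImageVolume
    lobes_F: LabelVolume
    lobes_M: LabelVolume
    kF_mm: np.ndarray
    kM_mm: np.ndarray
    y_true: DisplacementField
    seed: int


def make_phantom(shape=DEFAULT_SHAPE, seed: int = 0, n_tubes: int = 20,
                 n_keypoints: int = 50, spacing=(1.0, 1.0, 1.0)):
    """Generate (image, lobes, keypoints_mm); deterministic per seed."""
    shape = tuple(int(s) for s in shape)
    if min(shape) < 16:
        raise ValueError("shape too small to hold five lobe compartments")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(spacing, dtype=np.float64)
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                                indexing="ij"))
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.38

    # ellipsoidal lung region
    q = sum(((grid[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    lung = q <= 1.0

    # five lobes: nearest of five seeds under a smoothly warped metric
    seeds = center + (rng.uniform(-0.55, 0.55, size=(N_LOBES, 3)) * semi)
    warp = np.stack([gaussian_filter(rng.normal(0, 1, shape), 6.0) for _ in range(3)])
    warp *= 3.0 / (np.abs(warp).max() + 1e-12)
    coords = grid + warp
    d2 = np.stack([sum((coords[a] - seeds[i, a]) ** 2 for a in range(3))
                   for i in range(N_LOBES)])
    lobes = np.where(lung, np.argmin(d2, axis=0) + 1, 0).astype(np.int32)

    # parenchyma with smooth texture
    texture = gaussian_filter(rng.normal(0, 1, shape), 2.0)
    texture *= 30.0 / (np.abs(texture).max() + 1e-12)
    img = np.where(lung, PARENCHYMA_LEVEL + texture, BACKGROUND_LEVEL)

    # bright tubes crossing compartments, with centerline bookkeeping
    centerline_pts = []
    tube_mask = np.zeros(shape, dtype=bool)
    idx_grid = grid
    for _ in range(n_tubes):
        p0 = center + rng.uniform(-0.8, 0.8, 3) * semi
        direction = rng.normal(0, 1, 3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(0.4, 1.0) * min(shape) * 0.6
        radius = rng.uniform(1.0, 3.0)
        n_steps = int(length)
        for s in np.linspace(0, length, max(n_steps, 2)):
            p = p0 + s * direction
            if np.any(p < 1) or np.any(p >= np.asarray(shape) - 1):
                break
            lo = np.maximum(np.floor(p - radius - 1), 0).astype(int)
            hi = np.minimum(np.ceil(p + radius + 2), shape).astype(int)
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            d2loc = sum((idx_grid[a][sl] - p[a]) ** 2 for a in range(3))
            tube_mask[sl] |= d2loc <= radius ** 2
            if lung[tuple(np.round(p).astype(int))]:
                centerline_pts.append(p)
    img = np.where(tube_mask, TUBE_LEVEL, img)

    if len(centerline_pts) < n_keypoints:
        raise RuntimeError("not enough tube centerline points for keypoints")
    pick = rng.choice(len(centerline_pts), size=n_keypoints, replace=False)
    kp_vox = np.asarray(centerline_pts)[np.sort(pick)]
    kp_mm = kp_vox * spacing

    image = ImageVolume(img, spacing)
    labels = LabelVolume(lobes, spacing)
    return image, labels, kp_mm


def make_true_field(shape=DEFAULT_SHAPE, max_disp_voxels: float = DEFAULT_MAX_DISP,
                    smoothness: float = 8.0, seed: int = 0,
                    spacing=(1.0, 1.0, 1.0), max_tries: int = 20) -> DisplacementField:
    """Smooth random fold-free field with max displacement magnitude
    ``max_disp_voxels`` (within rescaling exactness) and min det > 0.1."""
    if max_disp_voxels < 0:
        raise ValueError("max_disp_voxels must be >= 0")
    shape = tuple(int(s) for s in shape)
    if max_disp_voxels == 0:
        return DisplacementField(np.zeros((3,) + shape), spacing)
    # cosine taper to zero near the boundary (applied to the noise before
    # smoothing, so it does not add gradient of its own) keeps warped
    # structures inside the domain
    win = np.ones(shape)
    for ax, s in enumerate(shape):
        ramp = np.clip(np.minimum(np.arange(s), np.arange(s)[::-1]) / (0.25 * s),
                       0, 1)
        w = 0.5 - 0.5 * np.cos(np.pi * ramp)
        sh = [1, 1, 1]
        sh[ax] = s
        win = win * w.reshape(sh)
    for trial in range(max_tries):
        rng = np.random.default_rng([seed, trial])
        u = np.stack([gaussian_filter(rng.normal(0, 1, shape) * win, smoothness)
                      for _ in range(3)])
        mag = np.sqrt((u ** 2).sum(0)).max()
        if mag == 0:
            continue
        u *= max_disp_voxels / mag
        det = dops.jacobian_det(u).value
        if det.min() > 0.1:
            return DisplacementField(u, spacing)
    raise RuntimeError("could not generate a fold-free field; "
                       "reduce max_disp_voxels or increase smoothness")


def deform_phantom(image: ImageVolume, lobes: LabelVolume, keypoints_mm,
                   y_true: DisplacementField,
                   intensity_shift: float = DEFAULT_INTENSITY_SHIFT,
                   noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0,
                   n_keypoints: int | None = None) -> PhantomPair:
    """Build the registration pair from a phantom and a true deformation.

    F is the deformed copy of the phantom, M the original with a
    multiplicative intensity shift and additive Gaussian noise; fixed
    keypoints are re-detected on the tubes of F and their moving partners are
    kM = y_true(kF), exact by construction.
    """
    if tuple(image.shape) != tuple(y_true.shape):
        raise ValueError("phantom and field grids differ")
    rng = np.random.default_rng(seed)
    F = warp_image(image, y_true)
    lobes_F = warp_label(lobes, y_true)
    lobes_M = lobes

    # fixed keypoints on the tubes of F (bright voxels inside the lung)
    n_kp = len(np.asarray(keypoints_mm)) if n_keypoints is None else n_keypoints
    tube_vox = np.argwhere((F.data > 0.9 * TUBE_LEVEL) & (lobes_F.data > 0))
    if len(tube_vox) < n_kp:
        raise RuntimeError("not enough tube voxels in the deformed image")
    pick = rng.choice(len(tube_vox), size=n_kp, replace=False)
    kF_mm = tube_vox[np.sort(pick)].astype(np.float64) * F.spacing
    kM_mm = displace_points(y_true, kF_mm)

    M_data = intensity_shift * image.data
    if noise_sd > 0:
        M_data = M_data + rng.normal(0, noise_sd, image.shape)
    M = ImageVolume(M_data, image.spacing.copy(), image.origin.copy())
    return PhantomPair(F=F, M=M, lobes_F=lobes_F, lobes_M=lobes_M,
                       kF_mm=kF_mm, kM_mm=kM_mm, y_true=y_true, seed=seed)


def make_pair(shape=DEFAULT_SHAPE, seed: int = 0,
              max_disp_voxels: float = DEFAULT_MAX_DISP,
              smoothness: float = 8.0,
              intensity_shift: float = DEFAULT_INTENSITY_SHIFT,
              noise_sd: float = DEFAULT_NOISE_SD,
              n_keypoints: int = 50) -> PhantomPair:
    """Convenience: phantom + true field + deformation in one seeded call."""
    image, lobes, kp = make_phantom(shape, seed=seed, n_keypoints=n_keypoints)
    y_true = make_true_field(shape, max_disp_voxels, smoothness, seed=seed + 1)
    return deform_phantom(image, lobes, kp, y_true,
                          intensity_shift=intensity_shift, noise_sd=noise_sd,
                          seed=seed + 2, n_keypoints=n_keypoints)
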