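"""Registration evaluation metrics: label overlap (Dice), surface distances
(average symmetric surface distance, symmetric Hausdorff distance), landmark
target registration error, and Jacobian/folding statistics.

Surfaces are the 6-connected boundary voxels of a label, located at voxel
centers in mm; no subvoxel meshing is performed.  Percentiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .fields import DisplacementField, JacobianMap, LabelVolume, displace_points

__all__ = ["MetricsReport", "dice", "asd", "hausdorff", "tre", "folding_stats",
           "evaluate_labels", "dice30"]


@dataclass
class MetricsReport:
    """Flat summary of overlap, surface-distance, TRE and folding metrics."""

    dice_per_label: dict = dc_field(default_factory=dict)
    dice_mean: float = float("nan")
    asd_per_label: dict = dc_field(default_factory=dict)
    asd_mean: float = float("nan")
    hd_per_label: dict = dc_field(default_factory=dict)
    hd_mean: float = float("nan")
    tre_stats: dict = dc_field(default_factory=dict)
    folding_fraction: float = float("nan")
    det_histogram: dict = dc_field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "dice_per_label": {str(k): v for k, v in self.dice_per_label.items()},
            "dice_mean": self.dice_mean,
            "asd_per_label": {str(k): v for k, v in self.asd_per_label.items()},
            "asd_mean": self.asd_mean,
            "hd_per_label": {str(k): v for k, v in self.hd_per_label.items()},
            "hd_mean": self.hd_mean,
            "tre_stats": self.tre_stats,
            "folding_fraction": self.folding_fraction,
            "det_histogram": self.det_histogram,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def to_csv(self, path):
        rows = [("metric", "label", "value")]
        for lab, v in self.dice_per_label.items():
            rows.append(("dice", str(lab), f"{v:.6f}"))
        rows.append(("dice", "mean", f"{self.dice_mean:.6f}"))
        for lab, v in self.asd_per_label.items():
            rows.append(("asd_mm", str(lab), f"{v:.6f}"))
        rows.append(("asd_mm", "mean", f"{self.asd_mean:.6f}"))
        for lab, v in self.hd_per_label.items():
            rows.append(("hd_mm", str(lab), f"{v:.6f}"))
        rows.append(("hd_mm", "mean", f"{self.hd_mean:.6f}"))
        for k, v in self.tre_stats.items():
            rows.append(("tre_mm", k, f"{v:.6f}"))
        rows.append(("folding_fraction", "", f"{self.folding_fraction:.8f}"))
        with open(path, "w") as fh:
            fh.write("\n".join(",".join(r) for r in rows) + "\n")


def _check_grids(X: LabelVolume, Y: LabelVolume):
    if not X.same_grid(Y):
        raise ValueError("label volumes must share a grid")


def dice(X: LabelVolume, Y: LabelVolume, label: int) -> float:
    """Dice overlap 2|X∩Y| / (|X|+|Y|) for one label."""
    _check_grids(X, Y)
    x = X.data == label
    y = Y.data == label
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 and ny == 0:
        warnings.warn(f"label {label} absent in both volumes; Dice defined as 1",
                      stacklevel=2)
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def _surface_points_mm(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """6-connected boundary voxel centers in mm."""
    struct = generate_binary_structure(3, 1)
    interior = binary_erosion(mask, structure=struct, border_value=0)
    surf = mask & ~interior
    idx = np.argwhere(surf)
    return idx * spacing


def asd(X: LabelVolume, Y: LabelVolume, label: int) -> float:
    """Average symmetric surface distance in mm:
    (sum_x d(x, Ys) + sum_y d(y, Xs)) / (|Xs| + |Ys|)."""
    _check_grids(X, Y)
    xs = _surface_points_mm(X.data == label, X.spacing)
    ys = _surface_points_mm(Y.data == label, Y.spacing)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError(f"label {label} empty in one of the volumes")
    d_xy = cKDTree(ys).query(xs)[0]
    d_yx = cKDTree(xs).query(ys)[0]
    return float((d_xy.sum() + d_yx.sum()) / (len(xs) + len(ys)))


def hausdorff(X: LabelVolume, Y: LabelVolume, label: int) -> float:
    """Symmetric Hausdorff distance of the label surfaces in mm."""
    _check_grids(X, Y)
    xs = _surface_points_mm(X.data == label, X.spacing)
    ys = _surface_points_mm(Y.data == label, Y.spacing)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError(f"label {label} empty in one of the volumes")
    d_xy = cKDTree(ys).query(xs)[0].max()
    d_yx = cKDTree(xs).query(ys)[0].max()
    return float(max(d_xy, d_yx))


def tre(u: DisplacementField, kF_mm: np.ndarray, kM_mm: np.ndarray,
        percentiles=(25, 50, 75, 95)) -> dict:
    """Target registration error statistics (mm): Euclidean distances between
    the moving keypoints and the displaced fixed keypoints y(k_F)."""
    kF_mm = np.asarray(kF_mm, dtype=np.float64)
    kM_mm = np.asarray(kM_mm, dtype=np.float64)
    if kF_mm.shape != kM_mm.shape or kF_mm.ndim != 2:
        raise ValueError("tre requires paired (N,3) keypoint arrays")
    yk = displace_points(u, kF_mm)
    d = np.linalg.norm(yk - kM_mm, axis=1)
    stats = {"mean": float(d.mean()), "sd": float(d.std()),
             "max": float(d.max()), "n": int(len(d))}
    for p in percentiles:
        stats[f"p{p}"] = float(np.percentile(d, p))
    return stats


def folding_stats(det: JacobianMap | np.ndarray, mask: np.ndarray | None = None,
                  bins: int = 32):
    """Fraction of (masked) voxels with det <= 0 and a determinant histogram."""
    d = det.data if isinstance(det, JacobianMap) else np.asarray(det)
    if mask is not None:
        d = d[np.asarray(mask) > 0]
    frac = float((d <= 0).mean())
    counts, edges = np.histogram(d, bins=bins)
    return frac, {"counts": counts.tolist(), "edges": edges.tolist()}


def dice30(per_case_dice) -> float:
    """Robustness summary: mean Dice over the worst 30% of cases."""
    arr = np.sort(np.asarray(per_case_dice, dtype=np.float64))
    n = max(1, int(np.ceil(0.3 * len(arr))))
    return float(arr[:n].mean())


def evaluate_labels(X: LabelVolume, Y: LabelVolume,
                    labels=None) -> MetricsReport:
    """Dice/ASD/HD for every (foreground) label plus means."""
    if labels is None:
        labels = sorted(set(np.unique(X.data)) | set(np.unique(Y.data)))
        labels = [int(l) for l in labels if l > 0]
    rep = MetricsReport()
    for lab in labels:
        rep.dice_per_label[lab] = dice(X, Y, lab)
        rep.asd_per_label[lab] = asd(X, Y, lab)
        rep.hd_per_label[lab] = hausdorff(X, Y, lab)
    rep.dice_mean = float(np.mean(list(rep.dice_per_label.values())))
    rep.asd_mean = float(np.mean(list(rep.asd_per_label.values())))
    rep.hd_mean = float(np.mean(list(rep.hd_per_label.values())))
    return rep
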