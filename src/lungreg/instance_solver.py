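"""Direct per-pair ("instance") optimization of the registration loss.

Instead of training a network, the displacement field itself is treated as
the free variable and minimized with first-order adaptive-moment gradient
steps.  This exercises every loss term on a single pair at desk scale and is
the reference solver for the multilevel driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor
from .losses import total_loss
from .pyramid import LevelProblem

__all__ = ["SolverConfig", "InstanceSolver", "optimize_field"]


@dataclass
class SolverConfig:
    iterations: int = 100
    lr: float = 0.01           # step size on voxel-unit displacements
    tol: float = 0.0           # relative loss-change convergence tolerance
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.tol < 0:
            raise ValueError("tolerance must be >= 0")


def optimize_field(problem: LevelProblem, config: SolverConfig):
    """Minimize the total loss over the level displacement field.

    Starts from u = 0, returns the best-loss iterate (robust to step-size
    overshoot) together with the per-iteration loss breakdown history.
    The running minimum of the history is non-increasing by construction.
    """
    F, M, w = problem.F, problem.M, problem.weights
    u = Tensor(np.zeros((3,) + F.shape), requires_grad=True)
    opt = Adam([u], lr=config.lr)
    best_u = u.value.copy()
    best_loss = np.inf
    history = []
    prev = None
    n_iter = problem.iterations or config.iterations
    for it in range(n_iter):
        opt.zero_grad()
        tot, breakdown = total_loss(
            F, M, u, w, bF=problem.bF, bM=problem.bM,
            kF_mm=problem.kF_mm, kM_mm=problem.kM_mm,
            ngf_mask=problem.ngf_mask, base_field=problem.base_field,
            return_tensor=True)
        if not np.isfinite(tot.value):
            bad = max(breakdown.as_dict().items(), key=lambda kv: abs(kv[1]))
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: worst term {bad[0]}={bad[1]}")
        history.append(breakdown)
        if breakdown.total < best_loss:
            best_loss = breakdown.total
            best_u = u.value.copy()
        tot.backward()
        if not np.all(np.isfinite(u.grad)):
            raise FloatingPointError(f"non-finite gradient at iteration {it}")
        opt.step()
        if prev is not None and config.tol > 0:
            rel = abs(prev - breakdown.total) / max(abs(prev), 1e-12)
            if rel < config.tol:
                break
        prev = breakdown.total
    return best_u, history


class InstanceSolver:
    """Level-solver adapter for :func:`lungreg.pyramid.multilevel_register`."""

    def __init__(self, config: SolverConfig | None = None):
        self.config = config or SolverConfig()

    def __call__(self, problem: LevelProblem):
        return optimize_field(problem, self.config)
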