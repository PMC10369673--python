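"""Displacement-regression U-Net and the progressive multilevel training.

The model takes the 2-channel concatenation of fixed and (coarse-warped)
moving image and regresses a dense 3-component displacement field at input
resolution.  Encoder stages apply 3x3x3 convolutions, each followed by
instance normalization and a rectifier, with 2x2x2 average pooling (stride 2)
between resolutions; decoder stages upsample with 2x2x2 transposed
convolutions carrying half the filters and concatenate the encoder skip; a
1x1x1 convolution maps the final features to three displacement components.

Levels are trained progressively, coarsest first with the keypoint weight at
zero; each finer network starts from the previous level's parameters and the
frozen coarser networks only supply the initial composed deformation.
Inference consumes images only — masks and keypoints are training inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .fields import ImageVolume
from .losses import total_loss
from .pyramid import (LevelProblem, MultilevelPlan, RegistrationAux,
                      RegistrationResult, multilevel_register)

__all__ = ["NetworkSpec", "TrainConfig", "UNet3D", "build_model",
           "train_progressive", "predict", "save_checkpoint", "load_checkpoint"]


@dataclass
class NetworkSpec:
    depth: int = 3           # encoder/decoder resolutions
    base_filters: int = 16   # first-layer filters, doubled per downsampling
    in_channels: int = 2
    out_channels: int = 3


@dataclass
class TrainConfig:
    epochs: int = 25
    lr: float = 1e-3
    seed: int = 0
    batch_size: int = 1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _xavier(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class UNet3D:
    """Parameterized displacement regressor (see module docstring)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        f = spec.base_filters
        d = spec.depth
        chans = [spec.in_channels] + [f * 2 ** i for i in range(d)]
        # encoder: two 3x3x3 convs per resolution
        for i in range(d):
            cin, cout = chans[i], chans[i + 1]
            self._add_conv(rng, f"enc{i}a", cin, cout)
            self._add_conv(rng, f"enc{i}b", cout, cout)
        # decoder: transposed conv (half filters) + one conv after skip concat
        for i in range(d - 2, -1, -1):
            cup = chans[i + 2]               # channels entering the upsample
            half = cup // 2
            self._add_convT(rng, f"up{i}", cup, half)
            self._add_conv(rng, f"dec{i}", half + chans[i + 1], chans[i + 1])
        # head: pointwise map to displacement components
        self.params["head_w"] = Tensor(
            _xavier(rng, (spec.out_channels, chans[1]), chans[1], spec.out_channels),
            requires_grad=True)
        self.params["head_b"] = Tensor(np.zeros(spec.out_channels),
                                       requires_grad=True)

    def _add_conv(self, rng, name, cin, cout):
        self.params[f"{name}_w"] = Tensor(
            _xavier(rng, (cout, cin, 3, 3, 3), cin * 27, cout * 27),
            requires_grad=True)
        self.params[f"{name}_b"] = Tensor(np.zeros(cout), requires_grad=True)

    def _add_convT(self, rng, name, cin, cout):
        self.params[f"{name}_w"] = Tensor(
            _xavier(rng, (cin, cout, 2, 2, 2), cin * 8, cout * 8),
            requires_grad=True)
        self.params[f"{name}_b"] = Tensor(np.zeros(cout), requires_grad=True)

    # -- forward -----------------------------------------------------------
    def forward(self, F_data: np.ndarray, M_data: np.ndarray) -> Tensor:
        """(F, M) -> displacement Tensor [3, D, H, W] (voxel units)."""
        shape = F_data.shape
        if any(s % 2 ** self.spec.depth for s in shape):
            raise ValueError(
                f"input shape {shape} not divisible by 2^depth={2**self.spec.depth}")
        p = self.params
        x = ad.concatenate([ad.as_tensor(F_data[None]), ad.as_tensor(M_data[None])],
                           axis=0)
        skips = []
        for i in range(self.spec.depth):
            x = ad.instance_norm(ad.conv3d(x, p[f"enc{i}a_w"], p[f"enc{i}a_b"])).relu()
            x = ad.instance_norm(ad.conv3d(x, p[f"enc{i}b_w"], p[f"enc{i}b_b"])).relu()
            skips.append(x)
            if i < self.spec.depth - 1:
                x = ad.avg_pool2(x)
        for i in range(self.spec.depth - 2, -1, -1):
            x = ad.conv_transpose2(x, p[f"up{i}_w"], p[f"up{i}_b"])
            x = ad.concatenate([x, skips[i]], axis=0)
            x = ad.instance_norm(ad.conv3d(x, p[f"dec{i}_w"], p[f"dec{i}_b"])).relu()
        return ad.conv1x1(x, p["head_w"], p["head_b"])

    __call__ = forward

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        return list(self.params.values())

    def state_dict(self) -> dict:
        return {k: v.value.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict):
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k}")
            if self.params[k].value.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            self.params[k].value = np.asarray(v, dtype=np.float64).copy()

    def zero_head(self):
        """Zero the final layer so the model outputs the identity field."""
        self.params["head_w"].value[:] = 0.0
        self.params["head_b"].value[:] = 0.0


def build_model(spec: NetworkSpec, seed: int = 0) -> UNet3D:
    """Deterministic Xavier-uniform-initialized model for one level."""
    return UNet3D(spec, seed=seed)


class NetworkSolver:
    """Adapter: a frozen trained model as a multilevel level solver."""

    def __init__(self, models: dict):
        self.models = models  # level number -> UNet3D

    def __call__(self, problem: LevelProblem):
        model = self.models.get(problem.level)
        if model is None:
            raise KeyError(f"no trained model for level {problem.level}")
        u = model.forward(problem.F.data, problem.M.data)
        return u.value, []


def _level_training_problems(pair, plan: MultilevelPlan, upto_index: int,
                             frozen: dict):
    """Build the training problem of level index ``upto_index`` for one pair,
    recomputing the coarse initial guess with the frozen coarser models."""
    from .pyramid import multilevel_register  # frozen coarse pass

    aux = RegistrationAux(pair.lobes_F, pair.lobes_M, pair.kF_mm, pair.kM_mm)
    captured = {}

    def capture_solver(problem: LevelProblem):
        spec_level = problem.level
        if spec_level in frozen:
            u = frozen[spec_level].forward(problem.F.data, problem.M.data)
            return u.value, []
        captured["problem"] = problem
        # stop composing here: return zeros for the level under training
        return np.zeros((3,) + problem.F.shape), []

    sub = MultilevelPlan(plan.levels[:upto_index + 1])
    multilevel_register(pair.F, pair.M, capture_solver, sub, aux)
    return captured["problem"]


def train_progressive(dataset, plan: MultilevelPlan, spec: NetworkSpec,
                      config: TrainConfig, verbose: bool = False):
    """Train one network per pyramid level, coarsest first.

    Every pair in ``dataset`` must carry lobe masks and keypoints (weak
    supervision is a training-time input only).  Returns ``(models, logs)``
    where models maps level number -> trained UNet3D and logs holds the
    per-epoch mean loss breakdown per level.
    """
    models: dict[int, UNet3D] = {}
    logs = []
    prev_state = None
    for li, level_spec in enumerate(plan.levels):
        model = build_model(spec, seed=config.seed + li)
        if prev_state is not None:
            model.load_state_dict(prev_state)
        opt = Adam(model.parameters(), lr=config.lr)
        level_log = []
        for epoch in range(config.epochs):
            epoch_terms = []
            for pair in dataset:
                problem = _level_training_problems(pair, plan, li, models)
                w = level_spec.weights
                u = model.forward(problem.F.data, problem.M.data)
                tot, breakdown = total_loss(
                    problem.F, problem.M, u, w, bF=problem.bF, bM=problem.bM,
                    kF_mm=problem.kF_mm if w.delta > 0 else None,
                    kM_mm=problem.kM_mm if w.delta > 0 else None,
                    ngf_mask=problem.ngf_mask, base_field=problem.base_field,
                    return_tensor=True)
                if not np.isfinite(tot.value):
                    bad = max(breakdown.as_dict().items(),
                              key=lambda kv: abs(kv[1]))
                    raise FloatingPointError(
                        f"non-finite training loss (level {level_spec.level}, "
                        f"epoch {epoch}): worst term {bad[0]}={bad[1]}")
                opt.zero_grad()
                tot.backward()
                opt.step()
                epoch_terms.append(breakdown)
            mean_total = float(np.mean([b.total for b in epoch_terms]))
            level_log.append({"epoch": epoch, "mean_total": mean_total,
                              "terms": epoch_terms})
            if verbose:
                print(f"level {level_spec.level} epoch {epoch}: {mean_total:.5f}")
        models[level_spec.level] = model
        prev_state = model.state_dict()
        logs.append(level_log)
    return models, logs


def predict(models: dict, F: ImageVolume, M: ImageVolume,
            plan: MultilevelPlan) -> RegistrationResult:
    """Multilevel inference with frozen models; images only, no supervision."""
    for level_spec in plan.levels:
        if level_spec.level not in models:
            raise KeyError(f"missing model for level {level_spec.level}")
    from dataclasses import replace as dc_replace
    # inference never evaluates the loss: strip supervision requirements
    bare_levels = [
        dc_replace(ls, weights=dc_replace(ls.weights, beta=0.0, delta=0.0))
        for ls in plan.levels
    ]
    return multilevel_register(F, M, NetworkSolver(models),
                               MultilevelPlan(bare_levels), aux=None)


def save_checkpoint(path, models: dict, spec: NetworkSpec, seed: int,
                    plan: MultilevelPlan | None = None):
    """Single-file checkpoint: parameters of every level + spec metadata."""
    arrays = {}
    for level, model in models.items():
        for k, v in model.state_dict().items():
            arrays[f"level{level}/{k}"] = v
    meta = {"depth": spec.depth, "base_filters": spec.base_filters,
            "in_channels": spec.in_channels, "out_channels": spec.out_channels,
            "seed": seed, "levels": sorted(models)}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        spec = NetworkSpec(depth=meta["depth"], base_filters=meta["base_filters"],
                           in_channels=meta["in_channels"],
                           out_channels=meta["out_channels"])
        models = {}
        for level in meta["levels"]:
            model = build_model(spec, seed=meta["seed"])
            state = {k.split("/", 1)[1]: data[k] for k in data.files
                     if k.startswith(f"level{level}/")}
            model.load_state_dict(state)
            models[level] = model
    return models, spec, meta
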