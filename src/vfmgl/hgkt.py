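"""Stage 1 — heterogeneous-model general knowledge transfer (HGKT).

A large frozen vision-transformer teacher and a small convolutional student
produce features at different granularities; HGKT builds the full bipartite
set of teacher-block × student-stage transfer channels and *learns where to
transfer*: a small meta-network emits a non-negative transfer weight per
channel, updated by a first-order one-step-lookahead scheme so that weights
grow where transfer helps held-out task performance and shrink where it
hurts (negative-transfer suppression).  Student layers that accumulate the
most transfer-weight mass are the robustness-critical layers; they are
frozen before the federated stage so the general knowledge they encode
survives later updates.

Raw transfer weights are free non-negative magnitudes (so the overall
transfer strength can decay to zero against an unhelpful teacher); the
per-student-layer *normalized* view is a probability vector and is what
criticality scoring and the serialized plan report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import ArrayDataset, make_batches
from .model_zoo import FeatureBundle, ModelSpec, extract_features
from .nn import Tensor, no_grad
from .nn.functional import cross_entropy, soft_dice_loss

__all__ = ["TransferPlan", "LayerCriticality", "MetaNet", "enumerate_pairs",
           "align_features", "transfer_loss", "meta_update_weights",
           "stage1_train", "score_and_freeze", "Stage1Config"]

_SOFTPLUS0 = np.log(2.0)


class MetaNet(nn.Module):
    """Two-layer perceptron mapping per-pair statistics to a raw weight.

    Inputs per pair: mean |teacher activation|, mean |student activation|,
    task-loss EMA.  Output passes through softplus and is scaled so the
    zero-initialized head yields exactly the uniform weight 1/|teacher
    layers| — the documented starting point.
    """

    def __init__(self, n_teacher_layers: int, seed: int = 42, hidden: int = 16):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(3, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)
        self.fc2.weight.data[:] = 0.0  # uniform start
        self.fc2.bias.data[:] = 0.0
        self.scale = 1.0 / (n_teacher_layers * _SOFTPLUS0)

    def forward(self, stats: Tensor) -> Tensor:
        z = self.fc2(self.fc1(stats).relu()).reshape(-1)
        softplus = (1.0 + z.exp()).log()
        return softplus * self.scale


@dataclass
class TransferPlan:
    """Candidate teacher→student layer pairs with learned transfer weights."""

    pairs: list[tuple[str, str]]
    weights: np.ndarray                       # raw non-negative, one per pair
    teacher_layers: list[str]
    student_layers: list[str]
    meta: MetaNet | None = None
    projectors: dict[int, nn.Parameter] = field(default_factory=dict)
    task_loss_ema: float = 0.0
    _stats: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("transfer weights must be non-negative")

    def pairs_into(self, student_layer: str) -> list[int]:
        return [i for i, (_, s) in enumerate(self.pairs) if s == student_layer]

    def normalized_weights(self) -> np.ndarray:
        """Per-student-layer probability vector over teacher candidates."""
        out = np.zeros_like(self.weights)
        for s in self.student_layers:
            idx = self.pairs_into(s)
            tot = self.weights[idx].sum()
            out[idx] = (self.weights[idx] / tot if tot > 0
                        else 1.0 / len(idx))
        return out

    def layer_mass(self) -> dict[str, float]:
        return {s: float(self.weights[self.pairs_into(s)].sum())
                for s in self.student_layers}

    def to_json(self, criticality: "LayerCriticality | None" = None) -> str:
        norm = self.normalized_weights()
        doc = {
            "pairs": [{"teacher": t, "student": s,
                       "weight": float(self.weights[i]),
                       "normalized_weight": float(norm[i])}
                      for i, (t, s) in enumerate(self.pairs)],
            "teacher_layers": self.teacher_layers,
            "student_layers": self.student_layers,
        }
        if criticality is not None:
            doc["criticality"] = criticality.scores
            doc["frozen"] = criticality.frozen
        return json.dumps(doc, indent=2)


@dataclass
class LayerCriticality:
    """Normalized transfer-weight mass per student layer + freeze flags."""

    scores: dict[str, float]
    frozen: dict[str, bool]

    def frozen_layers(self) -> list[str]:
        return [k for k, v in self.frozen.items() if v]


def enumerate_pairs(teacher: ModelSpec, student: ModelSpec) -> TransferPlan:
    """Full bipartite candidate set with uniform initial weights 1/|T|."""
    if not teacher.layer_names or not student.layer_names:
        raise ValueError("both specs need at least one hookable layer")
    pairs = [(t, s) for s in student.layer_names for t in teacher.layer_names]
    w0 = 1.0 / len(teacher.layer_names)
    return TransferPlan(pairs=pairs,
                        weights=np.full(len(pairs), w0),
                        teacher_layers=list(teacher.layer_names),
                        student_layers=list(student.layer_names))


def align_features(teacher_feats: FeatureBundle, pair: tuple[str, str],
                   projector: nn.Parameter,
                   out_shape: tuple[int, int, int]) -> Tensor:
    """Map a token matrix onto a student feature map's (C, h, w) geometry.

    Tokens (class token excluded) are reshaped to their (dim, gh, gw) grid,
    projected to the student channel count by a learnable 1×1 map, then
    bilinearly resized.  Gradients flow only into the projector — teacher
    features arrive detached.
    """
    if teacher_feats.grid is None:
        raise ValueError("teacher features carry no grid shape")
    gh, gw = teacher_feats.grid
    tok = teacher_feats.spatial_tokens(pair[0]).detach()
    n, n_tok, dim = tok.shape
    if n_tok != gh * gw:
        raise ValueError(f"token/grid mismatch: {n_tok} vs {gh}x{gw}")
    grid = tok.transpose(0, 2, 1).reshape(n, dim, gh, gw)
    projected = grid.conv2d(projector)
    c, h, w = out_shape
    return projected.bilinear_resize(h, w)


def _channel_norm(x: Tensor, rel_eps: float = 1e-5) -> Tensor:
    """Zero-mean/unit-variance per channel over (batch, h, w).

    The stabilizer is relative to the mean channel variance, so the
    normalization — and hence the transfer loss — is exactly invariant to a
    common positive rescaling of the map."""
    mu = x.mean(axis=(0, 2, 3), keepdims=True)
    var = x.var(axis=(0, 2, 3), keepdims=True)
    vbar = var.mean()
    return (x - mu) / (var + rel_eps * vbar + 1e-300).sqrt()


def _ensure_projectors(plan: TransferPlan, student_feats: FeatureBundle,
                       teacher_feats: FeatureBundle, seed: int = 42) -> None:
    rng = np.random.default_rng(seed)
    dim = next(iter(teacher_feats.features.values())).shape[-1]
    for i, (_, s) in enumerate(plan.pairs):
        if i not in plan.projectors:
            c = student_feats.features[s].shape[1]
            plan.projectors[i] = nn.Parameter(
                rng.normal(0, np.sqrt(1.0 / dim), (c, dim, 1, 1)))


def per_pair_losses(student_feats: FeatureBundle,
                    teacher_feats: FeatureBundle,
                    plan: TransferPlan) -> list[Tensor]:
    """Channel-normalized MSE of each transfer channel (unweighted)."""
    _ensure_projectors(plan, student_feats, teacher_feats)
    losses = []
    for i, (t, s) in enumerate(plan.pairs):
        smap = student_feats.features[s]
        if np.any(~np.isfinite(smap.data)):
            raise FloatingPointError(f"NaN in student features at {s}")
        aligned = align_features(teacher_feats, (t, s), plan.projectors[i],
                                 smap.shape[1:])
        d = _channel_norm(smap) - _channel_norm(aligned)
        losses.append((d * d).mean())
    return losses


def transfer_loss(student_feats: FeatureBundle, teacher_feats: FeatureBundle,
                  plan: TransferPlan) -> Tensor:
    """Σ_pairs weight · channel-normalized MSE; ≥ 0, zero iff every
    positively weighted channel matches exactly after normalization."""
    losses = per_pair_losses(student_feats, teacher_feats, plan)
    total = Tensor(0.0)
    for w, lp in zip(plan.weights, losses):
        if w != 0.0:
            total = total + float(w) * lp
    return total


def _pair_stats(plan: TransferPlan, student_feats: FeatureBundle,
                teacher_feats: FeatureBundle) -> np.ndarray:
    stats = np.zeros((len(plan.pairs), 3))
    with no_grad():
        t_abs = {t: float(np.abs(f.data).mean())
                 for t, f in teacher_feats.features.items()}
        s_abs = {s: float(np.abs(f.data).mean())
                 for s, f in student_feats.features.items()}
    for i, (t, s) in enumerate(plan.pairs):
        stats[i] = (t_abs[t], s_abs[s], plan.task_loss_ema)
    return stats


def _task_loss(model, images: np.ndarray, targets: np.ndarray) -> Tensor:
    if model.spec.task == "classification":
        return cross_entropy(model(Tensor(images)), targets)
    return soft_dice_loss(model(Tensor(images)), targets)


def refresh_weights(plan: TransferPlan) -> None:
    """Recompute raw weights from the meta-network on the cached stats."""
    if plan.meta is None or plan._stats is None:
        return
    with_grad = plan.meta(Tensor(plan._stats))
    plan.weights = with_grad.data.copy()


def meta_update_weights(plan: TransferPlan, student, teacher,
                        task_batch: tuple, lr_meta: float = 0.001,
                        inner_lr: float = 0.01,
                        transfer_coef: float = 1.0) -> TransferPlan:
    """One first-order bilevel step on the transfer weights.

    Simulates a student step on (task + transfer) loss, measures the task
    loss on a held-out mini-batch at the looked-ahead parameters, and pushes
    that validation signal into the meta-network: the gradient of the
    validation loss w.r.t. pair weight w_p is −lr·(∇L_val · ∇L_p), with the
    per-pair directional derivatives obtained by central finite differences
    along the validation-gradient direction (all pairs share two extra
    forward passes).  Meta parameters follow SGD with the configured
    learning rate, weight decay 0.001 and momentum 0.9; raw weights are then
    re-emitted by the meta-network.
    """
    tr_x, tr_y, va_x, va_y = task_batch
    if plan.meta is None:
        plan.meta = MetaNet(len(plan.teacher_layers))
    if lr_meta == 0.0:
        return plan

    params = dict(student.named_parameters())
    theta = {n: p.data.copy() for n, p in params.items()}
    buffers = {n: b.copy() for n, b in student.named_buffers()}

    # inner step on task + weighted transfer loss
    student.zero_grad()
    t_feats = extract_features(teacher, tr_x)
    s_feats = student.forward_features(Tensor(tr_x))
    task = _task_loss(student, tr_x, tr_y)
    total = task + transfer_coef * transfer_loss(s_feats, t_feats, plan)
    total.backward()
    if not all(np.all(np.isfinite(p.grad)) for p in params.values()
               if p.grad is not None):
        raise FloatingPointError("non-finite gradients in meta lookahead")
    for p in params.values():
        if p.grad is not None:
            p.data = p.data - inner_lr * p.grad

    # validation gradient at the looked-ahead parameters
    student.zero_grad()
    _task_loss(student, va_x, va_y).backward()
    g_val = {n: (p.grad.copy() if p.grad is not None else np.zeros_like(p.data))
             for n, p in params.items()}
    gnorm = np.sqrt(sum(float((g * g).sum()) for g in g_val.values()))
    for n, p in params.items():
        p.data = theta[n]
    if gnorm == 0.0:
        student.load_state_dict(buffers)
        return plan

    # directional derivatives of every per-pair loss along g_val/|g_val|
    eps = 1e-3
    def pair_losses_at(shift: float) -> np.ndarray:
        for n, p in params.items():
            p.data = theta[n] + shift * g_val[n] / gnorm
        with no_grad():
            sf = student.forward_features(Tensor(tr_x))
            vals = [lp.item() for lp in per_pair_losses(sf, t_feats, plan)]
        return np.array(vals)

    d_pairs = (pair_losses_at(eps) - pair_losses_at(-eps)) / (2 * eps) * gnorm
    for n, p in params.items():
        p.data = theta[n]
    student.load_state_dict(buffers)  # a meta step must not touch the student
    dL_dw = -inner_lr * transfer_coef * d_pairs

    # push into the meta-network and refresh the weights
    stats = _pair_stats(plan, s_feats, t_feats)
    plan._stats = stats
    plan.meta.zero_grad()
    w_out = plan.meta(Tensor(stats))
    (w_out * Tensor(dL_dw)).sum().backward()
    opt = getattr(plan, "_meta_opt", None)
    if opt is None:
        opt = nn.SGD(dict(plan.meta.named_parameters()), lr=lr_meta,
                     momentum=0.9, weight_decay=0.001)
        object.__setattr__(plan, "_meta_opt", opt)
    opt.step()
    refresh_weights(plan)
    return plan


@dataclass
class Stage1Config:
    epochs: int = 3
    lr: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 8
    optimizer: str = "sgd"
    transfer_coef: float = 1.0
    lr_meta: float = 0.001
    meta_every: int = 2          # meta step every k-th batch
    seed: int = 42


def stage1_train(dataset: ArrayDataset, teacher, student,
                 plan: TransferPlan, config: Stage1Config = Stage1Config()
                 ) -> tuple[object, TransferPlan, list[float]]:
    """Alternate student steps on task+transfer loss with meta weight
    updates; deterministic under the config seed.  Returns the trained
    student, the final plan, and per-epoch mean training loss."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    if plan.meta is None:
        plan.meta = MetaNet(len(plan.teacher_layers), seed=config.seed)
    named = dict(student.named_parameters())
    if config.optimizer == "adam":
        opt = nn.Adam(named, lr=config.lr, weight_decay=config.weight_decay)
    else:
        opt = nn.SGD(named, lr=config.lr, momentum=config.momentum,
                     weight_decay=config.weight_decay)
    history = []
    for _ in range(config.epochs):
        batches = make_batches(dataset, config.batch_size, rng)
        epoch_losses = []
        for k, batch in enumerate(batches):
            opt.zero_grad()
            t_feats = extract_features(teacher, batch.images)
            s_feats = student.forward_features(Tensor(batch.images))
            task = _task_loss(student, batch.images, batch.targets)
            loss = task + config.transfer_coef * transfer_loss(
                s_feats, t_feats, plan)
            loss.backward()
            opt.step()
            epoch_losses.append(task.item())
            plan.task_loss_ema = 0.9 * plan.task_loss_ema + 0.1 * task.item()
            if config.lr_meta > 0 and (k + 1) % config.meta_every == 0:
                val = batches[(k + 1) % len(batches)]
                meta_update_weights(plan, student, teacher,
                                    (batch.images, batch.targets,
                                     val.images, val.targets),
                                    lr_meta=config.lr_meta,
                                    inner_lr=config.lr,
                                    transfer_coef=config.transfer_coef)
        history.append(float(np.mean(epoch_losses)))
    return student, plan, history


def score_and_freeze(plan: TransferPlan, top_fraction: float = 0.5
                     ) -> LayerCriticality:
    """Criticality = share of total transfer-weight mass received by each
    student layer; the top fraction of layers by score is frozen (ties
    toward the earlier layer)."""
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    mass = plan.layer_mass()
    total = sum(mass.values())
    n = len(plan.student_layers)
    if total > 0:
        scores = {k: v / total for k, v in mass.items()}
    else:
        scores = {k: 1.0 / n for k in mass}
    n_freeze = max(1, int(round(top_fraction * n)))
    order = sorted(range(n),
                   key=lambda i: (-scores[plan.student_layers[i]], i))
    chosen = {plan.student_layers[i] for i in order[:n_freeze]}
    return LayerCriticality(scores=scores,
                            frozen={k: k in chosen
                                    for k in plan.student_layers})
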