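"""Stage 2 — batch-level data deduction (DDBL) and logit distillation (KD).

Each communication round a center scores random batches of its private data
by how far its local model's prediction distribution has drifted from the
shared model's (per-sample-averaged KL divergence on temperature-softened
outputs).  High-divergence batches carry the center's idiosyncratic
heterogeneity; training continues only on the low-heterogeneity remainder,
with a distillation term that pulls the non-frozen parameters of the local
model toward the shared model's softened logits — common knowledge flows
in, center-specific shortcuts are suppressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import ArrayDataset, Batch, make_batches
from .nn import Tensor, no_grad
from .nn.functional import (cross_entropy, kl_divergence, log_softmax,
                            soft_dice_loss, softmax)

__all__ = ["BatchHeterogeneityScore", "Stage2Config", "score_batches",
           "select_low_heterogeneity", "kd_loss", "stage2_train"]


@dataclass
class BatchHeterogeneityScore:
    batch_id: int
    divergence: float            # mean KL(local ‖ shared), softened outputs
    divergence_rate: float = 0.0  # change vs the previous scoring pass
    selected: bool = False


@dataclass
class Stage2Config:
    epochs: int = 1
    lr: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 8
    optimizer: str = "sgd"
    temperature: float = 2.0
    alpha: float = 0.5
    keep_fraction: float = 0.7
    seed: int = 42


def _soft_probs(model, images: np.ndarray, temperature: float) -> np.ndarray:
    """Softened prediction distributions, (N, C) or (N, 2, H, W) pixelwise."""
    with no_grad():
        logits = model(Tensor(images))
        if model.spec.task == "classification":
            return softmax(logits * (1.0 / temperature)).data
        p = (logits * (1.0 / temperature)).sigmoid().data
        return np.stack([1.0 - p[:, 0], p[:, 0]], axis=1)


def _mean_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Mean over samples (and pixels) of KL(p ‖ q); class axis is axis 1."""
    eps = 1e-12
    kl = (p * (np.log(p + eps) - np.log(q + eps))).sum(axis=1)
    return float(kl.mean())


def score_batches(local, shared, batches: list[Batch],
                  temperature: float = 2.0,
                  previous: list[BatchHeterogeneityScore] | None = None
                  ) -> list[BatchHeterogeneityScore]:
    """Per-batch divergence between local and shared prediction
    distributions; the rate field tracks the change since the previous
    scoring pass of the same batches."""
    prev = {s.batch_id: s.divergence for s in previous} if previous else {}
    modes = [(m, m.training) for m in (local, shared)]
    local.eval()
    shared.eval()  # deterministic scoring: running statistics, no dropout
    try:
        out = []
        for b in batches:
            p = _soft_probs(local, b.images, temperature)
            q = _soft_probs(shared, b.images, temperature)
            _check_normalized(p)
            _check_normalized(q)
            d = _mean_kl(p, q)
            rate = d - prev.get(b.batch_id, d)
            out.append(BatchHeterogeneityScore(b.batch_id, d, rate))
    finally:
        for m, mode in modes:
            m.train(mode)
    return out


def _check_normalized(p: np.ndarray, tol: float = 1e-6) -> None:
    s = p.sum(axis=1)
    if not np.allclose(s, 1.0, atol=tol):
        raise ValueError("prediction distributions are not normalized")


def select_low_heterogeneity(scores: list[BatchHeterogeneityScore],
                             keep_fraction: float) -> list[int]:
    """Lowest-divergence batches; ties broken by |divergence rate| then id."""
    if not scores:
        raise ValueError("empty score list")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    n_keep = max(1, math.ceil(keep_fraction * len(scores)))
    ranked = sorted(scores, key=lambda s: (s.divergence,
                                           abs(s.divergence_rate),
                                           s.batch_id))
    chosen = {s.batch_id for s in ranked[:n_keep]}
    for s in scores:
        s.selected = s.batch_id in chosen
    return sorted(chosen)


def kd_loss(student_logits: Tensor, shared_logits: Tensor,
            targets: np.ndarray, T: float = 2.0, alpha: float = 0.5,
            task: str = "classification") -> Tensor:
    """α·task loss + (1−α)·T²·KL(soft shared ‖ soft student).

    Task loss is cross-entropy for classification, soft Dice for
    segmentation (where distillation is applied pixelwise on the foreground
    Bernoulli distribution).
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if student_logits.shape != shared_logits.shape:
        raise ValueError("logit shape mismatch")
    if task == "classification":
        task_term = cross_entropy(student_logits, targets)
        p_shared = softmax(shared_logits.detach() * (1.0 / T))
        log_q = log_softmax(student_logits * (1.0 / T))
        distill = kl_divergence(p_shared, log_q)
    else:
        task_term = soft_dice_loss(student_logits, targets)
        ps = (shared_logits.detach() * (1.0 / T)).sigmoid()
        qs = (student_logits * (1.0 / T)).sigmoid()
        eps = 1e-12
        distill = (ps * ((ps + eps).log() - (qs + eps).log())
                   + (1.0 - ps) * ((1.0 - ps + eps).log()
                                   - (1.0 - qs + eps).log())).mean()
    return alpha * task_term + (1.0 - alpha) * (T * T) * distill


def stage2_train(local, shared, dataset: ArrayDataset,
                 frozen_prefixes: frozenset[str] | set[str],
                 config: Stage2Config = Stage2Config(),
                 previous_scores: list[BatchHeterogeneityScore] | None = None
                 ) -> tuple[object, list[BatchHeterogeneityScore], list[float]]:
    """One local-training pass: score → select → distill on selected batches.

    Only non-frozen parameters are updated (a fully frozen model still has
    its loss evaluated and logged); the returned score list is the round's
    audit record (divergence, rate, selected flag per batch).
    """
    # fixed sequential batches: identities must be stable across rounds
    # for divergence-rate tracking, and acquisition order keeps correlated
    # corruption (e.g. a bad scanner period) within few batches
    batches = make_batches(dataset, config.batch_size)
    if config.keep_fraction * len(batches) < 1.0:
        raise ValueError("keep_fraction leaves no batches; raise it or "
                         "use more data")
    scores = score_batches(local, shared, batches, config.temperature,
                           previous_scores)
    selected = select_low_heterogeneity(scores, config.keep_fraction)
    keep = [b for b in batches if b.batch_id in set(selected)]

    named = dict(local.named_parameters())
    if config.optimizer == "adam":
        opt = nn.Adam(named, lr=config.lr, weight_decay=config.weight_decay,
                      frozen=frozen_prefixes)
    else:
        opt = nn.SGD(named, lr=config.lr, momentum=config.momentum,
                     weight_decay=config.weight_decay, frozen=frozen_prefixes)
    trainable = bool(opt.params)
    losses: list[float] = []
    for _ in range(config.epochs):
        for b in keep:
            with no_grad():
                shared_logits = shared(Tensor(b.images))
            if not trainable:
                with no_grad():
                    loss = kd_loss(local(Tensor(b.images)), shared_logits,
                                   b.targets, config.temperature,
                                   config.alpha, local.spec.task)
                losses.append(loss.item())
                continue
            opt.zero_grad()
            loss = kd_loss(local(Tensor(b.images)), shared_logits, b.targets,
                           config.temperature, config.alpha, local.spec.task)
            loss.backward()
            opt.step()
            losses.append(loss.item())
    return local, scores, losses
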