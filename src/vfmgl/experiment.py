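"""End-to-end experiment drivers.

``run_experiment`` chains simulate-data → Stage 1 (HGKT + freezing) →
Stage 2 (federated DDBL+KD rounds) → evaluation → artifacts on disk.
The canned drivers reproduce the framework's three headline behaviours at
desk scale: the ablation ordering (HGKT → +KD → +KD+DDBL), planted-outlier
batch exclusion by DDBL, and negative-transfer suppression by the
meta-learned transfer weights.
"""

from __future__ import annotations

import copy
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig, save_config
from .data import ArrayDataset, Batch
from .ddbl_kd import (BatchHeterogeneityScore, Stage2Config, score_batches,
                      select_low_heterogeneity, stage2_train)
from .evaluation import (ScoredPredictions, cross_center_matrix,
                         evaluate_classifier, youden_cutoff)
from .federated import ClientState, SharedState, aggregate, run_round
from .hgkt import (Stage1Config, enumerate_pairs, score_and_freeze,
                   stage1_train)
from .model_zoo import ModelSpec, build_model, recalibrate_bn
from .synthetic import (CenterEffect, ObjectModel, SyntheticConfig,
                        generate_classification_center, generate_federation)

__all__ = ["default_effects", "federation_config", "train_stage1_centers",
           "run_federated_rounds", "run_experiment", "run_ablation",
           "robustness_sweep", "planted_outlier_experiment",
           "negative_transfer_experiment"]


def default_effects(n_centers: int, strength: float = 1.0,
                    artifact_prob: float = 0.1,
                    jitter: float | None = None,
                    artifact_kind: str = "inversion"
                    ) -> tuple[CenterEffect, ...]:
    """Deterministic per-center acquisition signatures spanning the effect
    families: graded intensity/contrast shifts, alternating blur, small
    channel rotations, mild noise, per-image protocol jitter, and a
    fraction of extreme-artifact acquisitions (shifted away from the
    center's own bias so they never saturate)."""
    shifts = np.linspace(-0.15, 0.15, n_centers) * strength
    gains = np.linspace(0.8, 1.25, n_centers) ** strength
    blurs = [0.0 if i % 2 == 0 else 0.6 * strength for i in range(n_centers)]
    rots = np.linspace(-0.15, 0.15, n_centers) * strength
    return tuple(CenterEffect(intensity_shift=float(s),
                              contrast_gain=float(g),
                              color_rotation=(float(r), 0.0, 0.0),
                              noise_sigma=0.02,
                              resolution_blur=float(b),
                              intensity_jitter=(0.08 * strength
                                                if jitter is None else jitter),
                              artifact_prob=artifact_prob,
                              artifact_shift=float(-np.sign(s) * 0.35
                                                   if s != 0 else 0.35),
                              artifact_kind=artifact_kind)
                 for s, g, b, r in zip(shifts, gains, blurs, rots))


def federation_config(cfg: ExperimentConfig) -> SyntheticConfig:
    return SyntheticConfig(
        task=cfg.task, n_centers=cfg.n_centers, n_samples=cfg.n_samples,
        prevalence=cfg.prevalence, image_size=cfg.image_size,
        effects=default_effects(cfg.n_centers, cfg.effect_strength,
                                artifact_prob=cfg.artifact_prob),
        split_ratios=cfg.split_ratios, seed=cfg.seed,
        distinct_centers=True)


def _student_spec(cfg: ExperimentConfig) -> ModelSpec:
    family = "residual-18" if cfg.task == "classification" else "u-shaped"
    n_out = 2 if cfg.task == "classification" else 1
    return ModelSpec(cfg.task, family, (cfg.image_size, cfg.image_size, 3),
                     n_out, width=cfg.student_width)


def _teacher_spec(cfg: ExperimentConfig) -> ModelSpec:
    size = 224 if cfg.teacher_family == "vit-b-14" else cfg.image_size
    return ModelSpec("classification", cfg.teacher_family, (size, size, 3), 2)


def train_stage1_centers(cfg: ExperimentConfig, federation: dict,
                         teacher=None) -> dict[str, dict]:
    """Stage 1 for every center: HGKT training + criticality freezing.

    Returns {center_id: {model, plan, criticality, history}}.
    """
    teacher = teacher or build_model(_teacher_spec(cfg), seed=cfg.seed)
    out = {}
    for i, (cid, entry) in enumerate(federation.items()):
        # common initialization across centers: parameter averaging in
        # stage 2 is only meaningful for clients sharing an origin
        student = build_model(_student_spec(cfg), seed=cfg.seed)
        plan = enumerate_pairs(teacher.spec, student.spec)
        s1 = replace(cfg.stage1, seed=cfg.stage1.seed + i)
        student, plan, history = stage1_train(entry["train"], teacher,
                                              student, plan, s1)
        crit = score_and_freeze(plan, cfg.top_fraction)
        out[cid] = {"model": student, "plan": plan, "criticality": crit,
                    "history": history}
    return out


def run_federated_rounds(cfg: ExperimentConfig, federation: dict,
                         stage1: dict, rounds: int | None = None,
                         keep_fraction: float | None = None,
                         log: list | None = None
                         ) -> tuple[list[ClientState], SharedState]:
    """Stage 2: build clients from Stage-1 results and run the rounds."""
    clients = []
    for i, (cid, entry) in enumerate(federation.items()):
        s2 = replace(cfg.stage2, seed=cfg.stage2.seed + i)
        if keep_fraction is not None:
            s2 = replace(s2, keep_fraction=keep_fraction)
        clients.append(ClientState(
            center_id=cid, model=stage1[cid]["model"],
            train_data=entry["train"],
            frozen_layers=tuple(stage1[cid]["criticality"].frozen_layers()),
            config=s2))
    shared = aggregate([c.parameters_message() for c in clients],
                       [c.n_train for c in clients])
    factory = lambda: build_model(_student_spec(cfg), seed=cfg.seed)
    for _ in range(rounds if rounds is not None else cfg.rounds):
        clients, shared = run_round(clients, shared, factory, log)
    return clients, shared


def _test_sets(federation: dict) -> dict[str, ArrayDataset]:
    return {cid: entry["test"] for cid, entry in federation.items()}


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Full pipeline; artifacts land in out_dir/<name>-<confighash>/."""
    out = Path(cfg.out_dir) / f"{cfg.name}-{cfg.config_hash()}"
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    federation = generate_federation(federation_config(cfg))
    stage1 = train_stage1_centers(cfg, federation)
    for cid, s in stage1.items():
        (out / f"plan_{cid}.json").write_text(
            s["plan"].to_json(s["criticality"]))
    log: list = []
    clients, shared = run_federated_rounds(cfg, federation, stage1, log=log)
    pd.DataFrame([{"center_id": e["center_id"], "round": e["round"],
                   "n_train": e["n_train"]} for e in log]).to_csv(
        out / "rounds.csv", index=False)
    sel_rows = []
    for c in clients:
        for s in (c.last_scores or []):
            sel_rows.append({"center": c.center_id, "batch_id": s.batch_id,
                             "divergence": s.divergence,
                             "selected": s.selected})
    pd.DataFrame(sel_rows).to_csv(out / "selection.csv", index=False)
    metric = "auc" if cfg.task == "classification" else "dice"
    models = {}
    for c in clients:
        recalibrate_bn(c.model, c.train_data.images)
        models[c.center_id] = c.model.eval()
    matrix = cross_center_matrix(models, _test_sets(federation), metric)
    matrix.to_csv(out / "cross_center.csv")
    summary = {"metric": metric,
               "cross_center_mean": float(matrix.values.mean()),
               "per_center": {c: float(matrix.loc[c, c]) for c in matrix.index}}
    (out / "metrics.json").write_text(json.dumps(summary, indent=2))
    return out


def ablation_study_config(seed: int) -> ExperimentConfig:
    """The canned three-arm ablation study conditions.

    Three centers of 80 samples at 32×32 with the default acquisition
    signatures plus a 20 % clustered decision-corrupting artifact run per
    center; a gentle Stage 1 (3 epochs, lr 0.005) so clients stay close to
    their common origin, a quarter of the stages frozen, and 6
    communication rounds at lr 0.02 with three local passes per round —
    enough local drift for the heterogeneity statistic to be informative
    at this scale.
    """
    return ExperimentConfig(
        n_centers=3, n_samples=80, image_size=32, student_width=4,
        split_ratios=(0.5, 0.5), top_fraction=0.25, artifact_prob=0.2,
        rounds=6, seed=seed,
        stage1=Stage1Config(epochs=3, lr=0.005, batch_size=8, seed=seed),
        stage2=Stage2Config(epochs=3, lr=0.02, batch_size=8, seed=seed))


def clean_test_federation(cfg: ExperimentConfig) -> dict[str, ArrayDataset]:
    """Quality-controlled evaluation data: the same centers' acquisition
    signatures without artifact acquisitions (clinical enrollment excludes
    poor-quality images), drawn as an independent cohort."""
    clean = replace(cfg, artifact_prob=0.0, seed=cfg.seed + 500_000)
    federation = generate_federation(federation_config(clean))
    return _test_sets(federation)


def run_ablation_study(seed: int) -> dict[str, float]:
    """One seed of the canned ablation: arms trained on federations whose
    training streams contain clustered artifact acquisitions, evaluated on
    quality-controlled test cohorts."""
    cfg = ablation_study_config(seed)
    return run_ablation(cfg, rounds=cfg.rounds,
                        test_sets=clean_test_federation(cfg))


def run_ablation(cfg: ExperimentConfig, rounds: int = 2,
                 test_sets: dict[str, ArrayDataset] | None = None
                 ) -> dict[str, float]:
    """The three-arm ablation: HGKT alone, +KD, +KD+DDBL.

    Stage 1 runs once; the federated arms reuse deep copies of its models.
    Returns the cross-center mean metric per arm.  ``test_sets`` overrides
    the federation's own test splits (e.g. quality-controlled evaluation
    data, as clinical studies enforce via image-quality exclusion
    criteria).
    """
    federation = generate_federation(federation_config(cfg))
    stage1 = train_stage1_centers(cfg, federation)
    metric = "auc" if cfg.task == "classification" else "dice"
    tests = test_sets if test_sets is not None else _test_sets(federation)

    def snapshot():
        snap = {}
        for cid, s in stage1.items():
            model = build_model(_student_spec(cfg))
            model.load_state_dict(s["model"].state_dict())
            snap[cid] = {**s, "model": model}
        return snap

    def evaluate(models_by_center):
        for cid, m in models_by_center.items():
            recalibrate_bn(m, federation[cid]["train"].images)
            m.eval()
        return float(cross_center_matrix(models_by_center, tests,
                                         metric).values.mean())

    results = {}
    results["hgkt"] = evaluate({cid: s["model"]
                                for cid, s in snapshot().items()})
    for arm, keep in (("hgkt_kd", 1.0), ("hgkt_kd_ddbl", None)):
        clients, _ = run_federated_rounds(cfg, federation, snapshot(),
                                          rounds=rounds, keep_fraction=keep)
        results[arm] = evaluate({c.center_id: c.model for c in clients})
    return results


def robustness_sweep(cfg: ExperimentConfig, seeds: list[int]
                     ) -> pd.DataFrame:
    """Repeat the experiment across seeds; per-center metric mean ± sd."""
    rows = []
    for seed in seeds:
        c = replace(cfg, seed=seed,
                    stage1=replace(cfg.stage1, seed=seed),
                    stage2=replace(cfg.stage2, seed=seed))
        federation = generate_federation(federation_config(c))
        stage1 = train_stage1_centers(c, federation)
        clients, _ = run_federated_rounds(c, federation, stage1)
        metric = "auc" if c.task == "classification" else "dice"
        models = {}
        for cl in clients:
            recalibrate_bn(cl.model, cl.train_data.images)
            models[cl.center_id] = cl.model.eval()
        matrix = cross_center_matrix(models, _test_sets(federation), metric)
        for cid in matrix.index:
            rows.append({"seed": seed, "center": cid, "metric": metric,
                         "value": float(matrix.loc[cid, cid])})
    df = pd.DataFrame(rows)
    stats = df.groupby("center")["value"].agg(["mean", "std"]).fillna(0.0)
    return df.merge(stats, on="center")


def _train_cutoff(model, train: ArrayDataset) -> float:
    """Training-set Youden cutoff — the published cutoff selection rule."""
    from .nn import Tensor

    scores = model.predict_proba(Tensor(train.images))[:, 1]
    return youden_cutoff(ScoredPredictions(train.targets, scores))


# --------------------------------------------------------------------------
# canned behavioural experiments
# --------------------------------------------------------------------------

def planted_outlier_experiment(seed: int, n_batches: int = 10,
                               batch_size: int = 8, image_size: int = 64,
                               keep_fraction: float = 0.8,
                               n_rounds: int = 2, warmup_rounds: int = 6,
                               local_epochs: int = 6,
                               outlier_shift: float = 0.4) -> float:
    """Plant extreme-shift batches (10%) in each of 3 centers and measure
    the fraction DDBL excludes after the final round.

    The setup mirrors the conditions the deduction mechanism presumes:
    centers hold distinct patient populations (independent structural
    seeds) with their usual acquisition signatures, and a warm-up phase of
    gentle federated averaging first builds a consensus that fits the
    common data.  The planted batches carry an extreme channel-asymmetric
    intensity shift (one channel +shift, one −shift) — heterogeneity far
    outside the inter-center range that does not wash out the image
    content.  Each scored round then broadcasts the consensus and lets
    every local model fit its own batches until it has memorized them;
    divergence against the consensus concentrates on the planted batches,
    which the selection rule excludes.  Batch membership is fixed so
    planted batches keep their identity across rounds.
    """
    n_centers = 3
    # the planted batches must be the only within-center heterogeneity:
    # no random artifacts and no per-image protocol jitter here
    effects = default_effects(n_centers, artifact_prob=0.0, jitter=0.0)
    n_outlier = max(1, n_batches // 10)
    rng = np.random.default_rng(seed)
    center_batches: dict[str, list[Batch]] = {}
    clean_batches: dict[str, list[Batch]] = {}
    planted: dict[str, set[int]] = {}
    for k in range(n_centers):
        syn = SyntheticConfig(
            task="classification", n_centers=n_centers,
            n_samples=n_batches * batch_size, image_size=image_size,
            effects=effects, split_ratios=(1.0,), seed=seed + 1000 * k)
        ds, _ = generate_classification_center(syn, k)
        cid = f"center_{k}"
        batches = [Batch(b, ds.images[b * batch_size:(b + 1) * batch_size].copy(),
                         ds.targets[b * batch_size:(b + 1) * batch_size])
                   for b in range(n_batches)]
        clean_batches[cid] = [Batch(b.batch_id, b.images.copy(), b.targets)
                              for b in batches]
        ids = rng.choice(n_batches, size=n_outlier, replace=False)
        for b in ids:
            img = batches[b].images.copy()
            img[:, 0] = np.clip(img[:, 0] + outlier_shift, 0.0, 1.0)
            img[:, 2] = np.clip(img[:, 2] - outlier_shift, 0.0, 1.0)
            batches[b].images = img
        center_batches[cid] = batches
        planted[cid] = set(int(i) for i in ids)

    from . import nn
    from .nn import Tensor
    from .nn.functional import cross_entropy

    def local_pass(model, batches, lr, epochs=1):
        opt = nn.SGD(dict(model.named_parameters()), lr=lr, momentum=0.9)
        for _ in range(epochs):
            for b in batches:
                opt.zero_grad()
                cross_entropy(model(Tensor(b.images)), b.targets).backward()
                opt.step()

    spec = ModelSpec("classification", "residual-18",
                     (image_size, image_size, 3), 2, width=4)
    locals_ = {cid: build_model(spec, seed=seed) for cid in center_batches}
    shared_model = build_model(spec, seed=seed)
    shared = aggregate([m.state_dict() for m in locals_.values()],
                       [1.0] * n_centers)
    for _ in range(warmup_rounds):  # consensus building, gentle local steps
        for cid, model in locals_.items():
            model.load_state_dict(shared.params)
            local_pass(model, clean_batches[cid], lr=0.02)
        shared = aggregate([m.state_dict() for m in locals_.values()],
                           [1.0] * n_centers)

    excluded, total = 0, 0
    history: dict[str, list[dict[int, float]]] = {cid: []
                                                  for cid in center_batches}
    selected: dict[str, set[int] | None] = {cid: None
                                            for cid in center_batches}
    for rnd in range(n_rounds):
        shared_model.load_state_dict(shared.params)
        last_round = rnd == n_rounds - 1
        for cid, model in locals_.items():
            model.load_state_dict(shared.params)
            # from round 2 on, train only on the previously selected
            # batches — the pipeline's own behaviour, which also keeps the
            # consensus from re-absorbing the excluded heterogeneity
            train_on = (center_batches[cid] if selected[cid] is None else
                        [b for b in center_batches[cid]
                         if b.batch_id in selected[cid]])
            local_pass(model, train_on, lr=0.05, epochs=local_epochs)
            scores = score_batches(model, shared_model, center_batches[cid])
            history[cid].append({s.batch_id: s.divergence for s in scores})
            # rank by the running mean of divergence over scoring passes,
            # combining the magnitude with its trajectory
            ranked = [BatchHeterogeneityScore(
                s.batch_id,
                float(np.mean([h[s.batch_id] for h in history[cid]])))
                for s in scores]
            kept = set(select_low_heterogeneity(ranked, keep_fraction))
            selected[cid] = kept
            if last_round:
                excluded += len(planted[cid] - kept)
                total += len(planted[cid])
        shared = aggregate([m.state_dict() for m in locals_.values()],
                           [1.0] * n_centers)
    return excluded / total


def negative_transfer_experiment(seed: int, n_train: int = 40,
                                 n_test: int = 24, image_size: int = 32,
                                 epochs: int = 3
                                 ) -> dict[str, float]:
    """Adversarial-teacher toy: a randomly initialized transformer emits
    label-independent features.  Train one student with meta-learned
    transfer weights and one with weights clamped uniform; report test
    accuracy of both and the final mean raw transfer weight."""
    syn = SyntheticConfig(task="classification", n_centers=1,
                          n_samples=n_train + n_test,
                          image_size=image_size, split_ratios=(1.0,),
                          seed=seed,
                          object_model=ObjectModel(texture_contrast=0.3))
    federation = generate_federation(syn)
    ds = next(iter(federation.values()))["train"]
    train = ds.subset(np.arange(n_train))
    test = ds.subset(np.arange(n_train, n_train + n_test))
    teacher = build_model(
        ModelSpec("classification", "tiny-vit",
                  (image_size, image_size, 3), 2), seed=seed + 1)
    spec = ModelSpec("classification", "residual-18",
                     (image_size, image_size, 3), 2, width=4)
    out = {}
    for arm, lr_meta in (("meta", 0.001), ("uniform", 0.0)):
        student = build_model(spec, seed=seed)
        plan = enumerate_pairs(teacher.spec, student.spec)
        cfg1 = Stage1Config(epochs=epochs, lr=0.02, batch_size=8,
                            transfer_coef=2.0, lr_meta=lr_meta, seed=seed)
        student, plan, _ = stage1_train(train, teacher, student, plan, cfg1)
        recalibrate_bn(student, train.images)
        student.eval()
        cutoff = _train_cutoff(student, train)
        rep = evaluate_classifier(student, test, cutoff=cutoff)
        out[f"accuracy_{arm}"] = rep.metrics["accuracy"]
        out[f"mean_weight_{arm}"] = float(np.mean(plan.weights))
    return out
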