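"""Interpretability: class-activation maps, deep-feature matrices, mRMR
selection, and adaptive-vs-common knowledge correlation analysis.

The knowledge analysis applies every center's local model to one common
sample set, producing per-center deep-feature matrices whose rows align.
After mRMR filtering, a feature unit is *adaptive* when it correlates
strongly with other units of the same center's model (center-specific
structure) and *common* when the same unit index correlates strongly
across all centers' models (shared structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ArrayDataset
from .nn import Tensor

__all__ = ["cam", "extract_feature_matrix", "mrmr_select",
           "correlation_analysis", "pca_embed", "save_heatmap",
           "CorrelationReport"]


# --------------------------------------------------------------------------
# class-activation mapping
# --------------------------------------------------------------------------

def cam(model, image: np.ndarray, target: int,
        layer: str | None = None,
        frozen_layers: tuple[str, ...] = ()) -> np.ndarray:
    """Gradient-weighted class-activation heatmap in [0, 1], image-sized.

    Activations of the chosen stage (default: the last non-frozen hookable
    layer) are weighted by the spatially pooled gradient of the target
    logit, rectified, max-normalized and bilinearly upsampled.
    """
    if layer is None:
        candidates = [l for l in model.spec.layer_names
                      if l not in frozen_layers]
        layer = (candidates[-1] if candidates
                 else model.spec.layer_names[-1])
    x = Tensor(np.asarray(image, dtype=np.float64)[None])
    was_training = model.training
    model.eval()  # single image: batch statistics are meaningless
    try:
        logits, feats = model.forward_with_features(x, [layer])
        fmap = feats[layer]
        if model.spec.task == "classification":
            score = logits[0, target]
        else:  # segmentation: mean logit of the target mask channel
            score = logits[0, target].mean()
        model.zero_grad()
        score.backward()
    finally:
        model.train(was_training)
    grads = fmap.grad[0]                      # (C, h, w)
    weights = grads.mean(axis=(1, 2))
    heat = np.maximum((weights[:, None, None] * fmap.data[0]).sum(axis=0), 0.0)
    if heat.max() > 0:
        heat = heat / heat.max()
    h, w = image.shape[-2:]
    return Tensor(heat[None, None]).bilinear_resize(h, w).data[0, 0]


# --------------------------------------------------------------------------
# deep-feature matrices
# --------------------------------------------------------------------------

def extract_feature_matrix(models: dict[str, object],
                           dataset: ArrayDataset,
                           labels: np.ndarray | None = None,
                           chunk: int = 32) -> dict[str, pd.DataFrame]:
    """Penultimate global-pooled activations of each center's model on one
    common sample set; rows align across centers."""
    if labels is None:
        labels = (dataset.targets if dataset.task == "classification"
                  else np.zeros(len(dataset), dtype=int))
    out = {}
    for center, model in models.items():
        rows = []
        from .nn import no_grad
        with no_grad():
            for start in range(0, len(dataset), chunk):
                batch = Tensor(dataset.images[start:start + chunk])
                rows.append(model.penultimate(batch).data)
        feats = np.vstack(rows)
        df = pd.DataFrame(feats,
                          columns=[f"f{i}" for i in range(feats.shape[1])])
        df["center_id"] = center
        df["label"] = np.asarray(labels, dtype=int)
        if df.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        out[center] = df
    return out


# --------------------------------------------------------------------------
# mRMR feature selection
# --------------------------------------------------------------------------

def _discretize(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency binning into at most `bins` levels."""
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI of two discrete variables, natural log."""
    joint = pd.crosstab(a, b).values.astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_select(matrix: pd.DataFrame, k: int = 256,
                target_col: str = "label", bins: int = 10) -> list[str]:
    """Greedy minimum-redundancy / maximum-relevance feature ranking.

    Mutual information on equal-frequency discretized features; the MID
    (difference) criterion relevance − mean redundancy; ties broken by
    lower feature index.  Returns k feature names in selection order.
    """
    feat_cols = [c for c in matrix.columns
                 if c not in (target_col, "center_id")]
    if k > len(feat_cols):
        raise ValueError(f"k={k} exceeds {len(feat_cols)} features")
    y = matrix[target_col].values
    disc = {c: _discretize(matrix[c].values, bins) for c in feat_cols}
    relevance = {c: _mutual_information(disc[c], y) for c in feat_cols}
    selected: list[str] = []
    remaining = list(feat_cols)
    mi_cache: dict[tuple[str, str], float] = {}

    def mi_ff(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = _mutual_information(disc[a], disc[b])
        return mi_cache[key]

    while len(selected) < k:
        best, best_score = None, -np.inf
        for c in remaining:  # iteration order = column order = tie-break
            red = (np.mean([mi_ff(c, s) for s in selected])
                   if selected else 0.0)
            score = relevance[c] - red
            if score > best_score + 1e-12:
                best, best_score = c, score
        selected.append(best)
        remaining.remove(best)
    return selected


# --------------------------------------------------------------------------
# adaptive vs common knowledge
# --------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    adaptive: dict[str, list[str]]     # per center: center-specific features
    common: list[str]                  # features shared across centers
    within: dict[str, pd.DataFrame]    # per-center Pearson matrices
    between: pd.DataFrame              # per-feature min cross-center |r|
    full: pd.DataFrame                 # correlation of all center features
    ordering: list[str] = field(default_factory=list)


def correlation_analysis(matrices: dict[str, pd.DataFrame],
                         class_filter: int | None = None,
                         n_select: int | None = None,
                         n_tag: int | None = None) -> CorrelationReport:
    """Pearson analysis of per-center deep features over common samples.

    Feature units are aligned by penultimate index across centers (all
    centers share the architecture).  A unit's *adaptive* score for a
    center is its maximal |r| against the other units of the same center;
    its *common* score is the minimal |r| of the same unit index across
    all center pairs.  The top ``n_tag`` units per criterion are tagged
    (default: a quarter of the selected features).
    """
    centers = list(matrices)
    if class_filter is not None:
        matrices = {c: m[m["label"] == class_filter] for c, m in
                    matrices.items()}
    lengths = {len(m) for m in matrices.values()}
    if len(lengths) != 1:
        raise ValueError("feature matrices must cover one common sample "
                         "set (label columns must align across centers)")
    feat_cols = [c for c in matrices[centers[0]].columns
                 if c not in ("label", "center_id")]
    if n_select is not None and n_select < len(feat_cols):
        order = mrmr_select(matrices[centers[0]], n_select)
        feat_cols = sorted(order, key=lambda c: feat_cols.index(c))
    n_tag = n_tag or max(1, len(feat_cols) // 4)

    data = {c: matrices[c][feat_cols].values for c in centers}
    within = {}
    adaptive = {}
    for c in centers:
        r = np.atleast_2d(np.corrcoef(data[c], rowvar=False))
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 1.0)
        within[c] = pd.DataFrame(r, index=feat_cols, columns=feat_cols)
        off = np.abs(r - np.eye(len(feat_cols)))
        score = off.max(axis=1)
        top = np.argsort(-score, kind="stable")[:n_tag]
        adaptive[c] = [feat_cols[i] for i in sorted(top)]

    # common: same unit index correlated across center pairs
    n_feat = len(feat_cols)
    min_cross = np.full(n_feat, np.inf)
    for i, a in enumerate(centers):
        for b in centers[i + 1:]:
            for f in range(n_feat):
                xa, xb = data[a][:, f], data[b][:, f]
                if xa.std() == 0 or xb.std() == 0:
                    r = 0.0
                else:
                    r = abs(np.corrcoef(xa, xb)[0, 1])
                min_cross[f] = min(min_cross[f], r)
    if len(centers) < 2:
        min_cross = np.zeros(n_feat)
    between = pd.DataFrame({"feature": feat_cols, "min_cross_r": min_cross})
    top_common = np.argsort(-min_cross, kind="stable")[:n_tag]
    common = [feat_cols[i] for i in sorted(top_common)]

    stacked = np.hstack([data[c] for c in centers])
    names = [f"{c}:{f}" for c in centers for f in feat_cols]
    full_r = np.nan_to_num(np.atleast_2d(np.corrcoef(stacked, rowvar=False)),
                           nan=0.0)
    np.fill_diagonal(full_r, 1.0)
    full = pd.DataFrame(full_r, index=names, columns=names)
    ordering = sorted(names)
    return CorrelationReport(adaptive=adaptive, common=common, within=within,
                             between=between, full=full, ordering=ordering)


def save_heatmap(matrix: pd.DataFrame, path, title: str = "",
                 cmap: str = "coolwarm") -> None:
    """Write a correlation heatmap to a PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap=cmap)
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)))
    ax.set_yticklabels(matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# PCA embedding
# --------------------------------------------------------------------------

def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> np.ndarray:
    """Centered principal-component projection with a fixed sign convention
    (largest-magnitude loading of each component is positive)."""
    from sklearn.decomposition import PCA

    feat_cols = [c for c in matrix.columns if c not in ("label", "center_id")]
    x = matrix[feat_cols].values
    p = PCA(n_components=min(n_components, min(x.shape) - 0))
    coords = p.fit_transform(x)
    for k, load in enumerate(p.components_):
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1.0
    return coords
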