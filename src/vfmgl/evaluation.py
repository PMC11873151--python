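"""Classification/segmentation metrics, ROC/DCA curves, cross-center
matrices, and deduction-based center-similarity model selection.

AUC is the normalized Mann–Whitney U statistic (ties counted half), which
equals the trapezoidal area under the empirical ROC; threshold metrics use
the training-set Youden cutoff when none is supplied; decision-curve net
benefit follows the standard TP/n − FP/n · p_t/(1−p_t) formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

from .data import ArrayDataset, make_batches
from .ddbl_kd import score_batches

__all__ = ["ScoredPredictions", "SegPair", "MetricReport", "auc", "roc_curve",
           "youden_cutoff", "confusion_metrics", "dca_curve", "dice_iou",
           "seg_pixel_metrics", "assd", "cross_center_matrix",
           "center_similarity", "profile_correlation", "evaluate_classifier",
           "evaluate_segmenter"]


@dataclass
class ScoredPredictions:
    y_true: np.ndarray      # {0,1}
    score: np.ndarray       # [0,1] probability of the positive class
    cutoff: float | None = None

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.score = np.asarray(self.score, dtype=float)
        if not np.all(np.isfinite(self.score)):
            raise ValueError("scores must be finite")
        if self.y_true.shape != self.score.shape:
            raise ValueError("label/score length mismatch")


@dataclass
class SegPair:
    pred: np.ndarray
    ref: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        self.pred = np.asarray(self.pred).astype(bool)
        self.ref = np.asarray(self.ref).astype(bool)
        if self.pred.shape != self.ref.shape:
            raise ValueError("mask shape mismatch")


@dataclass
class MetricReport:
    task: str
    metrics: dict[str, float]
    roc: pd.DataFrame | None = None   # fpr, tpr, threshold
    dca: pd.DataFrame | None = None   # threshold, net_benefit, treat_all
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"task": self.task, "metrics": self.metrics}


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def auc(preds: ScoredPredictions) -> float:
    """Mann–Whitney U / (n₊ n₋); ties counted one half."""
    y, s = preds.y_true, preds.score
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined on single-class input")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve(preds: ScoredPredictions) -> pd.DataFrame:
    """Empirical ROC points (fpr, tpr) at every distinct score threshold."""
    y, s = preds.y_true, preds.score
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    n_pos, n_neg = y.sum(), (1 - y).sum()
    return pd.DataFrame({
        "threshold": np.r_[np.inf, s_sorted[distinct]],
        "fpr": np.r_[0.0, fp / max(n_neg, 1)],
        "tpr": np.r_[0.0, tp / max(n_pos, 1)],
    })


def youden_cutoff(preds: ScoredPredictions) -> float:
    """Cutoff maximizing sensitivity + specificity − 1 (training-set rule)."""
    roc = roc_curve(preds)
    j = roc["tpr"] - roc["fpr"]
    best = roc.iloc[int(j.values.argmax())]
    return float(best["threshold"])


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(preds: ScoredPredictions,
                      cutoff: float | None = None) -> dict[str, float]:
    """Sensitivity/specificity/accuracy/PPV/NPV at a cutoff.

    Without an explicit cutoff the stored one is used, else the Youden
    cutoff of these predictions.  Ratios with empty denominators are NaN,
    never silently zero.
    """
    c = cutoff if cutoff is not None else preds.cutoff
    if c is None:
        c = youden_cutoff(preds)
    pred = (preds.score >= c).astype(int)
    y = preds.y_true
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "ppv": _safe_div(tp, tp + fp),
        "npv": _safe_div(tn, tn + fn),
        "cutoff": float(c),
    }


def dca_curve(preds: ScoredPredictions,
              thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Decision-curve analysis: net benefit per threshold probability.

    net benefit = TP/n − FP/n · p_t/(1−p_t); the treat-none reference is
    identically 0, treat-all is prevalence − (1−prevalence)·p_t/(1−p_t).
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    y, s = preds.y_true, preds.score
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt) if pt < 1.0 else np.inf
        pred = s >= pt
        tp = ((pred) & (y == 1)).sum()
        fp = ((pred) & (y == 0)).sum()
        rows.append({
            "threshold": pt,
            "net_benefit": tp / n - fp / n * odds,
            "treat_all": prev - (1 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def dice_iou(pair: SegPair) -> tuple[float, float]:
    inter = float((pair.pred & pair.ref).sum())
    a, b = float(pair.pred.sum()), float(pair.ref.sum())
    union = a + b - inter
    if a + b == 0:
        return 1.0, 1.0  # both empty: perfect agreement
    dice = 2 * inter / (a + b)
    iou = inter / union if union > 0 else 1.0
    return dice, iou


def seg_pixel_metrics(pair: SegPair) -> dict[str, float]:
    tp = float((pair.pred & pair.ref).sum())
    tn = float((~pair.pred & ~pair.ref).sum())
    fp = float((pair.pred & ~pair.ref).sum())
    fn = float((~pair.pred & pair.ref).sum())
    dice, iou = dice_iou(pair)
    return {
        "dice": dice, "iou": iou,
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "ppv": _safe_div(tp, tp + fp),
        "assd": assd(pair),
    }


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (or on the image edge)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1),
        border_value=0)
    return mask & ~eroded


def assd(pair: SegPair) -> float:
    """Average symmetric surface distance between boundary pixel sets.

    With exactly one empty mask the pair is maximally wrong but the
    distance must stay finite for center averaging: the image diagonal is
    returned (flag via `math.isfinite` comparisons upstream if needed).
    """
    a, b = pair.pred, pair.ref
    if not a.any() and not b.any():
        return 0.0
    diag = float(np.hypot(*a.shape)) * pair.spacing
    if not a.any() or not b.any():
        return diag
    ba, bb = _boundary(a), _boundary(b)
    # distance transforms give each pixel's distance to the other boundary
    da = ndimage.distance_transform_edt(~bb)  # distance to ref boundary
    db = ndimage.distance_transform_edt(~ba)
    d_ab = da[ba].mean()
    d_ba = db[bb].mean()
    return float(0.5 * (d_ab + d_ba) * pair.spacing)


# --------------------------------------------------------------------------
# model-level evaluation
# --------------------------------------------------------------------------

def evaluate_classifier(model, ds: ArrayDataset,
                        cutoff: float | None = None,
                        curves: bool = False) -> MetricReport:
    scores = _scores(model, ds)
    preds = ScoredPredictions(ds.targets, scores, cutoff)
    m = {"auc": auc(preds)}
    m.update(confusion_metrics(preds))
    report = MetricReport("classification", m)
    if curves:
        report.roc = roc_curve(preds)
        report.dca = dca_curve(preds)
    return report


def _scores(model, ds: ArrayDataset, chunk: int = 32) -> np.ndarray:
    out = []
    for start in range(0, len(ds), chunk):
        out.append(model.predict_proba(_tensorize(ds.images[start:start + chunk]))[:, 1])
    return np.concatenate(out)


def _tensorize(x):
    from .nn import Tensor
    return Tensor(np.asarray(x, dtype=np.float64))


def evaluate_segmenter(model, ds: ArrayDataset,
                       threshold: float = 0.5) -> MetricReport:
    per_image = []
    for start in range(0, len(ds), 16):
        probs = model.predict_proba(_tensorize(ds.images[start:start + 16]))
        for p, ref in zip(probs, ds.targets[start:start + 16]):
            pair = SegPair(p[0] >= threshold, ref[0] > 0.5)
            per_image.append(seg_pixel_metrics(pair))
    keys = per_image[0].keys()
    return MetricReport("segmentation",
                        {k: float(np.nanmean([r[k] for r in per_image]))
                         for k in keys})


def cross_center_matrix(models: dict[str, object],
                        test_sets: dict[str, ArrayDataset],
                        metric: str = "auc") -> pd.DataFrame:
    """Entry (i, j) = metric of center i's model on center j's test split."""
    centers_m = list(models)
    centers_d = list(test_sets)
    mat = np.zeros((len(centers_m), len(centers_d)))
    for i, cm in enumerate(centers_m):
        for j, cd in enumerate(centers_d):
            ds = test_sets[cd]
            if ds.task == "classification":
                rep = evaluate_classifier(models[cm], ds)
            else:
                rep = evaluate_segmenter(models[cm], ds)
            mat[i, j] = rep.metrics[metric]
    return pd.DataFrame(mat, index=centers_m, columns=centers_d)


# --------------------------------------------------------------------------
# deduction-based center similarity
# --------------------------------------------------------------------------

def profile_correlation(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Plain Pearson correlation of two equal-length score profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 batches per profile")
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _quantile_profile(profile: np.ndarray, m: int) -> np.ndarray:
    s = np.sort(np.asarray(profile, dtype=float))
    q = np.linspace(0, 1, m)
    return np.interp(q, np.linspace(0, 1, len(s)), s)


def center_similarity(reference: ArrayDataset, external: ArrayDataset,
                      local, shared, batch_size: int = 8,
                      temperature: float = 2.0, seed: int = 42) -> float:
    """Similarity of two centers' data under one (local, shared) model pair.

    Both datasets are scored batch-wise by the heterogeneity statistic; the
    two divergence profiles, brought onto a common quantile grid, are
    compared by Pearson correlation.  Higher similarity ⇒ the external
    center's heterogeneity looks like the reference center's, so its local
    model is the better pick for external prediction.
    """
    rng = np.random.default_rng(seed)
    ref_b = make_batches(reference, batch_size, rng)
    ext_b = make_batches(external, batch_size, rng)
    if len(ref_b) < 3 or len(ext_b) < 3:
        raise ValueError("need at least 3 batches on each side")
    ref_p = np.array([s.divergence for s in
                      score_batches(local, shared, ref_b, temperature)])
    ext_p = np.array([s.divergence for s in
                      score_batches(local, shared, ext_b, temperature)])
    m = min(len(ref_p), len(ext_p))
    return profile_correlation(_quantile_profile(ref_p, m),
                               _quantile_profile(ext_p, m))
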