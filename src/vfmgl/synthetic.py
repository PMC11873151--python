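"""Synthetic multi-center image generator with planted heterogeneity.

Stands in for multi-center clinical imaging: class-conditional structure
(a textured foreground blob for classification; gland-like or nuclei-like
blobs with exact masks for segmentation) is rendered first, then each
center's acquisition signature — additive intensity shift, contrast gain,
channel mixing, Gaussian noise, resolution blur — is superimposed,
emulating the equipment/protocol/quality differences between real centers.
Everything is a pure function of (config, seed); datasets are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .data import ArrayDataset

__all__ = ["CenterEffect", "ObjectModel", "SyntheticConfig", "CenterManifest",
           "generate_classification_center", "generate_segmentation_center",
           "generate_federation", "split_dataset", "apply_center_effect",
           "write_center_to_disk"]


@dataclass(frozen=True)
class CenterEffect:
    """One center's acquisition signature, applied after class rendering."""

    intensity_shift: float = 0.0   # additive, fraction of dynamic range
    contrast_gain: float = 1.0     # multiplicative around mid-gray
    color_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.02
    resolution_blur: float = 0.0   # Gaussian sigma in pixels
    intensity_jitter: float = 0.0  # per-image sd around intensity_shift
    artifact_prob: float = 0.0     # fraction of images with an extra
    artifact_shift: float = 0.0    # extreme acquisition-artifact shift
    artifact_kind: str = "colorcast"  # "colorcast" | "inversion"

    def __post_init__(self):
        if not -0.3 <= self.intensity_shift <= 0.3:
            raise ValueError("intensity_shift outside [-0.3, 0.3]")
        if self.intensity_jitter < 0:
            raise ValueError("intensity_jitter must be >= 0")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact_prob must be in [0, 1]")
        if self.contrast_gain <= 0:
            raise ValueError("contrast_gain must be > 0")
        if self.noise_sigma < 0 or self.resolution_blur < 0:
            raise ValueError("noise/blur must be >= 0")


@dataclass(frozen=True)
class ObjectModel:
    """Foreground structure: blob count, radius range (fraction of image
    side), and texture contrast inside the blob."""

    blob_count: tuple[int, int] = (1, 1)
    radius_range: tuple[float, float] = (0.15, 0.28)
    texture_contrast: float = 0.25
    foreground_level: float = 0.45  # brightness offset of the blob


@dataclass(frozen=True)
class SyntheticConfig:
    task: str = "classification"
    n_centers: int = 3
    n_samples: int = 60                       # per center
    prevalence: float = 0.5                   # per-center positive fraction
    image_size: int = 64
    effects: tuple[CenterEffect, ...] = ()
    object_model: ObjectModel = field(default_factory=ObjectModel)
    split_ratios: tuple[float, ...] = (0.6, 0.4)
    seed: int = 42
    distinct_centers: bool = False  # independent structural draws per center

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.effects and len(self.effects) != self.n_centers:
            raise ValueError("one CenterEffect per center required")

    def effect_for(self, center: int) -> CenterEffect:
        if self.effects:
            return self.effects[center]
        return CenterEffect()


@dataclass
class CenterManifest:
    center_id: str
    rows: pd.DataFrame  # columns: path, label|mask_path, split

    def __post_init__(self):
        splits = set(self.rows["split"].unique()) if len(self.rows) else set()
        unknown = splits - {"train", "val", "test"}
        if unknown:
            raise ValueError(f"unknown splits {unknown}")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _smooth_background(rng: np.random.Generator, size: int) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, (3, size // 8 + 1, size // 8 + 1))
    up = np.stack([ndimage.zoom(c, size / c.shape[0], order=1)[:size, :size]
                   for c in coarse])
    return 0.45 + 0.05 * up


def _render_blobs(rng: np.random.Generator, size: int, om: ObjectModel,
                  n_blobs: int) -> tuple[np.ndarray, np.ndarray]:
    """Foreground intensity field and exact binary mask."""
    yy, xx = np.mgrid[0:size, 0:size]
    field = np.zeros((size, size))
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(n_blobs):
        r = rng.uniform(*om.radius_range) * size
        cy = rng.uniform(r, size - r)
        cx = rng.uniform(r, size - r)
        ry = r * rng.uniform(0.7, 1.3)
        rx = r * rng.uniform(0.7, 1.3)
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.35, 0.7)
        texture = np.sin(freq * xx + phase) * np.sin(freq * yy + phase)
        field[inside] = (om.foreground_level
                         + om.texture_contrast * texture[inside])
        mask |= inside
    return field, mask


def _rotation_matrix(weights: tuple[float, float, float]) -> np.ndarray:
    """Small channel-mixing rotation from per-axis angles (radians)."""
    ax, ay, az = weights
    def rot(a, i, j):
        m = np.eye(3)
        m[i, i] = m[j, j] = np.cos(a)
        m[i, j], m[j, i] = -np.sin(a), np.sin(a)
        return m
    return rot(az, 0, 1) @ rot(ay, 0, 2) @ rot(ax, 1, 2)


def apply_center_effect(img: np.ndarray, effect: CenterEffect,
                        rng: np.random.Generator,
                        artifact: bool = False) -> np.ndarray:
    """Apply one center's signature to a (3, H, W) image in [0, 1].

    The intensity shift gets per-image jitter (protocol and scanner drift
    within a center), so heterogeneity varies across a center's batches,
    not just between centers; ``artifact`` marks a corrupted acquisition
    that additionally receives the extreme artifact shift — the kind of
    sample batch-level deduction should drop."""
    shift = effect.intensity_shift
    if effect.intensity_jitter > 0:
        shift = shift + rng.normal(0.0, effect.intensity_jitter)
    out = (img - 0.5) * effect.contrast_gain + 0.5 + shift
    if artifact:
        if effect.artifact_kind == "inversion":
            # contrast inversion about the image mean: reverses the
            # brightness cue (decision-corrupting) without saturating
            out = 2 * out.mean() - out
        else:
            # channel-opposed extreme shift: a color-cast corruption that
            # stays image-like but sits far outside the center range
            out[0] = out[0] + effect.artifact_shift
            out[2] = out[2] - effect.artifact_shift
    if any(effect.color_rotation):
        m = _rotation_matrix(effect.color_rotation)
        out = np.einsum("ij,jhw->ihw", m, out - 0.5) + 0.5
    if effect.resolution_blur > 0:
        out = np.stack([ndimage.gaussian_filter(c, effect.resolution_blur)
                        for c in out])
    if effect.noise_sigma > 0:
        out = out + rng.normal(0, effect.noise_sigma, out.shape)
    return np.clip(out, 0.0, 1.0)


def generate_classification_center(config: SyntheticConfig, center: int
                                   ) -> tuple[ArrayDataset, CenterManifest]:
    """Images + binary labels for one center.

    The class signal is the presence of a bright textured blob; labels are
    exactly balanced to the configured prevalence.  The center effect is
    applied after class rendering, so heterogeneity is label-independent.
    """
    n = config.n_samples
    n_pos = int(round(config.prevalence * n))
    if min(n_pos, n - n_pos) < 2:
        raise ValueError("need at least 2 samples per class")
    rng = _center_rng(config, center)
    size = config.image_size
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    labels = labels[rng.permutation(n)]
    imgs = np.empty((n, 3, size, size))
    effect = config.effect_for(center)
    artifacts = _artifact_run(rng, n, effect.artifact_prob)
    for i, lab in enumerate(labels):
        img = _smooth_background(rng, size)
        if lab == 1:
            field, mask = _render_blobs(rng, size, config.object_model,
                                        rng.integers(*_count(config)))
            img = img + field[None]
        imgs[i] = apply_center_effect(img, effect, rng, artifacts[i])
    manifest = _memory_manifest(config, center, labels=labels)
    return ArrayDataset(imgs, labels, "classification"), manifest


def generate_segmentation_center(config: SyntheticConfig, center: int
                                 ) -> tuple[ArrayDataset, CenterManifest]:
    """Images + exact binary masks of the rendered foreground blobs."""
    n = config.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = _center_rng(config, center)
    size = config.image_size
    imgs = np.empty((n, 3, size, size))
    masks = np.empty((n, 1, size, size))
    effect = config.effect_for(center)
    artifacts = _artifact_run(rng, n, effect.artifact_prob)
    lo, hi = _count(config)
    for i in range(n):
        img = _smooth_background(rng, size)
        n_blobs = int(rng.integers(lo, hi))
        field, mask = _render_blobs(rng, size, config.object_model, n_blobs)
        imgs[i] = apply_center_effect(img + field[None], effect, rng,
                                      artifacts[i])
        masks[i, 0] = mask.astype(np.float64)
    manifest = _memory_manifest(config, center, n_rows=n)
    return ArrayDataset(imgs, masks, "segmentation"), manifest


def _artifact_run(rng: np.random.Generator, n: int,
                  prob: float) -> np.ndarray:
    """Corrupted acquisitions cluster in time: mark one contiguous run of
    ~prob·n samples (in acquisition order) as artifacts."""
    flags = np.zeros(n, dtype=bool)
    n_art = int(round(prob * n))
    if n_art > 0:
        start = int(rng.integers(0, n - n_art + 1))
        flags[start:start + n_art] = True
    return flags


def _count(config: SyntheticConfig) -> tuple[int, int]:
    lo, hi = config.object_model.blob_count
    return lo, hi + 1


def _center_rng(config: SyntheticConfig, center: int) -> np.random.Generator:
    """By default centers share one structural random stream: with
    identical configs and zero effects, all centers render pixel-identical
    datasets, so any cross-center difference is attributable to the
    planted effects.  With ``distinct_centers`` each center draws its own
    population (distinct patients)."""
    if not 0 <= center < config.n_centers:
        raise ValueError("center index out of range")
    if config.distinct_centers:
        return np.random.default_rng(config.seed + 9973 * center)
    return np.random.default_rng(config.seed)


def _memory_manifest(config: SyntheticConfig, center: int,
                     labels: np.ndarray | None = None,
                     n_rows: int | None = None) -> CenterManifest:
    cid = f"center_{chr(ord('A') + center)}"
    n = len(labels) if labels is not None else n_rows
    rows = pd.DataFrame({
        "path": [f"{cid}/img_{i:05d}.png" for i in range(n)],
        ("label" if labels is not None else "mask_path"):
            (labels if labels is not None
             else [f"{cid}/mask_{i:05d}.png" for i in range(n)]),
    })
    rows["split"] = split_dataset(
        n, config.split_ratios, config.seed,
        labels=labels if labels is not None else None)
    return CenterManifest(cid, rows)


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

_SPLIT_NAMES = ("train", "val", "test")


def _allocate(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n items to the ratio vector."""
    raw = [r * n for r in ratios]
    base = [int(np.floor(x)) for x in raw]
    rem = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # most owed first
    for i in order[:rem]:
        base[i] += 1
    return base


def split_dataset(n: int, ratios: tuple[float, ...], seed: int,
                  labels: np.ndarray | None = None) -> np.ndarray:
    """Assign train/val/test (or train/test) splits, stratified by label.

    Ratios of length 2 mean (train, test); length 3 means (train, val,
    test); length 1 puts everything in train.  Reproducible per seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    names = (["train"] if len(ratios) == 1 else
             ["train", "test"] if len(ratios) == 2 else
             list(_SPLIT_NAMES))
    if len(ratios) > 3:
        raise ValueError("at most 3 splits supported")
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=object)
    strata = ([np.arange(n)] if labels is None else
              [np.flatnonzero(labels == v) for v in np.unique(labels)])
    for idx in strata:
        if len(idx) < len(ratios):
            raise ValueError("stratum smaller than the number of splits")
        perm = rng.permutation(idx)
        counts = _allocate(len(idx), ratios)
        start = 0
        for name, c in zip(names, counts):
            out[perm[start:start + c]] = name
            start += c
    return out.astype(str)


# --------------------------------------------------------------------------
# federation convenience + disk I/O
# --------------------------------------------------------------------------

def generate_federation(config: SyntheticConfig
                        ) -> dict[str, dict[str, object]]:
    """All centers at once: {center_id: {split: ArrayDataset, 'manifest': …}}."""
    gen = (generate_classification_center if config.task == "classification"
           else generate_segmentation_center)
    out = {}
    for c in range(config.n_centers):
        ds, manifest = gen(config, c)
        entry: dict[str, object] = {"manifest": manifest, "full": ds}
        for split in manifest.rows["split"].unique():
            idx = np.flatnonzero((manifest.rows["split"] == split).values)
            entry[split] = ds.subset(idx)
        out[manifest.center_id] = entry
    return out


def write_center_to_disk(ds: ArrayDataset, manifest: CenterManifest,
                         root: str | Path) -> Path:
    """Materialize a center as 8-bit PNGs + a CSV manifest; returns the CSV
    path.  Every referenced file exists on return."""
    root = Path(root)
    (root / manifest.center_id).mkdir(parents=True, exist_ok=True)
    for i, row in manifest.rows.iterrows():
        img8 = (ds.images[i].transpose(1, 2, 0) * 255).round().astype(np.uint8)
        Image.fromarray(img8).save(root / row["path"])
        if "mask_path" in row:
            m8 = (ds.targets[i, 0] * 255).round().astype(np.uint8)
            Image.fromarray(m8).save(root / row["mask_path"])
    csv_path = root / f"{manifest.center_id}.csv"
    rows = manifest.rows.copy()
    rows.insert(0, "center_id", manifest.center_id)
    rows.to_csv(csv_path, index=False)
    return csv_path
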