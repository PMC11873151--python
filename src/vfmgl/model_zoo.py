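"""Student and teacher architectures with feature hooks.

Students are the two workhorse medical-imaging networks — an 18-layer
residual classifier and a u-shaped encoder/decoder segmenter — and teachers
are vision transformers (the ViT-B/14 foundation-model geometry, plus a
small randomly initialized "tiny-vit" so the full transfer pipeline runs
without pretrained weights).  Every model exposes

* ``forward(x)`` — task prediction (class logits or mask logits),
* ``forward_features(x, layers)`` — hookable intermediate representations,
* ``layer_param_prefixes`` — mapping from hookable layer name to the dotted
  parameter prefixes it owns (the freezing granularity).

Transfer candidates are block-level: the four residual stages, the u-net
encoder/decoder blocks, and the transformer blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, no_grad
from .nn.functional import softmax

__all__ = ["ModelSpec", "FeatureBundle", "build_model", "extract_features",
           "recalibrate_bn", "FAMILIES"]

FAMILIES = ("residual-18", "u-shaped", "vit-b-14", "tiny-vit")

_VIT_GEOM = {
    # family: (dim, depth, heads, mlp_ratio, patch)
    "vit-b-14": (768, 12, 12, 4, 14),
    "tiny-vit": (96, 4, 4, 4, 8),
}


def _default_layers(family: str) -> list[str]:
    if family == "residual-18":
        return ["stage1", "stage2", "stage3", "stage4"]
    if family == "u-shaped":
        return ["enc1", "enc2", "enc3", "enc4", "bottleneck",
                "dec4", "dec3", "dec2", "dec1"]
    depth = _VIT_GEOM[family][1]
    return [f"block{i + 1}" for i in range(depth)]


@dataclass
class ModelSpec:
    """Declarative description of a network; profiling needs nothing else.

    ``width`` scales the channel widths of the convolutional students
    (default 64 for the residual student, 64 for the u-shaped student);
    reduced widths give faithful but fast models for desk-scale experiments.
    """

    task: str  # "classification" | "segmentation"
    family: str
    in_shape: tuple[int, int, int] = (224, 224, 3)
    n_outputs: int = 2
    width: int | None = None
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.task not in ("classification", "segmentation"):
            raise ValueError(f"unknown task {self.task!r}")
        h, w, c = self.in_shape
        if h < 32 or w < 32:
            raise ValueError("in_shape spatial dims must be >= 32")
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        if self.family in _VIT_GEOM:
            patch = _VIT_GEOM[self.family][4]
            if h % patch or w % patch:
                raise ValueError(
                    f"{self.family} input must be a multiple of patch {patch}")
        if not self.layer_names:
            self.layer_names = _default_layers(self.family)

    @property
    def base_width(self) -> int:
        return self.width if self.width is not None else 64


@dataclass
class FeatureBundle:
    """Per-layer features: student layers as (N,C,h,w) maps, teacher layers
    as (N,tokens,dim) token matrices with their spatial grid shape."""

    features: dict[str, Tensor]
    grid: tuple[int, int] | None = None  # (gh, gw) for token features
    has_class_token: bool = False
    layer_names: tuple[str, ...] = ()

    def __post_init__(self):
        for k in self.features:
            if self.layer_names and k not in self.layer_names:
                raise ValueError(f"feature key {k!r} not in producing spec")
        if self.grid is not None:
            gh, gw = self.grid
            want = gh * gw + (1 if self.has_class_token else 0)
            for k, t in self.features.items():
                if t.shape[1] != want:
                    raise ValueError(
                        f"{k}: token count {t.shape[1]} != grid {want}")

    def spatial_tokens(self, layer: str) -> Tensor:
        """Token matrix with any class token stripped (alignment input)."""
        t = self.features[layer]
        return t[:, 1:, :] if self.has_class_token else t


# --------------------------------------------------------------------------
# Residual-18 student
# --------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    def __init__(self, c_in, c_out, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1,
                               bias=False)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down_conv = nn.Conv2d(c_in, c_out, 1, rng, stride=stride,
                                       bias=False)
            self.down_bn = nn.BatchNorm2d(c_out)
        else:
            self.down_conv = None

    def forward(self, x):
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        if self.down_conv is not None:
            x = self.down_bn(self.down_conv(x))
        return (out + x).relu()


class ResNet18(nn.Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        w = spec.base_width
        c_in = spec.in_shape[2]
        self.conv1 = nn.Conv2d(c_in, w, 7, rng, stride=2, padding=3, bias=False)
        self.bn1 = nn.BatchNorm2d(w)
        self.maxpool = nn.MaxPool2d(3, 2, padding=1)
        widths = [w, 2 * w, 4 * w, 8 * w]
        strides = [1, 2, 2, 2]
        prev = w
        for i, (cw, st) in enumerate(zip(widths, strides), start=1):
            setattr(self, f"layer{i}", nn.Sequential(
                _BasicBlock(prev, cw, st, rng), _BasicBlock(cw, cw, 1, rng)))
            prev = cw
        self.fc = nn.Linear(8 * w, spec.n_outputs, rng)
        self.layer_param_prefixes = {f"stage{i}": [f"layer{i}"]
                                     for i in range(1, 5)}
        self.stem_head_prefixes = ["conv1", "bn1", "fc"]

    def _stem(self, x):
        return self.maxpool(self.bn1(self.conv1(x)).relu())

    def forward(self, x: Tensor) -> Tensor:
        h = self._stem(x)
        for i in range(1, 5):
            h = self._modules[f"layer{i}"](h)
        return self.fc(h.mean(axis=(2, 3)))

    def penultimate(self, x: Tensor) -> Tensor:
        h = self._stem(x)
        for i in range(1, 5):
            h = self._modules[f"layer{i}"](h)
        return h.mean(axis=(2, 3))

    def forward_features(self, x: Tensor, layers=None) -> FeatureBundle:
        layers = set(layers or self.spec.layer_names)
        _check_layers(layers, self.spec)
        feats = {}
        h = self._stem(x)
        for i in range(1, 5):
            h = self._modules[f"layer{i}"](h)
            if f"stage{i}" in layers:
                feats[f"stage{i}"] = h
        return FeatureBundle(feats, layer_names=tuple(self.spec.layer_names))

    def predict_proba(self, x: Tensor) -> np.ndarray:
        with no_grad():
            return softmax(self.forward(x)).data

    def forward_with_features(self, x: Tensor, layers) -> tuple[Tensor, dict]:
        """Logits plus hooked feature maps from one shared graph."""
        layers = set(layers)
        _check_layers(layers, self.spec)
        feats = {}
        h = self._stem(x)
        for i in range(1, 5):
            h = self._modules[f"layer{i}"](h)
            if f"stage{i}" in layers:
                feats[f"stage{i}"] = h
        return self.fc(h.mean(axis=(2, 3))), feats


# --------------------------------------------------------------------------
# U-shaped student
# --------------------------------------------------------------------------

class _DoubleConv(nn.Module):
    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(c_in, c_out, 3, rng, padding=1, bias=False),
            nn.BatchNorm2d(c_out), nn.ReLU(),
            nn.Conv2d(c_out, c_out, 3, rng, padding=1, bias=False),
            nn.BatchNorm2d(c_out), nn.ReLU())

    def forward(self, x):
        return self.block(x)


class UNet(nn.Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        w = spec.base_width
        c_in = spec.in_shape[2]
        ws = [w, 2 * w, 4 * w, 8 * w]
        self.enc1 = _DoubleConv(c_in, ws[0], rng)
        self.enc2 = _DoubleConv(ws[0], ws[1], rng)
        self.enc3 = _DoubleConv(ws[1], ws[2], rng)
        self.enc4 = _DoubleConv(ws[2], ws[3], rng)
        self.pool = nn.MaxPool2d(2)
        self.bottleneck = _DoubleConv(ws[3], 16 * w, rng)
        self.up = nn.UpsampleBilinear(2)
        self.dec4 = _DoubleConv(16 * w + ws[3], ws[3], rng)
        self.dec3 = _DoubleConv(ws[3] + ws[2], ws[2], rng)
        self.dec2 = _DoubleConv(ws[2] + ws[1], ws[1], rng)
        self.dec1 = _DoubleConv(ws[1] + ws[0], ws[0], rng)
        self.out_conv = nn.Conv2d(ws[0], spec.n_outputs, 1, rng)
        self.layer_param_prefixes = {n: [n] for n in
                                     ["enc1", "enc2", "enc3", "enc4",
                                      "bottleneck", "dec4", "dec3", "dec2",
                                      "dec1"]}
        self.stem_head_prefixes = ["out_conv"]

    def _run(self, x, layers):
        feats = {}

        def keep(name, t):
            if name in layers:
                feats[name] = t

        e1 = self.enc1(x); keep("enc1", e1)
        e2 = self.enc2(self.pool(e1)); keep("enc2", e2)
        e3 = self.enc3(self.pool(e2)); keep("enc3", e3)
        e4 = self.enc4(self.pool(e3)); keep("enc4", e4)
        b = self.bottleneck(self.pool(e4)); keep("bottleneck", b)
        d4 = self.dec4(nn.concat([self.up(b), e4], axis=1)); keep("dec4", d4)
        d3 = self.dec3(nn.concat([self.up(d4), e3], axis=1)); keep("dec3", d3)
        d2 = self.dec2(nn.concat([self.up(d3), e2], axis=1)); keep("dec2", d2)
        d1 = self.dec1(nn.concat([self.up(d2), e1], axis=1)); keep("dec1", d1)
        return self.out_conv(d1), feats

    def forward(self, x: Tensor) -> Tensor:
        return self._run(x, set())[0]

    def penultimate(self, x: Tensor) -> Tensor:
        _, feats = self._run(x, {"dec1"})
        return feats["dec1"].mean(axis=(2, 3))

    def forward_features(self, x: Tensor, layers=None) -> FeatureBundle:
        layers = set(layers or self.spec.layer_names)
        _check_layers(layers, self.spec)
        _, feats = self._run(x, layers)
        return FeatureBundle(feats, layer_names=tuple(self.spec.layer_names))

    def predict_proba(self, x: Tensor) -> np.ndarray:
        with no_grad():
            return self.forward(x).sigmoid().data

    def forward_with_features(self, x: Tensor, layers) -> tuple[Tensor, dict]:
        layers = set(layers)
        _check_layers(layers, self.spec)
        out, feats = self._run(x, layers)
        return out, feats


# --------------------------------------------------------------------------
# Vision-transformer teachers
# --------------------------------------------------------------------------

class _MHSA(nn.Module):
    def __init__(self, dim, heads, rng):
        super().__init__()
        self.heads, self.dh = heads, dim // heads
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)

    def forward(self, x):
        b, n, d = x.shape
        qkv = self.qkv(x).reshape(b, n, 3, self.heads, self.dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, b, h, n, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (self.dh ** -0.5))
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)


class _ViTBlock(nn.Module):
    def __init__(self, dim, heads, mlp_ratio, rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = _MHSA(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = nn.Linear(mlp_ratio * dim, dim, rng)

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class ViT(nn.Module):
    """Plain ViT encoder with class token; emits per-block token features."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        dim, depth, heads, mlp_ratio, patch = _VIT_GEOM[spec.family]
        h, w, c = spec.in_shape
        self.patch = patch
        self.grid = (h // patch, w // patch)
        n_tok = self.grid[0] * self.grid[1] + 1
        self.patch_embed = nn.Conv2d(c, dim, patch, rng, stride=patch)
        self.cls_token = nn.Parameter(rng.normal(0, 0.02, (1, 1, dim)))
        self.pos_embed = nn.Parameter(rng.normal(0, 0.02, (1, n_tok, dim)))
        for i in range(depth):
            setattr(self, f"block{i + 1}", _ViTBlock(dim, heads, mlp_ratio, rng))
        self.norm = nn.LayerNorm(dim)
        self.depth = depth
        self.layer_param_prefixes = {f"block{i + 1}": [f"block{i + 1}"]
                                     for i in range(depth)}
        self.stem_head_prefixes = ["patch_embed", "cls_token", "pos_embed",
                                   "norm"]

    def _embed(self, x: Tensor) -> Tensor:
        b = x.shape[0]
        p = self.patch_embed(x)  # (b, dim, gh, gw)
        tok = p.reshape(b, p.shape[1], -1).transpose(0, 2, 1)
        cls = self.cls_token + Tensor(np.zeros((b, 1, tok.shape[2])))
        return nn.concat([cls, tok], axis=1) + self.pos_embed

    def forward(self, x: Tensor) -> Tensor:
        h = self._embed(x)
        for i in range(self.depth):
            h = self._modules[f"block{i + 1}"](h)
        return self.norm(h)[:, 0, :]  # class-token embedding

    def forward_features(self, x: Tensor, layers=None) -> FeatureBundle:
        layers = set(layers or self.spec.layer_names)
        _check_layers(layers, self.spec)
        feats = {}
        h = self._embed(x)
        for i in range(self.depth):
            h = self._modules[f"block{i + 1}"](h)
            name = f"block{i + 1}"
            if name in layers:
                feats[name] = h
        return FeatureBundle(feats, grid=self.grid, has_class_token=True,
                             layer_names=tuple(self.spec.layer_names))


def _check_layers(layers, spec: ModelSpec) -> None:
    bad = set(layers) - set(spec.layer_names)
    if bad:
        raise KeyError(f"unknown layer(s) {sorted(bad)} for {spec.family}")


# --------------------------------------------------------------------------
# Factory + feature extraction
# --------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 42):
    """Instantiate a trainable model from its spec.

    Teacher families (the vision transformers) come back frozen: their
    parameters never require gradients.  An optional ``.npz`` checkpoint can
    be loaded afterwards via ``model.load_state_dict``.
    """
    rng = np.random.default_rng(seed)
    if spec.family == "residual-18":
        model = ResNet18(spec, rng)
    elif spec.family == "u-shaped":
        if spec.task != "segmentation":
            raise ValueError("u-shaped student is a segmentation model")
        model = UNet(spec, rng)
    else:
        model = ViT(spec, rng)
        for p in model.parameters():
            p.requires_grad = False
        model.eval()
    return model


def recalibrate_bn(model, images: np.ndarray, chunk: int = 128) -> None:
    """Refresh batch-norm running statistics under the final weights.

    Running averages lag the parameters they normalize for; one pass over
    (up to ``chunk``) training images with full-weight updates realigns
    eval-mode statistics before metric computation.
    """
    from .nn.layers import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    saved = [(bn.momentum, bn.training) for bn in bns]
    model.train()
    for bn in bns:
        bn.momentum = 1.0
    with no_grad():
        model(Tensor(np.asarray(images[:chunk], dtype=np.float64)))
    for bn, (mom, mode) in zip(bns, saved):
        bn.momentum = mom
        bn.training = mode


def extract_features(model, images: np.ndarray, layers=None) -> FeatureBundle:
    """Run a batch (N,C,H,W float) through the model's feature hooks.

    Teacher gradients never flow: transformer families run under no_grad and
    with inputs resized to their own resolution when shapes differ.
    """
    x = np.asarray(images, dtype=np.float64)
    is_teacher = isinstance(model, ViT)
    th, tw = model.spec.in_shape[0], model.spec.in_shape[1]
    t = Tensor(x)
    if x.shape[-2:] != (th, tw):
        t = t.bilinear_resize(th, tw)
    if is_teacher:
        with no_grad():
            return model.forward_features(t, layers)
    return model.forward_features(t, layers)
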