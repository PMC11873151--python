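"""In-memory dataset containers and batching.

Images are float64 NCHW in [0, 1]; classification targets are integer label
vectors, segmentation targets binary (N, 1, H, W) masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArrayDataset", "Batch", "make_batches"]


@dataclass
class ArrayDataset:
    images: np.ndarray            # (N, C, H, W) float in [0, 1]
    targets: np.ndarray           # (N,) int labels or (N, 1, H, W) masks
    task: str = "classification"

    def __post_init__(self):
        if self.images.ndim != 4:
            raise ValueError("images must be NCHW")
        if len(self.images) != len(self.targets):
            raise ValueError("images/targets length mismatch")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "ArrayDataset":
        return ArrayDataset(self.images[idx], self.targets[idx], self.task)


@dataclass
class Batch:
    batch_id: int
    images: np.ndarray
    targets: np.ndarray


def make_batches(ds: ArrayDataset, batch_size: int,
                 rng: np.random.Generator | None = None) -> list[Batch]:
    """Fixed partition into batches; shuffled when an rng is given."""
    n = len(ds)
    if n == 0:
        raise ValueError("empty dataset")
    order = np.arange(n)
    if rng is not None:
        order = rng.permutation(n)
    out = []
    for b, start in enumerate(range(0, n, batch_size)):
        idx = order[start:start + batch_size]
        out.append(Batch(b, ds.images[idx], ds.targets[idx]))
    return out
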