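"""Pluggable convolutional backbone for transfer-learning classifiers.

The transfer-learning strategy is architecture-generic: a backbone is an
ordered list of convolutional modules with a frozen/trainable boundary.
Off-the-shelf use freezes everything and trains a new head on the final
feature maps; partial fine-tuning unfreezes the trailing ``n`` modules.
Activations at the boundary ("bottlenecks") are computed once and cached,
since the frozen part never changes during training.

A full-scale ImageNet-pretrained backbone (299 x 299 x 3 input, 2048-d
features) can be plugged in by matching this interface.  The bundled
:class:`MiniBackbone` is a deterministic miniature (4 modules, 64 x 64 x 3
input, 32-d features) sized for desk-scale experiments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .nn.layers import Conv2D, GlobalAvgPool, Layer, MaxPool2D, ReLU

__all__ = ["BackboneSpec", "MiniBackbone", "backbone_prepare",
           "BottleneckCache"]


@dataclass(frozen=True)
class BackboneSpec:
    """Shape contract of a backbone: input geometry and module structure."""

    n_modules: int = 4
    input_side: int = 64
    channels: int = 3
    feature_dim: int = 32
    pretrained: bool = True
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("backbone needs at least one module")


class MiniBackbone:
    """Miniature module-structured convnet with deterministic random init.

    Four modules of (3x3 conv, ReLU, 2x2 max-pool) with channel widths
    8-16-24-32, followed by global average pooling to a 32-d feature
    vector.  ``forward_modules`` runs a contiguous module range, so the
    frozen prefix and the trainable suffix can be executed separately.
    """

    CHANNEL_PLAN = (8, 16, 24, 32)

    def __init__(self, spec: BackboneSpec = BackboneSpec()):
        if spec.n_modules != len(self.CHANNEL_PLAN):
            raise ValueError(
                f"MiniBackbone has {len(self.CHANNEL_PLAN)} modules")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.modules: list[list[Layer]] = []
        c_in = spec.channels
        for c_out in self.CHANNEL_PLAN:
            self.modules.append([Conv2D(c_in, c_out, 3, rng, padding=1),
                                 ReLU(), MaxPool2D(2)])
            c_in = c_out
        self.pool = GlobalAvgPool()

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def feature_dim(self) -> int:
        return self.CHANNEL_PLAN[-1]

    def module_layers(self, start: int, stop: int | None = None) -> list[Layer]:
        stop = self.n_modules if stop is None else stop
        return [l for m in self.modules[start:stop] for l in m]

    def forward_modules(self, x: np.ndarray, start: int = 0,
                        stop: int | None = None,
                        batch_size: int = 64) -> np.ndarray:
        """Run modules [start, stop) over x in batches (no caching of
        activations; inference only)."""
        layers = self.module_layers(start, stop)
        outs = []
        for s in range(0, len(x), batch_size):
            h = x[s : s + batch_size]
            for layer in layers:
                h = layer.forward(h)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def features(self, x: np.ndarray) -> np.ndarray:
        """Pooled feature vectors (n, feature_dim) from prepared images."""
        return self.forward_modules(x).mean(axis=(2, 3))

    def module_weight_hash(self, start: int, stop: int | None = None) -> str:
        h = hashlib.sha256()
        for layer in self.module_layers(start, stop):
            for p in layer.params:
                h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


def backbone_prepare(images: np.ndarray,
                     spec: BackboneSpec = BackboneSpec()) -> np.ndarray:
    """Resize padded cell images to the backbone input and replicate the
    grayscale channel three times.

    Input: (n, h, w) or (h, w) 8-bit images.  Output: (n, channels, side,
    side) float64 in [0, 1], all channels identical, bilinear interpolation.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    n = len(images)
    side = spec.input_side
    out = np.empty((n, spec.channels, side, side))
    for i in range(n):
        r = resize(images[i] / 255.0, (side, side), order=1,
                   mode="edge", anti_aliasing=False, preserve_range=True)
        out[i] = r[None, :, :]
    return out


class BottleneckCache:
    """Cache of frozen-prefix activations keyed by (cell ids, boundary).

    A re-request with the same key must carry byte-identical inputs; a key
    collision with a different input hash is a hard error (stale cache)."""

    def __init__(self) -> None:
        self._store: dict[tuple, tuple[str, np.ndarray]] = {}
        self.hits = 0
        self.misses = 0

    @staticmethod
    def _input_hash(x: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()

    def extract(self, backbone: MiniBackbone, x: np.ndarray, boundary: int,
                key: tuple | str = "") -> np.ndarray:
        """Activations after the first ``boundary`` modules, cached."""
        if not 0 <= boundary <= backbone.n_modules:
            raise ValueError("boundary outside module list")
        cache_key = (key, boundary)
        xh = self._input_hash(x)
        if cache_key in self._store:
            stored_hash, feats = self._store[cache_key]
            if stored_hash != xh:
                raise ValueError(
                    f"bottleneck cache collision for key {cache_key}: "
                    "inputs differ from the cached run")
            self.hits += 1
            return feats
        self.misses += 1
        feats = backbone.forward_modules(x, 0, boundary)
        self._store[cache_key] = (xh, feats)
        return feats
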