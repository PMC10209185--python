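"""U-Net variant for 14-class tissue segmentation.

The architecture follows the classic encoder–decoder layout with three
departures from the original U-Net:

* the first level starts at 32 filters (doubling after every max-pooling);
* every U-Net block ends by concatenating its own input with the last
  feature map it produced (a residual-style intra-block skip);
* the decoder upsamples with nearest-neighbor interpolation followed by a
  2×2 convolution instead of transposed convolutions.

Convolutions are same-padded, so the output label grid aligns with the
input tile.  Each block is two 3×3 conv + batch-norm + ReLU stages.  The
head is a 1×1 convolution to C classes; likelihood maps are the pixel-wise
softmax of its output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .losses import softmax


@dataclass(frozen=True)
class ModelSpec:
    in_channels: int = 3
    n_classes: int = 14
    base_filters: int = 32
    depth: int = 4

    def __post_init__(self):
        if min(self.in_channels, self.n_classes, self.base_filters) < 1:
            raise ValueError("channel counts must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    def filters_at(self, level: int) -> int:
        return self.base_filters * 2 ** level

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "n_classes": self.n_classes,
                "base_filters": self.base_filters, "depth": self.depth}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class NetworkOutput:
    """Per-pixel class likelihoods, channel-first, softmax-normalized."""

    likelihoods: np.ndarray  # (C, H, W)
    valid_region: tuple[int, int, int, int] = field(default=None)

    def __post_init__(self):
        if self.valid_region is None:
            _, H, W = self.likelihoods.shape
            self.valid_region = (0, 0, H, W)

    def argmax(self) -> np.ndarray:
        """Label map; ties resolve to the lowest class index (numpy argmax)."""
        return self.likelihoods.argmax(axis=0)


class _UNetBlock(nn.Layer):
    """conv3-bn-relu ×2, then concat(block input, last feature map)."""

    def __init__(self, in_ch: int, filters: int, rng, name: str):
        self.in_ch = in_ch
        self.out_ch = in_ch + filters
        self.seq = nn.Sequential(
            nn.Conv2d(in_ch, filters, 3, rng, f"{name}.c1"),
            nn.BatchNorm(filters, name=f"{name}.bn1"),
            nn.ReLU(),
            nn.Conv2d(filters, filters, 3, rng, f"{name}.c2"),
            nn.BatchNorm(filters, name=f"{name}.bn2"),
            nn.ReLU(),
        )

    def params(self):
        return self.seq.params()

    def forward(self, x, train):
        y = self.seq.forward(x, train)
        return np.concatenate([x, y], axis=-1)

    def backward(self, dout):
        dx_skip = dout[..., :self.in_ch]
        dy = dout[..., self.in_ch:]
        return dx_skip + self.seq.backward(dy)


class UNet:
    """Differentiable tile → class-likelihood function.

    Construction is fully determined by ``(spec, seed)``: two builds with
    the same seed have bit-identical initial parameters.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.enc_blocks, self.pools, skip_ch = [], [], []
        ch = spec.in_channels
        for k in range(spec.depth):
            block = _UNetBlock(ch, spec.filters_at(k), rng, f"enc{k}")
            self.enc_blocks.append(block)
            self.pools.append(nn.MaxPool2())
            skip_ch.append(block.out_ch)
            ch = block.out_ch
        self.bottleneck = _UNetBlock(ch, spec.filters_at(spec.depth), rng, "bottleneck")
        ch = self.bottleneck.out_ch
        self.up_convs, self.dec_blocks = [], []
        for k in reversed(range(spec.depth)):
            f = spec.filters_at(k)
            self.up_convs.append(nn.Conv2d(ch, f, 2, rng, f"up{k}"))
            block = _UNetBlock(f + skip_ch[k], f, rng, f"dec{k}")
            self.dec_blocks.append(block)
            ch = block.out_ch
        self.head = nn.Conv2d(ch, spec.n_classes, 1, rng, "head")
        self._upsample = nn.UpsampleNearest2()

    # -- parameter access ---------------------------------------------------

    def params(self):
        out = []
        for b in self.enc_blocks:
            out += b.params()
        out += self.bottleneck.params()
        for c, b in zip(self.up_convs, self.dec_blocks):
            out += c.params()
            out += b.params()
        out += self.head.params()
        return out

    def _batchnorms(self):
        def from_block(block):
            return [l for l in block.seq.layers if isinstance(l, nn.BatchNorm)]
        out = []
        for b in self.enc_blocks:
            out += from_block(b)
        out += from_block(self.bottleneck)
        for b in self.dec_blocks:
            out += from_block(b)
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Activations (N, H, W, C) for a float input batch (N, H, W, 3)."""
        N, H, W, _ = x.shape
        div = 2 ** self.spec.depth
        if H % div or W % div:
            raise ValueError(
                f"spatial size {H}x{W} not divisible by 2^depth = {div}")
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_ch = []
        for conv, block, skip in zip(self.up_convs, self.dec_blocks,
                                     reversed(skips)):
            x = self._upsample.forward(x, train)
            x = conv.forward(x, train)
            self._skip_ch.append(x.shape[-1])
            x = np.concatenate([x, skip], axis=-1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dact: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(activations)."""
        dy = self.head.backward(np.ascontiguousarray(dact, dtype=nn.DTYPE))
        dskips = []
        for conv, block, up_ch in zip(reversed(self.up_convs),
                                      reversed(self.dec_blocks),
                                      reversed(self._skip_ch)):
            dy = block.backward(dy)
            dskips.append(dy[..., up_ch:])
            dy = conv.backward(dy[..., :up_ch])
            dy = self._upsample.backward(dy)
        dy = self.bottleneck.backward(dy)
        for block, pool, dskip in zip(reversed(self.enc_blocks),
                                      reversed(self.pools), reversed(dskips)):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = block.backward(dy)

    # -- inference ----------------------------------------------------------

    def predict_tile(self, tile: np.ndarray) -> NetworkOutput:
        """Likelihood maps for one 8-bit RGB tile (H, W, 3).

        Input is scaled to [0, 1]; output channels softmax-normalize to 1
        at every pixel.
        """
        if tile.ndim != 3 or tile.shape[-1] != self.spec.in_channels:
            raise ValueError(f"expected (H, W, {self.spec.in_channels}) tile")
        x = np.asarray(tile, dtype=np.float64) / 255.0
        act = self.forward(x[None], train=False)[0]
        probs = softmax(act)
        return NetworkOutput(likelihoods=np.moveaxis(probs, -1, 0))

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for bn in self._batchnorms():
            arrays += [bn.running_mean, bn.running_var]
        return arrays

    def save(self, path, extra: dict | None = None) -> None:
        meta = {"spec": self.spec.to_dict(), "extra": extra or {}}
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(ModelSpec.from_dict(meta["spec"]), seed=0)
        targets = model.state_arrays()
        for i, t in enumerate(targets):
            t[...] = data[f"arr_{i}"]
        model._loaded_extra = meta["extra"]
        return model

    def describe(self) -> str:
        """Human-readable layer table with channel counts per stage."""
        lines = [f"UNet(base={self.spec.base_filters}, depth={self.spec.depth}, "
                 f"classes={self.spec.n_classes}): {self.n_parameters} parameters"]
        ch = self.spec.in_channels
        for k, b in enumerate(self.enc_blocks):
            lines.append(f"  enc{k}: block {ch}->{b.out_ch} "
                         f"({self.spec.filters_at(k)} filters) + maxpool 2x2")
            ch = b.out_ch
        lines.append(f"  bottleneck: block {ch}->{self.bottleneck.out_ch} "
                     f"({self.spec.filters_at(self.spec.depth)} filters)")
        ch = self.bottleneck.out_ch
        for conv, b in zip(self.up_convs, self.dec_blocks):
            lines.append(f"  dec: nearest-up + conv2x2 {ch}->{conv.out_ch}, "
                         f"block -> {b.out_ch}")
            ch = b.out_ch
        lines.append(f"  head: conv1x1 {ch}->{self.spec.n_classes} + softmax")
        return "\n".join(lines)


def build_model(spec: ModelSpec, seed: int = 0) -> UNet:
    """Seed-deterministic construction of the segmentation network."""
    return UNet(spec, seed=seed)
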