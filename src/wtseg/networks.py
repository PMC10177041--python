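"""The two segmentation families: U-Net and a dense-prediction DenseNet.

Both map an RGB patch to a per-pixel probability vector over the tissue
classes through a final softmax, so their outputs can be ensembled by
plain per-pixel averaging.  The U-Net is the classic encoder–decoder
with skip connections and same-padding, so output size equals input
size.  The DenseNet is adapted from the classification architecture to
dense prediction: densely connected convolutional blocks with
transition downsampling, a 1x1 classifier head, and nearest-neighbor
upsampling back to input resolution.

Capacity presets:
  * ``paper``: reference-scale depths (U-Net 4 down/4 up with 64 base
    filters; DenseNet 4 blocks, growth 16).
  * ``tiny``: 2-level / 2-block variants sized for CPU-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import (
    AvgPool2,
    Conv2d,
    MaxPool2,
    ReLU,
    UpsampleNearest2,
    concat_channels,
    split_channels,
)

__all__ = ["NetworkSpec", "UNet", "DenseNetFCN", "build_network",
           "save_model", "load_model", "softmax"]

FAMILIES = ("u-net", "dense-net")
PRESETS = ("paper", "tiny")

#: default patch shape per (family, preset)
DEFAULT_PATCH_SHAPES = {
    ("u-net", "paper"): (412, 412),
    ("dense-net", "paper"): (128, 128),
    ("u-net", "tiny"): (64, 64),
    ("dense-net", "tiny"): (32, 32),
}


@dataclass
class NetworkSpec:
    family: str
    input_shape: tuple[int, int] | None = None
    n_classes: int = 15
    preset: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}; one of {FAMILIES}")
        if self.preset not in PRESETS:
            raise ValueError(f"unsupported preset {self.preset!r}; one of {PRESETS}")
        if self.input_shape is None:
            self.input_shape = DEFAULT_PATCH_SHAPES[(self.family, self.preset)]
        if min(self.input_shape) < 8:
            raise ValueError(f"input shape too small: {self.input_shape}")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


#: input standardization: patches arrive in [0, 1]; centering and scaling
#: them to a roughly unit dynamic range speeds up early convergence of
#: the normalization-free stacks.
INPUT_SHIFT = 0.5
INPUT_SCALE = 4.0


class _Model:
    """Shared plumbing: input standardization, padding to the
    downsampling multiple, softmax head."""

    spec: NetworkSpec
    downsample: int  # input dims must be divisible by this for backward

    def layers(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def _run_logits(self, x):  # overridden
        raise NotImplementedError

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Logits for a (N,H,W,3) float batch; pads oddly shaped inputs."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected (N,H,W,3) input, got {x.shape}")
        x = (x - INPUT_SHIFT) * INPUT_SCALE
        n, h, w, _ = x.shape
        m = self.downsample
        ph, pw = (-h) % m, (-w) % m
        self._pad = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
        logits = self._run_logits(x)
        if ph or pw:
            logits = logits[:, :h, :w, :]
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities on the simplex."""
        return softmax(self.forward_logits(x))

    def backward(self, dlogits: np.ndarray) -> None:
        if any(self._pad):
            raise ValueError(
                "backward requires input dims divisible by "
                f"{self.downsample}; got padded forward pass"
            )
        self._run_backward(dlogits.astype(np.float32))


class _DoubleConv:
    def __init__(self, c_in, c_out, rng):
        self.c1 = Conv2d(c_in, c_out, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(c_out, c_out, 3, rng)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(d))))


class UNet(_Model):
    """Encoder–decoder with skip connections, same-padding convolutions."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        depth, base = (4, 64) if spec.preset == "paper" else (1, 20)
        self.depth, self.base = depth, base
        self.downsample = 2 ** depth
        rng = np.random.default_rng(spec.seed)
        self.enc: list[_DoubleConv] = []
        self.pools: list[MaxPool2] = []
        c = 3
        for d in range(depth):
            self.enc.append(_DoubleConv(c, base * 2**d, rng))
            self.pools.append(MaxPool2())
            c = base * 2**d
        self.bottleneck = _DoubleConv(c, base * 2**depth, rng)
        self.ups: list[UpsampleNearest2] = []
        self.upconvs: list[Conv2d] = []
        self.upact: list[ReLU] = []
        self.dec: list[_DoubleConv] = []
        c = base * 2**depth
        for d in reversed(range(depth)):
            skip = base * 2**d
            self.ups.append(UpsampleNearest2())
            self.upconvs.append(Conv2d(c, skip, 3, rng))
            self.upact.append(ReLU())
            self.dec.append(_DoubleConv(2 * skip, skip, rng))
            c = skip
        self.head = Conv2d(base, spec.n_classes, 1, rng)

    def layers(self):
        return (
            self.enc + [self.bottleneck] + self.upconvs + self.dec + [self.head]
        )

    def _run_logits(self, x):
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_sizes = []
        for up, conv, act, dec, skip in zip(
            self.ups, self.upconvs, self.upact, self.dec, reversed(skips)
        ):
            x = act.forward(conv.forward(up.forward(x)))
            self._skip_sizes.append((skip.shape[-1], x.shape[-1]))
            x = concat_channels([skip, x])
            x = dec.forward(x)
        return self.head.forward(x)

    def _run_backward(self, d):
        d = self.head.backward(d)
        dskips = []
        for up, conv, act, dec, sizes in zip(
            reversed(self.ups),
            reversed(self.upconvs),
            reversed(self.upact),
            reversed(self.dec),
            reversed(self._skip_sizes),
        ):
            d = dec.backward(d)
            dskip, d = split_channels(d, list(sizes))
            dskips.append(dskip)
            d = up.backward(conv.backward(act.backward(d)))
        d = self.bottleneck.backward(d)
        # dskips[0] belongs to the shallowest encoder level; walk deep-to-shallow
        for enc, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d) + dskip
            d = enc.backward(d)


class _DenseBlock:
    def __init__(self, c_in, n_layers, growth, rng):
        self.convs = [
            Conv2d(c_in + i * growth, growth, 3, rng) for i in range(n_layers)
        ]
        self.acts = [ReLU() for _ in range(n_layers)]
        self.c_out = c_in + n_layers * growth

    def params(self):
        out = []
        for c in self.convs:
            out.extend(c.params())
        return out

    def forward(self, x):
        feats = [x]
        for conv, act in zip(self.convs, self.acts):
            y = act.forward(conv.forward(concat_channels(feats)))
            feats.append(y)
        self._sizes = [f.shape[-1] for f in feats]
        return concat_channels(feats)

    def backward(self, d):
        dfeats = split_channels(d, self._sizes)
        for conv, act, i in zip(
            reversed(self.convs), reversed(self.acts),
            range(len(self.convs) - 1, -1, -1),
        ):
            din = conv.backward(act.backward(dfeats[i + 1]))
            dins = split_channels(din, self._sizes[: i + 1])
            for j in range(i + 1):
                dfeats[j] = dfeats[j] + dins[j]
        return dfeats[0]


class DenseNetFCN(_Model):
    """Densely connected blocks adapted to dense per-pixel prediction."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        if spec.preset == "paper":
            n_blocks, layers_per, growth, stem = 4, 4, 16, 48
        else:
            n_blocks, layers_per, growth, stem = 2, 3, 8, 16
        self.downsample = 2 ** (n_blocks - 1)
        rng = np.random.default_rng(spec.seed)
        self.stem = Conv2d(3, stem, 3, rng)
        self.stem_act = ReLU()
        self.blocks: list[_DenseBlock] = []
        self.trans: list[Conv2d] = []
        self.trans_act: list[ReLU] = []
        self.trans_pool: list[AvgPool2] = []
        c = stem
        for b in range(n_blocks):
            blk = _DenseBlock(c, layers_per, growth, rng)
            self.blocks.append(blk)
            c = blk.c_out
            if b < n_blocks - 1:
                self.trans.append(Conv2d(c, c // 2, 1, rng))
                self.trans_act.append(ReLU())
                self.trans_pool.append(AvgPool2())
                c = c // 2
        self.head = Conv2d(c, spec.n_classes, 1, rng)
        self.ups = [UpsampleNearest2() for _ in range(n_blocks - 1)]

    def layers(self):
        return [self.stem] + self.blocks + self.trans + [self.head]

    def _run_logits(self, x):
        x = self.stem_act.forward(self.stem.forward(x))
        for b, blk in enumerate(self.blocks):
            x = blk.forward(x)
            if b < len(self.trans):
                x = self.trans_pool[b].forward(
                    self.trans_act[b].forward(self.trans[b].forward(x))
                )
        x = self.head.forward(x)
        for up in self.ups:
            x = up.forward(x)
        return x

    def _run_backward(self, d):
        for up in reversed(self.ups):
            d = up.backward(d)
        d = self.head.backward(d)
        for b in range(len(self.blocks) - 1, -1, -1):
            if b < len(self.trans):
                d = self.trans[b].backward(
                    self.trans_act[b].backward(self.trans_pool[b].backward(d))
                )
            d = self.blocks[b].backward(d)
        self.stem.backward(self.stem_act.backward(d))


def build_network(spec: NetworkSpec) -> _Model:
    """Instantiate a trainable model fulfilling the softmax output contract."""
    if spec.family == "u-net":
        return UNet(spec)
    return DenseNetFCN(spec)


def save_model(model: _Model, path: str | Path) -> None:
    """Checkpoint: spec JSON + weights npz side by side."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spec = model.spec
    meta = {
        "family": spec.family,
        "input_shape": list(spec.input_shape),
        "n_classes": spec.n_classes,
        "preset": spec.preset,
        "seed": spec.seed,
    }
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_model(path: str | Path) -> _Model:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec(
        family=meta["family"],
        input_shape=tuple(meta["input_shape"]),
        n_classes=meta["n_classes"],
        preset=meta["preset"],
        seed=meta["seed"],
    )
    model = build_network(spec)
    with np.load(path.with_suffix(".npz")) as data:
        for i, (p, _) in enumerate(model.params()):
            p[...] = data[f"p{i}"]
    return model
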