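"""Compact encoder-decoder semantic segmenter trained with soft Dice loss.

The network is a U-shaped fully convolutional architecture: an encoder of
3x3 conv + ReLU blocks with 2x2 max-pooling, a bottleneck, and a decoder
of nearest-neighbor upsampling with skip concatenations from the matching
encoder level, finished by a 1x1 convolution and a per-pixel 3-way softmax
(background / optic disc / optic cup).  Forward and backward passes are
written directly in numpy (im2col convolutions), so training is
CPU-deterministic under a seed and needs no deep-learning runtime.

Three width/depth presets (small / medium / large) stand in for the
backbone choices common in the segmentation literature; they are trained
from random initialization.  At the desk scale this package targets, the
contract being exercised is architectural (skips, softmax head, Dice
optimization), demonstrated by overfitting small synthetic sets.

Loss: 1 - mean over the 3 classes of the soft Dice coefficient
(2*sum(p*t) + eps) / (sum(p) + sum(t) + eps), eps = 1e-6.  The background
class is included in the mean, not ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage import transform as sktransform

EPS = 1e-6
N_CLASSES = 3

PRESETS = {
    # name: (base channels, depth = number of pooling levels)
    "small": (8, 2),
    "medium": (16, 2),
    "large": (24, 3),
}


@dataclass(frozen=True)
class SegModelConfig:
    preset: str = "small"
    input_size: int = 224
    n_classes: int = N_CLASSES
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; use one of {list(PRESETS)}")
        if self.n_classes != N_CLASSES:
            raise ValueError("the segmenter is fixed at 3 classes (bg / disc / cup)")
        _, depth = PRESETS[self.preset]
        if self.input_size % (2**depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by {2**depth} "
                f"(downsampling factor of preset {self.preset!r})")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 2
    learning_rate: float = 5e-5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


# ----------------------------------------------------------------- layers


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(C, H, W) -> (C*9, H*W) column matrix for a 3x3 same-padded conv."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    v = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C, H, W, 3, 3)
    return v.reshape(c, h * w, 9).transpose(0, 2, 1).reshape(c * 9, h * w)


def _col2im3(dcols: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    d = dcols.reshape(c, 9, h, w)
    dxp = np.zeros((c, h + 2, w + 2), dtype=dcols.dtype)
    for ki in range(3):
        for kj in range(3):
            dxp[:, ki : ki + h, kj : kj + w] += d[:, ki * 3 + kj]
    return dxp[:, 1 : h + 1, 1 : w + 1]


class _Conv:
    """3x3 (same padding) or 1x1 convolution with bias."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.k = k
        self.cin = cin
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (cout, fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        cols = _im2col3(x) if self.k == 3 else x.reshape(c, h * w)
        self._cols, self._shape = cols, (c, h, w)
        out = self.w @ cols + self.b[:, None]
        return out.reshape(-1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        d2 = dout.reshape(dout.shape[0], h * w)
        self.dw += d2 @ self._cols.T
        self.db += d2.sum(axis=1)
        dcols = self.w.T @ d2
        if self.k == 3:
            return _col2im3(dcols, c, h, w)
        return dcols.reshape(c, h, w)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    def forward(self, x):
        c, h, w = x.shape
        xr = x.reshape(c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._shape = (c, h, w)
        return out

    def backward(self, dout):
        c, h, w = self._shape
        dxr = self._mask * dout[:, :, None, :, None]
        return dxr.reshape(c, h, w)


def _upsample2(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _downgrad2(dout):
    c, h, w = dout.shape
    return dout.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class _ConvBlock:
    """Two 3x3 conv + ReLU layers."""

    def __init__(self, cin, cout, rng):
        self.c1, self.r1 = _Conv(cin, cout, 3, rng), _ReLU()
        self.c2, self.r2 = _Conv(cout, cout, 3, rng), _ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dout):
        return self.c1.backward(self.r1.backward(
            self.c2.backward(self.r2.backward(dout))))

    def params(self):
        return self.c1.params() + self.c2.params()


# ------------------------------------------------------------------ model


class UNet:
    """U-shaped segmenter; see module docstring for the architecture."""

    def __init__(self, config: SegModelConfig):
        self.config = config
        base, depth = PRESETS[config.preset]
        self.depth = depth
        rng = np.random.default_rng(config.rng_seed)
        self.enc = []
        cin = 3
        for i in range(depth):
            cout = base * 2**i
            self.enc.append(_ConvBlock(cin, cout, rng))
            cin = cout
        self.bottleneck = _ConvBlock(cin, base * 2**depth, rng)
        self.pools = [_MaxPool2() for _ in range(depth)]
        self.dec = []
        cin = base * 2**depth
        for i in reversed(range(depth)):
            skip = base * 2**i
            self.dec.append(_ConvBlock(cin + skip, skip, rng))
            cin = skip
        self.head = _Conv(cin, config.n_classes, 1, rng)

    # -- parameter plumbing

    def params(self):
        out = []
        for block in [*self.enc, self.bottleneck, *self.dec, self.head]:
            out.extend(block.params())
        return out

    def num_params(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    # -- forward / backward

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (3, H, W) float32 in [0, 1] -> per-pixel class probabilities
        (n_classes, H, W), softmax-normalized along the class axis."""
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for block, skip in zip(self.dec, reversed(skips)):
            x = _upsample2(x)
            self._skip_channels.append((x.shape[0], skip.shape[0]))
            x = np.concatenate([x, skip], axis=0)
            x = block.forward(x)
        logits = self.head.forward(x)
        z = logits - logits.max(axis=0, keepdims=True)
        ez = np.exp(z)
        self._probs = ez / ez.sum(axis=0, keepdims=True)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the softmax probabilities."""
        p = self._probs
        dlogits = p * (dprobs - (dprobs * p).sum(axis=0, keepdims=True))
        dx = self.head.backward(dlogits)
        dskips = []
        for block, (c_up, c_skip) in zip(reversed(self.dec),
                                         reversed(self._skip_channels)):
            dx = block.backward(dx)
            dskips.append(dx[c_up:])
            dx = _downgrad2(dx[:c_up])
        dx = self.bottleneck.backward(dx)
        # dskips were collected finest level first; the encoder is walked
        # deepest level first, so pair them in reverse
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            dx = pool.backward(dx)
            dx = block.backward(dx + dskip)

    # -- persistence

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, (p, _) in enumerate(self.params()):
            arrays[f"p{i}"] = p
        meta = json.dumps({"preset": self.config.preset,
                           "input_size": self.config.input_size,
                           "n_classes": self.config.n_classes,
                           "rng_seed": self.config.rng_seed})
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        model = cls(SegModelConfig(**meta))
        for i, (p, _) in enumerate(model.params()):
            p[...] = data[f"p{i}"]
        return model


def build_model(config: SegModelConfig) -> UNet:
    """Construct a segmenter; initialization is deterministic per seed."""
    return UNet(config)


# ------------------------------------------------------------- dice loss


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    t = np.zeros((n_classes,) + target.shape, dtype=np.float32)
    for c in range(n_classes):
        t[c] = target == c
    return t


def dice_loss(pred_probs: np.ndarray, target_mask: np.ndarray,
              with_grad: bool = False):
    """Soft multi-class Dice loss, background included.

    ``pred_probs`` is (C, H, W) with class probabilities summing to 1 per
    pixel; ``target_mask`` is (H, W) with labels in {0..C-1}.  Returns the
    scalar loss, or (loss, dL/dprobs) when ``with_grad`` is set.
    """
    if pred_probs.shape[1:] != target_mask.shape:
        raise ValueError(
            f"shape mismatch: probs {pred_probs.shape} vs mask {target_mask.shape}")
    n_classes = pred_probs.shape[0]
    t = _one_hot(np.asarray(target_mask), n_classes)
    num = 2.0 * (pred_probs * t).sum(axis=(1, 2)) + EPS
    den = pred_probs.sum(axis=(1, 2)) + t.sum(axis=(1, 2)) + EPS
    loss = float(1.0 - (num / den).mean())
    if not with_grad:
        return loss
    # d(dice_c)/d(p_ci) = (2*t_ci*den_c - num_c) / den_c^2 ; loss = 1 - mean
    grad = -(2.0 * t * den[:, None, None] - num[:, None, None]) / (
        den[:, None, None] ** 2 * n_classes)
    return loss, grad.astype(np.float32)


# -------------------------------------------------------------- training


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def prepare_input(image: np.ndarray, input_size: int) -> np.ndarray:
    """8-bit RGB (H, W, 3) -> float32 (3, S, S) in [0, 1], bilinear resize."""
    img = np.asarray(image, dtype=np.float32)
    if img.shape[:2] != (input_size, input_size):
        img = sktransform.resize(img, (input_size, input_size), order=1,
                                 preserve_range=True, anti_aliasing=False)
    return (img / 255.0).transpose(2, 0, 1).astype(np.float32)


def prepare_target(mask: np.ndarray, input_size: int) -> np.ndarray:
    """Label mask resized to the model grid with nearest-neighbor."""
    mask = np.asarray(mask)
    if mask.shape != (input_size, input_size):
        mask = sktransform.resize(mask, (input_size, input_size), order=0,
                                  preserve_range=True,
                                  anti_aliasing=False).astype(mask.dtype)
    return mask


def train_model(model: UNet, samples, train_config: TrainConfig,
                ) -> list[float]:
    """Train in place on (image, mask) pairs; returns the per-epoch loss trace.

    ``samples`` is a sequence of FundusSample objects or (image, mask)
    tuples.  Shuffling, batching and every gradient step are deterministic
    under ``train_config.rng_seed``.
    """
    pairs = []
    for s in samples:
        image, mask = (s.image, s.mask) if hasattr(s, "image") else s
        pairs.append((prepare_input(image, model.config.input_size),
                      prepare_target(mask, model.config.input_size)))
    if not pairs:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(train_config.rng_seed)
    opt = _Adam(model.params(), train_config.learning_rate)
    trace = []
    for _ in range(train_config.epochs):
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for start in range(0, len(pairs), train_config.batch_size):
            batch = order[start : start + train_config.batch_size]
            model.zero_grad()
            batch_loss = 0.0
            for idx in batch:
                x, t = pairs[idx]
                probs = model.forward(x)
                loss, grad = dice_loss(probs, t, with_grad=True)
                model.backward(grad / len(batch))
                batch_loss += loss / len(batch)
            opt.step()
            epoch_losses.append(batch_loss)
        trace.append(float(np.mean(epoch_losses)))
    return trace


def predict_labelmap(model: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax label raster at the input image's original size.

    The image is resized to the model grid for inference; the hard label
    map is resized back with nearest-neighbor (labels are categorical and
    must never be interpolated).
    """
    h, w = np.asarray(image).shape[:2]
    x = prepare_input(image, model.config.input_size)
    probs = model.forward(x)
    labels = probs.argmax(axis=0).astype(np.uint8)
    if (h, w) != labels.shape:
        labels = sktransform.resize(labels, (h, w), order=0,
                                    preserve_range=True,
                                    anti_aliasing=False).astype(np.uint8)
    return labels
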