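"""A small U-type fully convolutional network for B-scan segmentation.

The architecture follows the usual encoder-decoder layout with short-circuit
(skip) connections: the encoding path halves the feature-map size at each
level to compute increasingly global features, the decoding path expands them
back and the skips re-inject local detail, and a final 1x1 convolution
classifies every sample into one of the 10 classes (vitreous, 8 retinal
layers, sub-RPE).

The network is implemented directly on numpy (im2col convolutions with
explicit backward passes, Adam updates). That keeps the package free of any
deep-learning framework dependency and is entirely adequate at the scale it
is used here: B-scans downscaled to 128 x 256 and a few thousand training
steps on a single CPU. Two input channels are used: normalised intensity and
a normalised axial-depth coordinate, the latter giving the net a cheap
positional anchor for layers whose reflectivity alone is ambiguous.

All randomness (weight init, shuffling) is driven by the seed in
:class:`ModelConfig`, so training runs are reproducible bit-for-bit on a
fixed backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelConfig", "UNet", "train", "segment_bscan", "segment", "dice_scores"]

N_CLASSES = 10


@dataclass
class ModelConfig:
    """Hyperparameters of the segmentation network."""

    depth: int = 3  # number of encoder levels (pooling steps)
    base_channels: int = 8
    learning_rate: float = 3e-3
    epochs: int = 30
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if min(self.base_channels, self.learning_rate, self.batch_size) <= 0:
            raise ValueError("all hyperparameters must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


# ---------------------------------------------------------------- primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C,H,W) -> (H*W, C*k*k) patch matrix, 'same' zero padding."""
    c, h, w = x.shape
    if k == 1:
        return x.reshape(c, h * w).T
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C,H,W,k,k)
    return win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * k * k)


class _Conv:
    """k x k same-padding convolution with ReLU option and explicit backward."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 k: int = 3, relu: bool = True) -> None:
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)
        self.k, self.relu = k, relu
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._mask: np.ndarray | None = None
        self._hw: tuple[int, int] = (0, 0)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c_out, c_in, k, _ = self.W.shape
        h, w = x.shape[1:]
        cols = _im2col(x, k)
        y = cols @ self.W.reshape(c_out, -1).T + self.b
        y = y.T.reshape(c_out, h, w)
        if self.relu:
            mask = y > 0
            y = np.where(mask, y, 0.0)
        if train:
            self._cols, self._hw = cols, (h, w)
            self._mask = mask if self.relu else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out, c_in, k, _ = self.W.shape
        h, w = self._hw
        if self._mask is not None:
            dy = np.where(self._mask, dy, 0.0)
        dyf = dy.reshape(c_out, h * w).T  # (HW, c_out)
        self.dW += (dyf.T @ self._cols).reshape(self.W.shape)
        self.db += dyf.sum(axis=0)
        # input gradient = convolution of dy with the rotated, transposed kernel
        w_rot = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in,c_out,k,k)
        cols_dy = _im2col(dy, k)
        dx = cols_dy @ w_rot.reshape(c_in, -1).T
        self._cols = self._mask = None
        return dx.T.reshape(c_in, h, w)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def _pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pool; returns (pooled, argmax indices) for the backward pass."""
    c, h, w = x.shape
    xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
    xr = xr.reshape(c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], idx


def _pool_back(dy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    c, h2, w2 = dy.shape
    out = np.zeros((c, h2, w2, 4), np.float32)
    np.put_along_axis(out, idx[..., None], dy[..., None], axis=-1)
    return out.reshape(c, h2, w2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h2 * 2, w2 * 2)


def _upsample(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample_back(dy: np.ndarray) -> np.ndarray:
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


# ---------------------------------------------------------------------- net


class UNet:
    """Encoder-decoder with skips; ``depth`` pooling levels, channel widths
    ``base * 2**level``. Input: (2, H, W); output logits: (10, H, W)."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, base = config.depth, config.base_channels
        ch = [base * 2 ** i for i in range(d + 1)]
        self.enc: list[list[_Conv]] = []
        c_prev = 2
        for i in range(d):
            self.enc.append([_Conv(rng, c_prev, ch[i]), _Conv(rng, ch[i], ch[i])])
            c_prev = ch[i]
        self.mid = [_Conv(rng, c_prev, ch[d]), _Conv(rng, ch[d], ch[d])]
        self.dec: list[list[_Conv]] = []
        c_prev = ch[d]
        for i in reversed(range(d)):
            self.dec.append(
                [_Conv(rng, c_prev + ch[i], ch[i]), _Conv(rng, ch[i], ch[i])]
            )
            c_prev = ch[i]
        self.head = _Conv(rng, c_prev, N_CLASSES, k=1, relu=False)
        self.loss_trajectory: list[float] = []
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- plumbing

    def _convs(self) -> list[_Conv]:
        out = [c for blk in self.enc for c in blk] + list(self.mid)
        out += [c for blk in self.dec for c in blk] + [self.head]
        return out

    def zero_grad(self) -> None:
        for conv in self._convs():
            conv.dW[:] = 0.0
            conv.db[:] = 0.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = self.config.depth
        if any((s % 2 ** d) for s in x.shape[1:]):
            raise ValueError(
                f"B-scan shape {x.shape[1:]} not divisible by 2**depth={2**d}"
            )
        skips, pools = [], []
        h = x.astype(np.float32)
        for blk in self.enc:
            for conv in blk:
                h = conv.forward(h, train)
            skips.append(h)
            h, idx = _pool(h)
            pools.append(idx)
        for conv in self.mid:
            h = conv.forward(h, train)
        for i, blk in enumerate(self.dec):
            h = _upsample(h)
            skip = skips[d - 1 - i]
            h = np.concatenate([h, skip], axis=0)
            for conv in blk:
                h = conv.forward(h, train)
        logits = self.head.forward(h, train)
        if train:
            self._pools = pools
            self._skip_ch = [s.shape[0] for s in skips]
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.config.depth
        g = self.head.backward(dlogits)
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(len(self.dec))):
            for conv in reversed(self.dec[i]):
                g = conv.backward(g)
            level = d - 1 - i
            n_up = g.shape[0] - self._skip_ch[level]
            skip_grads[level] = g[n_up:]
            g = _upsample_back(g[:n_up])
        for conv in reversed(self.mid):
            g = conv.backward(g)
        for level in reversed(range(d)):
            g = _pool_back(g, self._pools[level])
            g = g + skip_grads[level]
            for conv in reversed(self.enc[level]):
                g = conv.backward(g)

    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for conv in self._convs():
            for p, gr in conv.params:
                if i not in self._adam_state:
                    self._adam_state[i] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self._adam_state[i]
                m += (1 - beta1) * (gr - m)
                v += (1 - beta2) * (gr * gr - v)
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1

    # -- persistence

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for j, conv in enumerate(self._convs()):
            arrays[f"W{j}"] = conv.W
            arrays[f"b{j}"] = conv.b
        np.savez(path, **arrays)
        report = {
            "config": self.config.__dict__,
            "loss_trajectory": self.loss_trajectory,
        }
        path.with_suffix(".json").write_text(json.dumps(report, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        report = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**report["config"]))
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            for j, conv in enumerate(model._convs()):
                conv.W = z[f"W{j}"]
                conv.b = z[f"b{j}"]
        model.loss_trajectory = list(report["loss_trajectory"])
        return model


# ----------------------------------------------------------------- training


def _normalize(img: np.ndarray) -> np.ndarray:
    """Scale a B-scan to [0, ~1] by its 99.5th intensity percentile."""
    x = img.astype(np.float32)
    m = np.percentile(x, 99.5)
    if m > 0:
        x = np.clip(x / m, 0.0, 1.5)
    return x


def _with_coord(img: np.ndarray) -> np.ndarray:
    """Stack the normalised image with an axial-depth coordinate channel."""
    h, w = img.shape
    coord = np.broadcast_to(np.linspace(0.0, 1.0, w, dtype=np.float32), (h, w))
    return np.stack([img, coord])


def _softmax_ce(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    k, h, w = logits.shape
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)
    n = h * w
    onehot_p = p[labels, np.arange(h)[:, None], np.arange(w)[None, :]]
    loss = float(-np.log(np.maximum(onehot_p, 1e-12)).mean())
    dlogits = p.copy()
    dlogits[labels, np.arange(h)[:, None], np.arange(w)[None, :]] -= 1.0
    return loss, dlogits / n


def train(
    config: ModelConfig,
    training_set: list[tuple[np.ndarray, np.ndarray]],
) -> UNet:
    """Train the network on (B-scan, label image) pairs.

    Labels are integers 0..9 of the same shape as the B-scan. A class absent
    from the training labels triggers a warning, not a failure. Returns the
    model with its recorded per-epoch mean loss trajectory.
    """
    if len(training_set) < 8:
        raise ValueError("need at least 8 labeled B-scans")
    present = np.unique(np.concatenate([lab.ravel() for _, lab in training_set]))
    if any(lab.min() < 0 or lab.max() >= N_CLASSES for _, lab in training_set):
        raise ValueError("labels must lie in 0..9")
    missing = sorted(set(range(N_CLASSES)) - set(present.tolist()))
    if missing:
        import warnings

        warnings.warn(f"classes absent from training labels: {missing}", stacklevel=2)
    model = UNet(config)
    inputs = [_with_coord(_normalize(img)) for img, _ in training_set]
    labels = [lab.astype(np.int64) for _, lab in training_set]
    rng = np.random.default_rng(config.seed + 1)
    for _ in range(config.epochs):
        order = rng.permutation(len(inputs))
        losses = []
        for pos, j in enumerate(order):
            model.zero_grad()
            logits = model.forward(inputs[j], train=True)
            loss, dlogits = _softmax_ce(logits, labels[j])
            model.backward(dlogits)
            model.adam_step(config.learning_rate)
            losses.append(loss)
        model.loss_trajectory.append(float(np.mean(losses)))
    return model


def segment_bscan(model: UNet, img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment one B-scan; returns (labels (H,W) uint8, probs (H,W,10))."""
    logits = model.forward(_with_coord(_normalize(img)), train=False)
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)
    return logits.argmax(axis=0).astype(np.uint8), p.transpose(1, 2, 0)


def segment(model: UNet, volume, keep_scores: bool = False):
    """Segment every B-scan of a volume and stack the results.

    Returns a :class:`muroct.segmentation.ClassMap`. ``keep_scores=True``
    retains the softmax probabilities (memory: 10 floats per sample) for the
    boundary-projection step; with hard labels the projection is equivalent
    up to ties.
    """
    from .segmentation import ClassMap

    data = volume.intensities
    h = data.shape[0]
    labels = np.empty(data.shape, np.uint8)
    scores = (
        np.empty(data.shape + (N_CLASSES,), np.float32) if keep_scores else None
    )
    for i in range(h):
        lab, p = segment_bscan(model, data[i])
        labels[i] = lab
        if scores is not None:
            scores[i] = p
    return ClassMap(labels, scores)


def dice_scores(
    pred: np.ndarray, truth: np.ndarray, classes=range(1, 9)
) -> dict[int, float]:
    """Per-class Dice overlap between two label arrays (any matching shape)."""
    out = {}
    for c in classes:
        p = pred == c
        t = truth == c
        denom = p.sum() + t.sum()
        out[c] = float(2.0 * np.logical_and(p, t).sum() / denom) if denom else np.nan
    return out
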