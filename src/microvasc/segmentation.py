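"""Vessel segmentation with an ensemble of U-Nets.

Each ensemble member is a standard encoder–decoder U-Net with skip
connections (depth-3, base 16 channels by default — sized for CPU
training), trained with pixel-wise binary cross-entropy on random patches
with flip/rotation augmentation.  Members share the training data and
differ only in initialization and shuffle order; the ensemble probability
map is the arithmetic mean of the member maps.  Preprocessing is per-image
standardization of the green channel.

Evaluation metrics operate over FOV pixels only: Dice overlap
``2|P∩T| / (|P|+|T|)``, pixel accuracy, and a rank-based (Mann–Whitney)
ROC AUC of the probability map against the truth mask.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from . import nn
from .synth import FundusImage

__all__ = [
    "SegConfig",
    "SegEnsemble",
    "SegMetrics",
    "UNet",
    "train_segmentation_ensemble",
    "segment",
    "segment_with_disagreement",
    "binarize",
    "segmentation_metrics",
    "dice_coefficient",
]


@dataclass(frozen=True)
class SegConfig:
    ensemble_size: int = 3
    depth: int = 3
    base_channels: int = 16
    patch_size: int = 64
    epochs: int = 4  # passes over the training set (one random patch per image per pass)
    batch_size: int = 8
    learning_rate: float = 3e-3
    augment: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.patch_size % (2**self.depth) != 0:
            raise ValueError("patch_size must be a multiple of 2**depth")

    def member_seeds(self) -> list[int]:
        return [self.seed + 1000 * i for i in range(self.ensemble_size)]


def _preprocess(image) -> np.ndarray:
    """Green channel standardized per image; (1, H, W)."""
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image, dtype=float)
    if px.ndim == 3:
        px = px[:, :, 1]
    sd = px.std()
    px = (px - px.mean()) / (sd if sd > 1e-9 else 1.0)
    return px[None, :, :]


class _Concat:
    """Channel concatenation of a skip connection with the upsampled path."""

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._ca = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, dout: np.ndarray):
        return dout[:, : self._ca], dout[:, self._ca :]


class UNet:
    """Encoder–decoder with skip connections; single-channel logit output."""

    def __init__(self, depth: int = 3, base_channels: int = 16, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.enc: list[tuple[nn.Conv2d, nn.ReLU]] = []
        self.pools: list[nn.MaxPool2x2] = []
        c_in = 1
        ch = base_channels
        for _ in range(depth):
            self.enc.append((nn.Conv2d(c_in, ch, rng=rng), nn.ReLU()))
            self.pools.append(nn.MaxPool2x2())
            c_in = ch
            ch *= 2
        self.bottleneck = (nn.Conv2d(c_in, ch, rng=rng), nn.ReLU())
        self.ups: list[nn.Upsample2x] = []
        self.concats: list[_Concat] = []
        self.dec: list[tuple[nn.Conv2d, nn.ReLU]] = []
        c_up = ch
        for i in reversed(range(depth)):
            skip_ch = base_channels * (2**i)
            self.ups.append(nn.Upsample2x())
            self.concats.append(_Concat())
            self.dec.append((nn.Conv2d(skip_ch + c_up, skip_ch, rng=rng), nn.ReLU()))
            c_up = skip_ch
        self.head = nn.Conv2d(c_up, 1, k=1, rng=rng)

    def _layers(self):
        out = []
        for conv, relu in self.enc:
            out += [conv, relu]
        out += list(self.bottleneck)
        for conv, relu in self.dec:
            out += [conv, relu]
        out.append(self.head)
        return out

    def collect(self):
        return nn.collect_params(self._layers())

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for (conv, relu), pool in zip(self.enc, self.pools):
            x = relu.forward(conv.forward(x))
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck[1].forward(self.bottleneck[0].forward(x))
        for up, cat, (conv, relu), skip in zip(self.ups, self.concats, self.dec, reversed(skips)):
            x = up.forward(x)
            x = cat.forward(skip, x)
            x = relu.forward(conv.forward(x))
        return self.head.forward(x)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None])
        dskips = []
        for up, cat, (conv, relu) in zip(reversed(self.ups), reversed(self.concats), reversed(self.dec)):
            d = conv.backward(relu.backward(d))
            dskip, d = cat.backward(d)
            d = up.backward(d)
            dskips.append(dskip)
        d = self.bottleneck[0].backward(self.bottleneck[1].backward(d))
        dskips.reverse()
        for (conv, relu), pool, dskip in zip(reversed(self.enc), reversed(self.pools), dskips):
            d = pool.backward(d) + dskip
            d = conv.backward(relu.backward(d))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(x))


@dataclass
class SegEnsemble:
    members: list[UNet]
    config: SegConfig
    loss_traces: list[list[float]]

    @property
    def fingerprint(self) -> str:
        params = []
        for m in self.members:
            params.extend(m.collect()[0])
        return nn.params_fingerprint(params)

    def save(self, path: str | Path) -> None:
        blobs = []
        for m in self.members:
            params, _ = m.collect()
            blobs.append([p.copy() for p in params])
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "loss_traces": self.loss_traces, "params": blobs}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SegEnsemble":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        cfg = blob["config"]
        members = []
        for saved in blob["params"]:
            net = UNet(cfg.depth, cfg.base_channels, np.random.default_rng(0))
            params, _ = net.collect()
            for p, s in zip(params, saved):
                p[...] = s
            members.append(net)
        return cls(members, cfg, blob["loss_traces"])


@dataclass
class SegMetrics:
    dice: float
    pixel_accuracy: float
    auc: float | None
    both_empty: bool = False


def _augment(patch_x, patch_y, rng):
    k = int(rng.integers(0, 4))
    if k:
        patch_x = np.rot90(patch_x, k, axes=(1, 2))
        patch_y = np.rot90(patch_y, k, axes=(0, 1))
    if rng.uniform() < 0.5:
        patch_x = patch_x[:, ::-1, :]
        patch_y = patch_y[::-1, :]
    if rng.uniform() < 0.5:
        patch_x = patch_x[:, :, ::-1]
        patch_y = patch_y[:, ::-1]
    return np.ascontiguousarray(patch_x), np.ascontiguousarray(patch_y)


def train_segmentation_ensemble(images, masks, config: SegConfig | None = None) -> SegEnsemble:
    """Train K U-Nets on paired images and binary masks.

    All members see the same data with distinct seeds and shuffle orders.
    Raises on any image/mask shape mismatch (naming the pair) and with
    fewer than 4 training pairs.
    """
    cfg = config or SegConfig()
    if len(images) != len(masks):
        raise ValueError("images and masks lengths disagree")
    if len(images) < 4:
        raise ValueError("need at least 4 training pairs")
    xs = [_preprocess(im) for im in images]
    ys = [np.asarray(m, dtype=float) for m in masks]
    for i, (x, y) in enumerate(zip(xs, ys)):
        if x.shape[1:] != y.shape:
            raise ValueError(f"image/mask shape mismatch at pair {i}: {x.shape[1:]} vs {y.shape}")

    members, traces = [], []
    for seed in cfg.member_seeds():
        rng = np.random.default_rng(seed)
        net = UNet(cfg.depth, cfg.base_channels, rng)
        params, grads = net.collect()
        opt = nn.Adam(params, grads, lr=cfg.learning_rate)
        trace = []
        n = len(xs)
        p = cfg.patch_size
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                bx, by = [], []
                for j in idx:
                    h, w = ys[j].shape
                    r0 = int(rng.integers(0, max(1, h - p + 1)))
                    c0 = int(rng.integers(0, max(1, w - p + 1)))
                    px = xs[j][:, r0 : r0 + p, c0 : c0 + p]
                    py = ys[j][r0 : r0 + p, c0 : c0 + p]
                    if cfg.augment:
                        px, py = _augment(px, py, rng)
                    bx.append(px)
                    by.append(py)
                bx = np.stack(bx)
                by = np.stack(by)
                logits = net.forward(bx)
                loss, dlogits = nn.bce_with_logits(logits, by)
                opt.zero_grad()
                net.backward(dlogits)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            trace.append(epoch_loss / max(n_batches, 1))
        members.append(net)
        traces.append(trace)
    return SegEnsemble(members, cfg, traces)


def _pad_to_multiple(x: np.ndarray, mult: int):
    h, w = x.shape[-2:]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="edge")
    return x, (h, w)


def segment(ensemble: SegEnsemble, image) -> np.ndarray:
    """Ensemble vessel-probability map: arithmetic mean of member maps."""
    probs = _member_probs(ensemble, image)
    return probs.mean(axis=0)


def segment_with_disagreement(ensemble: SegEnsemble, image):
    """Mean probability map plus pixel-wise member disagreement (SD across
    members; identically zero for an ensemble of one)."""
    probs = _member_probs(ensemble, image)
    return probs.mean(axis=0), probs.std(axis=0)


def _member_probs(ensemble: SegEnsemble, image) -> np.ndarray:
    x = _preprocess(image)
    mult = 2**ensemble.config.depth
    xp, (h, w) = _pad_to_multiple(x, mult)
    out = np.stack([m.predict_proba(xp[None])[0] for m in ensemble.members])
    return out[:, :h, :w]


def binarize(prob: np.ndarray, threshold: float = 0.5, fov: np.ndarray | None = None) -> np.ndarray:
    """Vessel mask: probability >= threshold, clipped to the FOV."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    mask = np.asarray(prob) >= threshold
    if fov is not None:
        mask = mask & np.asarray(fov, dtype=bool)
    return mask


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, fov: np.ndarray | None = None):
    """Dice overlap over FOV pixels; (dice, both_empty flag)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        pred = pred & fov
        truth = truth & fov
    p, t = int(pred.sum()), int(truth.sum())
    if p == 0 and t == 0:
        return 1.0, True
    inter = int((pred & truth).sum())
    return 2.0 * inter / (p + t), False


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Mann–Whitney rank AUC; None when only one class is present."""
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(np.asarray(scores, dtype=float))
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def segmentation_metrics(prob: np.ndarray, pred: np.ndarray, truth: np.ndarray,
                         fov: np.ndarray) -> SegMetrics:
    """Dice, pixel accuracy, and rank AUC over FOV pixels."""
    fov = np.asarray(fov, dtype=bool)
    if not (prob.shape == pred.shape == truth.shape == fov.shape):
        raise ValueError("shape mismatch among prob/pred/truth/fov")
    dice, both_empty = dice_coefficient(pred, truth, fov)
    pf = np.asarray(pred, dtype=bool)[fov]
    tf = np.asarray(truth, dtype=bool)[fov]
    acc = float((pf == tf).mean())
    auc = rank_auc(np.asarray(prob, dtype=float)[fov], tf)
    return SegMetrics(dice=dice, pixel_accuracy=acc, auc=auc, both_empty=both_empty)
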