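"""Automated fundus image quality control.

A small convolutional classifier (three conv blocks, global average
pooling, a linear head) is trained to flag poor-quality images — the
blurred, occluded, or over-exposed frames that would corrupt downstream
vessel metrics.  Images are resized to a fixed input size and the
green channel is standardized per image before entering the network.
Training is deterministic given its seed.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn
from .synth import FundusImage

__all__ = ["QcConfig", "QcModel", "QcMetrics", "train_qc", "predict_qc", "evaluate_qc"]

LABELS = ("good", "poor")


@dataclass(frozen=True)
class QcConfig:
    input_size: int = 64
    channels: tuple[int, int, int] = (8, 16, 32)
    epochs: int = 16
    batch_size: int = 16
    learning_rate: float = 2e-3
    threshold: float = 0.5  # call "poor" when probability >= threshold


@dataclass
class QcMetrics:
    """Confusion-table metrics at a stated threshold ("poor" is positive)."""

    sensitivity: float | None
    specificity: float | None
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int


def _preprocess(image, size: int) -> np.ndarray:
    """Two-channel green input: fixed-scale and per-image standardized.

    The fixed-scale channel preserves absolute brightness (over-exposure
    and occlusion shift it); the standardized channel preserves local
    structure independently of illumination.  Returns (2, size, size).
    """
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image, dtype=float)
    if px.ndim == 3:
        px = px[:, :, 1]
    elif px.ndim != 2:
        raise ValueError("expected an RGB or single-channel image")
    if px.shape != (size, size):
        px = resize(px, (size, size), order=1, anti_aliasing=True, preserve_range=True)
    fixed = (px - 0.5) / 0.25
    sd = px.std()
    standardized = (px - px.mean()) / (sd if sd > 1e-9 else 1.0)
    return np.stack([fixed, standardized])


class _QcNet:
    def __init__(self, channels: tuple[int, int, int], rng: np.random.Generator):
        c1, c2, c3 = channels
        self.layers = [
            nn.Conv2d(2, c1, rng=rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(c1, c2, rng=rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(c2, c3, rng=rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.GlobalAvgPool(), nn.Linear(c3, 1, rng=rng),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        d = dlogit[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)


@dataclass
class QcModel:
    """Trained quality-control classifier plus its training fingerprint."""

    net: _QcNet
    config: QcConfig
    loss_trace: list[float]
    fingerprint: str

    def predict_proba(self, image) -> float:
        return predict_qc(self, image)

    def save(self, path: str | Path) -> None:
        params, _ = nn.collect_params(self.net.layers)
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "loss_trace": self.loss_trace,
                         "fingerprint": self.fingerprint,
                         "params": [p.copy() for p in params]}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "QcModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        net = _QcNet(blob["config"].channels, np.random.default_rng(0))
        params, _ = nn.collect_params(net.layers)
        for p, saved in zip(params, blob["params"]):
            p[...] = saved
        return cls(net, blob["config"], blob["loss_trace"], blob["fingerprint"])


def train_qc(images, labels, config: QcConfig | None = None, seed: int = 0) -> QcModel:
    """Train the quality classifier on labelled images.

    ``labels`` are "good"/"poor" strings (or 0/1 with 1 = poor).  Requires
    at least two examples of each class.  Deterministic given ``seed``.
    """
    cfg = config or QcConfig()
    if len(images) == 0:
        raise ValueError("empty training set")
    y = np.array([1.0 if (lab == "poor" or lab == 1) else 0.0 for lab in labels])
    if len(y) != len(images):
        raise ValueError("images and labels lengths disagree")
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 examples per class")

    rng = np.random.default_rng(seed)
    x = np.stack([_preprocess(im, cfg.input_size) for im in images])
    net = _QcNet(cfg.channels, rng)
    params, grads = nn.collect_params(net.layers)
    opt = nn.Adam(params, grads, lr=cfg.learning_rate)
    trace: list[float] = []
    n = len(images)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(x[idx])
            loss, dlogit = nn.bce_with_logits(logits, y[idx])
            opt.zero_grad()
            net.backward(dlogit)
            opt.step()
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
    return QcModel(net, cfg, trace, nn.params_fingerprint(params))


def predict_qc(model: QcModel, image) -> float:
    """Probability in [0, 1] that the image is poor quality."""
    x = _preprocess(image, model.config.input_size)[None]
    return float(nn.sigmoid(model.net.forward(x))[0])


def predict_qc_batch(model: QcModel, images) -> np.ndarray:
    x = np.stack([_preprocess(im, model.config.input_size) for im in images])
    return nn.sigmoid(model.net.forward(x))


def evaluate_qc(probs, labels, threshold: float = 0.5) -> QcMetrics:
    """Confusion-table sensitivity/specificity at ``threshold``.

    "poor" is the positive class; an image is called poor when
    ``prob >= threshold``.  With no positives (or no negatives) in
    ``labels`` the undefined metric is reported as None, not 0.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.array([1 if (lab == "poor" or lab == 1) else 0 for lab in labels])
    if probs.shape[0] != y.shape[0]:
        raise ValueError("probs and labels lengths disagree")
    called = probs >= threshold
    tp = int(np.sum(called & (y == 1)))
    fn = int(np.sum(~called & (y == 1)))
    tn = int(np.sum(~called & (y == 0)))
    fp = int(np.sum(called & (y == 0)))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return QcMetrics(sens, spec, threshold, tp, fp, tn, fn)
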