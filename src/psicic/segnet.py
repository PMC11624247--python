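"""U-Net-style semantic segmentation of plate images into three classes.

The network follows the U-Net pattern — a contracting path of double
3x3 convolution blocks with 2x2 max pooling, an expanding path of
nearest-neighbor upsampling with skip concatenations — with two departures:
every convolution is same-padded so the output segmentation has the same
spatial resolution as the input image, and the final 1x1 convolution emits
three feature channels (background, red colony, white colony). A softmax
over the channels gives per-pixel class probabilities; the predicted label
is the per-pixel argmax, encoded with the module-wide 0/128/255 codes.

Training minimizes mean pixelwise cross-entropy with Adam. A sklearn-style
estimator (`UNetSegmenter`) wraps build/train/predict; the module-level
functions are the thin functional surface over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .masks import classes_to_codes, codes_to_classes

__all__ = [
    "SegModelConfig",
    "TrainConfig",
    "TrainReport",
    "UNet",
    "build_model",
    "train_model",
    "predict_mask",
    "save_weights",
    "load_weights",
    "UNetSegmenter",
]

WEIGHTS_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SegModelConfig:
    input_size: int = 1024
    n_classes: int = 3
    encoder_depth: int = 4
    base_channels: int = 64
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_classes != 3:
            raise ValueError("segmentation model is defined for exactly 3 classes")
        if self.encoder_depth < 1 or self.base_channels < 1:
            raise ValueError("encoder_depth and base_channels must be >= 1")
        if self.input_size % (2**self.encoder_depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"2^encoder_depth = {2 ** self.encoder_depth}"
            )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 24
    batch_size: int = 2
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    lr_schedule: str = "cosine"  # "cosine" (annealed to 0) or "constant"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


@dataclass
class TrainReport:
    """Per-epoch loss/accuracy history of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


class UNet:
    """Same-padded U-Net over (N, 3, H, W) inputs; see module docstring."""

    def __init__(self, cfg: SegModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        d, base = cfg.encoder_depth, cfg.base_channels
        ch = [base * 2**i for i in range(d + 1)]

        self.enc_blocks: list[list] = []
        c_in = 3
        for lvl in range(d):
            self.enc_blocks.append(
                [nn.Conv2D(c_in, ch[lvl], 3, rng), nn.ReLU(), nn.Conv2D(ch[lvl], ch[lvl], 3, rng), nn.ReLU()]
            )
            c_in = ch[lvl]
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = [
            nn.Conv2D(ch[d - 1], ch[d], 3, rng), nn.ReLU(), nn.Conv2D(ch[d], ch[d], 3, rng), nn.ReLU()
        ]
        self.ups = [nn.Upsample2() for _ in range(d)]
        self.dec_blocks: list[list] = []
        for lvl in range(d - 1, -1, -1):
            c_above = ch[lvl + 1]
            self.dec_blocks.append(
                [
                    nn.Conv2D(c_above, ch[lvl], 3, rng),  # up-convolution after upsample
                    nn.ReLU(),
                    # post-concat block: skip (ch[lvl]) + upsampled (ch[lvl])
                    nn.Conv2D(2 * ch[lvl], ch[lvl], 3, rng),
                    nn.ReLU(),
                    nn.Conv2D(ch[lvl], ch[lvl], 3, rng),
                    nn.ReLU(),
                ]
            )
        self.head = nn.Conv2D(base, cfg.n_classes, 1, rng)
        self._skip_channels = ch

    def _all_layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.bottleneck
        for blk in self.dec_blocks:
            yield from blk
        yield self.head

    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 3, H, W) float32 in [0, 1] -> logits (N, n_classes, H, W)."""
        if x.shape[2] % (2**self.cfg.encoder_depth) or x.shape[3] % (2**self.cfg.encoder_depth):
            raise ValueError("input spatial size must be divisible by 2^encoder_depth")
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                h = layer.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for layer in self.bottleneck:
            h = layer.forward(h, train)
        self._concat_splits = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            h = blk[1].forward(blk[0].forward(h, train), train)
            self._concat_splits.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            for layer in blk[2:]:
                h = layer.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dskips = []
        for blk, up, split in zip(
            reversed(self.dec_blocks), reversed(self.ups), reversed(self._concat_splits)
        ):
            for layer in reversed(blk[2:]):
                dh = layer.backward(dh)
            dskip, dh = dh[:, :split], dh[:, split:]
            dskips.append(dskip)
            dh = blk[0].backward(blk[1].backward(dh))
            dh = up.backward(dh)
        for layer in reversed(self.bottleneck):
            dh = layer.backward(dh)
        # dskips were collected for skips[0], skips[1], ... in that order
        for blk, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dh = pool.backward(dh) + dskip
            for layer in reversed(blk):
                dh = layer.backward(dh)

    # weight (de)serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._all_layers()):
            if isinstance(layer, nn.Conv2D):
                out[f"w{i}"] = layer.w
                out[f"b{i}"] = layer.b
        return out

    def load_state_arrays(self, arrays) -> None:
        for i, layer in enumerate(self._all_layers()):
            if isinstance(layer, nn.Conv2D):
                layer.w = np.asarray(arrays[f"w{i}"], dtype=np.float32)
                layer.b = np.asarray(arrays[f"b{i}"], dtype=np.float32)


def build_model(cfg: SegModelConfig) -> UNet:
    """Build an untrained segmentation network for ``cfg``."""
    return UNet(cfg)


def _to_batches(images: np.ndarray) -> np.ndarray:
    """8-bit RGB images -> (N, 3, H, W) float32 centered to [-1, 1].

    Centering matters: the informative color differences are small relative
    to the common brightness offset, and a zero-mean input range keeps the
    first-layer units sensitive to them.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[-1] == 3:  # (N,H,W,3) -> (N,3,H,W)
        x = x.transpose(0, 3, 1, 2)
    if x.max() > 1.5:
        x = x / 255.0
    return np.ascontiguousarray(x * 2.0 - 1.0)


def _dataset_arrays(dataset):
    """dataset: sequence of (image, class_mask) -> (x, y) arrays."""
    imgs, ys = [], []
    for image, mask in dataset:
        imgs.append(np.asarray(image))
        ys.append(codes_to_classes(mask))
    return _to_batches(np.stack(imgs)), np.stack(ys)


def _eval_model(model: UNet, x: np.ndarray, y: np.ndarray, batch_size: int):
    losses, correct, total = [], 0, 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * len(x[i : i + batch_size]))
        pred = logits.argmax(axis=1)
        correct += int((pred == y[i : i + batch_size]).sum())
        total += pred.size
    return float(np.sum(losses) / len(x)), correct / total


def train_model(model: UNet, train_set, val_set, cfg: TrainConfig):
    """Train ``model`` by minimizing pixelwise cross-entropy.

    ``train_set`` and ``val_set`` are sequences of (RGB image, label mask)
    pairs at the model resolution. Returns ``(model, TrainReport)``; the
    model keeps the weights of the epoch with the lowest validation loss
    (training loss when no validation set is given). ``cfg.epochs == 0``
    leaves the weights untouched and the history empty.
    """
    cfg.validate()
    report = TrainReport()
    if cfg.epochs == 0:
        return model, report
    if len(train_set) == 0:
        raise ValueError("empty training set")
    x_tr, y_tr = _dataset_arrays(train_set)
    has_val = val_set is not None and len(val_set) > 0
    if has_val:
        x_va, y_va = _dataset_arrays(val_set)

    opt = nn.Adam(lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.rng_seed)
    best_loss, best_state = np.inf, None
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs))
        order = rng.permutation(len(x_tr))
        ep_loss, correct, total = 0.0, 0, 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step(model.params())
            ep_loss += loss * len(sel)
            correct += int((logits.argmax(axis=1) == yb).sum())
            total += yb.size
        report.train_loss.append(ep_loss / len(x_tr))
        report.train_accuracy.append(correct / total)
        if has_val:
            vl, va = _eval_model(model, x_va, y_va, cfg.batch_size)
            report.val_loss.append(vl)
            report.val_accuracy.append(va)
            track = vl
        else:
            track = report.train_loss[-1]
        if track < best_loss:
            best_loss = track
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, report


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over class probabilities, as a 0/128/255 label mask."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if img.shape[0] != model.cfg.input_size or img.shape[1] != model.cfg.input_size:
        raise ValueError(
            f"image size {img.shape[:2]} does not match model input size "
            f"{model.cfg.input_size}"
        )
    logits = model.forward(_to_batches(img), train=False)
    return classes_to_codes(logits.argmax(axis=1)[0])


def save_weights(path, model: UNet, report: TrainReport | None = None) -> None:
    header = {
        "format_version": WEIGHTS_FORMAT_VERSION,
        "config": model.cfg.__dict__,
    }
    arrays = dict(model.state_arrays())
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    if report is not None:
        Path(str(path)).with_suffix(".report.json").write_text(report.to_json())


def load_weights(path) -> UNet:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header["format_version"] != WEIGHTS_FORMAT_VERSION:
            raise ValueError(f"unsupported weights format {header['format_version']}")
        model = UNet(SegModelConfig(**header["config"]))
        model.load_state_arrays(data)
    return model


class UNetSegmenter(BaseEstimator):
    """Sklearn-style wrapper: fit on (images, masks), predict label masks.

    Parameters mirror `SegModelConfig` and `TrainConfig`. Fitted attributes:
    ``model_`` (the trained network) and ``report_`` (per-epoch history).
    """

    def __init__(
        self,
        input_size: int = 256,
        encoder_depth: int = 2,
        base_channels: int = 8,
        epochs: int = 8,
        batch_size: int = 4,
        learning_rate: float = 1e-3,
        rng_seed: int = 0,
    ):
        self.input_size = input_size
        self.encoder_depth = encoder_depth
        self.base_channels = base_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.rng_seed = rng_seed

    def fit(self, X, y, X_val=None, y_val=None):
        """X: sequence of RGB images; y: matching label masks."""
        cfg = SegModelConfig(
            input_size=self.input_size,
            encoder_depth=self.encoder_depth,
            base_channels=self.base_channels,
            rng_seed=self.rng_seed,
        )
        tcfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            rng_seed=self.rng_seed,
        )
        model = build_model(cfg)
        train_set = list(zip(X, y))
        val_set = list(zip(X_val, y_val)) if X_val is not None else []
        self.model_, self.report_ = train_model(model, train_set, val_set, tcfg)
        return self

    def predict(self, X):
        return [predict_mask(self.model_, img) for img in X]

    def score(self, X, y):
        """Mean pixel accuracy against ground-truth masks."""
        preds = self.predict(X)
        accs = [float((p == np.asarray(t)).mean()) for p, t in zip(preds, y)]
        return float(np.mean(accs))
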