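"""Simplified five-layer DCNN for classifying segmented tumor ROIs.

Five blocks of [3x3(x3) same-padded stride-1 convolution -> batch
normalization -> ReLU -> 2x max-pooling with stride 2] reduce a
32-extent input to extent 1 (32, 16, 8, 4, 2, 1) while the filter
ladder grows 8-16-32-64-128; a 64-neuron fully connected ReLU layer and
a softmax output produce class probabilities.  The default task is
tumor-grade classification (high- vs low-grade glioma, 2 classes); any
number of classes >= 2 is supported, e.g. a four-class tissue mode
(necrosis / edema / non-enhancing / enhancing, with ROIs taken per
ground-truth subregion).  ROIs are 3-D volumes by default; a 2-D slice
mode (``spatial_dims=2``) is available.

Training: Adam, categorical cross-entropy, same default recipe as the
segmenter (learning rate 1e-3, batch 16, L2 4e-4), reproducible from
``random_state``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .errors import ConfigError, DataError, ShapeError
from .preprocess import resample


@dataclasses.dataclass
class ClassifierConfig:
    """Architecture hyperparameters of the DCNN."""

    n_conv_layers: int = 5
    filters: tuple = (8, 16, 32, 64, 128)
    dense_units: int = 64
    n_classes: int = 2
    input_channels: int = 4
    spatial_dims: int = 3

    def __post_init__(self):
        self.filters = tuple(int(f) for f in self.filters)
        if len(self.filters) != self.n_conv_layers:
            raise ConfigError(
                f"need {self.n_conv_layers} filter counts, got {self.filters}")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.spatial_dims not in (2, 3):
            raise ConfigError("spatial_dims must be 2 or 3")


@dataclasses.dataclass
class RoiSample:
    """A masked-and-cropped multi-channel ROI ready for classification."""

    tensor: np.ndarray  # (channels, *spatial)
    label: object = None
    empty: bool = False
    bbox: tuple = None  # ((x0,x1),(y0,y1),(z0,z1)) half-open, or None
    provenance: str = ""


def extract_roi(scan_tensor: np.ndarray, mask, out_extent: int = None) -> RoiSample:
    """Mask, crop and resample a scan tensor to the classifier input grid.

    Intensities outside the mask are zeroed; the tight bounding box of
    the mask is cropped and each channel resampled (trilinear) back to
    the input spatial shape (or a cube of ``out_extent``).  An empty
    mask yields an all-zero tensor flagged ``empty``.
    """
    x = np.asarray(scan_tensor, dtype=np.float64)
    m = np.asarray(getattr(mask, "mask", mask))
    if x.ndim != 4:
        raise ShapeError(f"expected (channels, x, y, z) tensor, got {x.shape}")
    if m.shape != x.shape[1:]:
        raise ShapeError(f"mask shape {m.shape} != scan spatial shape {x.shape[1:]}")
    target = x.shape[1:] if out_extent is None else (int(out_extent),) * 3
    if not m.any():
        return RoiSample(tensor=np.zeros((x.shape[0],) + tuple(target), dtype=np.float32),
                         empty=True, bbox=None)
    masked = x * (m > 0)
    idx = np.nonzero(m)
    bbox = tuple((int(a.min()), int(a.max()) + 1) for a in idx)
    crop = masked[(slice(None),) + tuple(slice(a, b) for a, b in bbox)]
    channels = [resample(c, target, kind="intensity") for c in crop]
    return RoiSample(tensor=np.stack(channels, axis=0).astype(np.float32),
                     empty=False, bbox=bbox)


class _CNNCore:
    """conv->BN->ReLU->pool blocks, then dense(64, ReLU) and softmax logits."""

    def __init__(self, cfg: ClassifierConfig, input_extent: int, rng,
                 dtype=np.float32):
        nd = cfg.spatial_dims
        self.blocks = []
        c = cfg.input_channels
        ext = input_extent
        for bi, f in enumerate(cfg.filters):
            self.blocks.append({
                "conv": _nn.ConvND(c, f, 3, nd, rng, dtype, needs_dx=bi > 0),
                "bn": _nn.BatchNorm(f, dtype=dtype),
                "act": _nn.ReLU(),
                "pool": _nn.MaxPoolND(nd),
            })
            c = f
            ext //= 2
        self.flatten = _nn.Flatten()
        flat = c * ext ** nd
        self.dense1 = _nn.Dense(flat, cfg.dense_units, rng, dtype)
        self.act1 = _nn.ReLU()
        self.dense2 = _nn.Dense(cfg.dense_units, cfg.n_classes, rng, dtype)

    def layers(self):
        out = []
        for b in self.blocks:
            out.extend(b.values())
        out += [self.flatten, self.dense1, self.act1, self.dense2]
        return out

    def n_parameters(self) -> int:
        return _nn.n_parameters(self.layers())

    def describe(self, input_extent: int):
        stages, ext = [], input_extent
        for i, b in enumerate(self.blocks):
            stages.append({"stage": f"block{i}", "extent_in": ext, "extent_out": ext // 2,
                           "channels_in": b["conv"].c_in, "channels_out": b["conv"].c_out})
            ext //= 2
        stages.append({"stage": "dense", "units": self.dense1.W.value.shape[1]})
        stages.append({"stage": "softmax", "units": self.dense2.W.value.shape[1]})
        return stages

    def forward(self, x, train=False):
        h = x
        for b in self.blocks:
            h = b["conv"].forward(h, train)
            h = b["bn"].forward(h, train)
            h = b["act"].forward(h, train)
            h = b["pool"].forward(h, train)
        h = self.flatten.forward(h, train)
        h = self.act1.forward(self.dense1.forward(h, train), train)
        return self.dense2.forward(h, train)  # logits (B, n_classes)

    def backward(self, dlogits):
        d = self.dense2.backward(dlogits)
        d = self.dense1.backward(self.act1.backward(d))
        d = self.flatten.backward(d)
        for b in reversed(self.blocks):
            d = b["pool"].backward(d)
            d = b["act"].backward(d)
            d = b["bn"].backward(d)
            d = b["conv"].backward(d)
        return d


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style DCNN classifier over ROI tensors.

    ``fit(X, y)`` takes ``(n, channels, *spatial)`` tensors (cubic
    extent divisible by 2^n_conv_layers) and arbitrary class labels;
    ``classes_`` follows the usual sklearn convention.
    """

    def __init__(self, filters=(8, 16, 32, 64, 128), dense_units=64,
                 spatial_dims=3, learning_rate=1e-3, epochs=30, batch_size=16,
                 l2_lambda=4e-4, random_state=0):
        self.filters = filters
        self.dense_units = dense_units
        self.spatial_dims = spatial_dims
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.l2_lambda = l2_lambda
        self.random_state = random_state

    def _config(self, n_classes, input_channels):
        return ClassifierConfig(n_conv_layers=len(tuple(self.filters)),
                                filters=tuple(self.filters),
                                dense_units=self.dense_units, n_classes=n_classes,
                                input_channels=input_channels,
                                spatial_dims=self.spatial_dims)

    def build(self, input_extent=32, n_classes=2, input_channels=4):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        cfg = self._config(n_classes, input_channels)
        if input_extent % (2 ** cfg.n_conv_layers) != 0:
            raise ConfigError(
                f"input extent {input_extent} not divisible by 2^{cfg.n_conv_layers}")
        rng = np.random.default_rng(self.random_state or 0)
        self.model_ = _CNNCore(cfg, input_extent, rng)
        self.input_extent_ = int(input_extent)
        self.n_parameters_ = self.model_.n_parameters()
        return self

    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        want = 2 + self.spatial_dims
        if X.ndim == want - 1:
            X = X[None]
        if X.ndim != want:
            raise ShapeError(f"expected (n, channels, *spatial), got {X.shape}")
        ext = X.shape[2]
        if any(s != ext for s in X.shape[2:]):
            raise ShapeError(f"expected cubic spatial extent, got {X.shape[2:]}")
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        if X.shape[0] == 0 or y.shape[0] != X.shape[0]:
            raise DataError(f"bad training set: {X.shape[0]} tensors, {y.shape} labels")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise DataError("training set must contain >= 2 classes")
        self.build(input_extent=X.shape[2], n_classes=len(self.classes_),
                   input_channels=X.shape[1])
        xl = np.moveaxis(X, 1, -1)
        rng = np.random.default_rng((self.random_state or 0) + 1)
        params = _nn.collect_params(self.model_.layers())
        opt = _nn.Adam(params, lr=self.learning_rate, l2=self.l2_lambda)

        n = xl.shape[0]
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = xl[idx], y_idx[idx]
                logits = self.model_.forward(xb, train=True)
                loss, grad, p = _nn.softmax_ce_loss_grad(logits, yb, len(self.classes_))
                opt.zero_grad()
                self.model_.backward(grad)
                opt.step()
                losses.append(loss)
                correct += int(np.count_nonzero(p.argmax(axis=1) == yb))
            history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                            "accuracy": correct / n})
        self.history_ = pd.DataFrame(history)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise DataError("model is not built; call fit()")
        X = self._check_X(X)
        if X.shape[2] != self.input_extent_:
            raise ShapeError(
                f"extent {X.shape[2]} != model input extent {self.input_extent_}")
        out = []
        for start in range(0, X.shape[0], max(1, int(self.batch_size))):
            xb = np.moveaxis(X[start:start + max(1, int(self.batch_size))], 1, -1)
            logits = self.model_.forward(xb, train=False)
            out.append(_nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- persistence -------------------------------------------------------
    def save(self, path):
        arrays = {}
        for i, p in enumerate(_nn.collect_params(self.model_.layers())):
            arrays[f"p{i}"] = p.value
        for i, b in enumerate(self.model_.blocks):
            arrays[f"bn{i}_mean"] = b["bn"].running_mean
            arrays[f"bn{i}_var"] = b["bn"].running_var
        meta = json.dumps({"params": self.get_params(),
                           "input_extent": self.input_extent_,
                           "classes": np.asarray(self.classes_).tolist(),
                           "input_channels": self.model_.blocks[0]["conv"].c_in})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "CNNClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            est = cls(**meta["params"])
            est.classes_ = np.asarray(meta["classes"])
            est.build(input_extent=meta["input_extent"],
                      n_classes=len(est.classes_),
                      input_channels=meta["input_channels"])
            for i, p in enumerate(_nn.collect_params(est.model_.layers())):
                p.value[...] = data[f"p{i}"]
            for i, b in enumerate(est.model_.blocks):
                b["bn"].running_mean[...] = data[f"bn{i}_mean"]
                b["bn"].running_var[...] = data[f"bn{i}_var"]
        return est


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def build_classifier(cfg: ClassifierConfig = None, input_extent: int = 32,
                     random_state: int = 0) -> CNNClassifier:
    cfg = cfg or ClassifierConfig()
    est = CNNClassifier(filters=cfg.filters, dense_units=cfg.dense_units,
                        spatial_dims=cfg.spatial_dims, random_state=random_state)
    return est.build(input_extent=input_extent, n_classes=cfg.n_classes,
                     input_channels=cfg.input_channels)


def train_classifier(est: CNNClassifier, samples, labels) -> CNNClassifier:
    return est.fit(np.stack([np.asarray(s.tensor if isinstance(s, RoiSample) else s)
                             for s in samples]), labels)


def classify(est: CNNClassifier, tensor) -> np.ndarray:
    """Class probability vector for one ROI tensor."""
    return est.predict_proba(np.asarray(tensor)[None])[0]
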