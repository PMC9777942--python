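"""Lightweight 3-D U-Net for whole-tumor segmentation.

The network maps a four-channel cubic volume (default 32^3) to a voxel
probability map of the tumor region.  The encoder is ``depth``
convolutional blocks (two 3x3x3 same-padded stride-1 convolutions with
ELU, then 2x max-pooling), doubling the filter count per block along
the default ladder 8-16-32-64 so the feature mappings grow from the 4
input sequences to 64 at the deepest level; at depth 4 a 32-voxel
extent shrinks to 2.  The decoder mirrors it: 2x nearest-neighbor
upsampling followed by a 3x3x3 convolution (or a learned stride-2
transposed convolution, ``upsample_mode="transposed"``), concatenation
with the matching encoder output — doubling the channel count at every
merge — and two further convolutions.  A final 1x1x1 convolution with a
sigmoid yields the probability map; depths 2-4 are supported.

Exposed as a scikit-learn style estimator: ``fit(X, y)`` on
``(n, 4, s, s, s)`` tensors and binary voxel targets, then
``predict_proba`` / ``predict``.  Training uses Adam (defaults: learning
rate 1e-3, batch 16, L2 4e-4) with binary cross-entropy (soft-Dice
available) and is bit-reproducible given ``random_state``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _nn
from .errors import ConfigError, DataError, ShapeError
from .io_volumes import BinaryMask
from .metrics import ConfusionCounts, dice as dice_metric

_LOSSES = ("bce", "soft_dice")


@dataclasses.dataclass
class SegmenterConfig:
    """Architecture hyperparameters of the U-Net."""

    depth: int = 4
    encoder_filters: tuple = (8, 16, 32, 64)
    input_channels: int = 4
    upsample_mode: str = "nearest"  # or "transposed"

    def __post_init__(self):
        if self.depth not in (2, 3, 4):
            raise ConfigError(f"depth must be in {{2,3,4}}, got {self.depth}")
        self.encoder_filters = tuple(int(f) for f in self.encoder_filters)
        if len(self.encoder_filters) != self.depth:
            raise ConfigError(
                f"need {self.depth} encoder filter counts, got {self.encoder_filters}")
        if self.upsample_mode not in ("nearest", "transposed"):
            raise ConfigError(f"unknown upsample_mode {self.upsample_mode!r}")


@dataclasses.dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference recipe:
    Adam, initial learning rate 1e-3, batch size 16, L2 4e-4; the
    published epoch budget is 200 — desk-scale runs use far fewer)."""

    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    l2_lambda: float = 4e-4
    loss: str = "bce"
    seed: int = 0
    mask_threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.l2_lambda < 0:
            raise ConfigError("invalid optimization hyperparameters")
        if self.loss not in _LOSSES:
            raise ConfigError(f"loss must be one of {_LOSSES}")
        if not (0.0 < self.mask_threshold < 1.0):
            raise ConfigError("mask_threshold must lie in (0, 1)")


class _UNetCore:
    """Layer graph + forward/backward, channels-last."""

    def __init__(self, cfg: SegmenterConfig, rng, dtype=np.float32):
        self.cfg = cfg
        nd = 3
        C = _nn.ConvND
        self.encoder = []
        c = cfg.input_channels
        for bi, f in enumerate(cfg.encoder_filters):
            block = {
                "conv1": C(c, f, 3, nd, rng, dtype, needs_dx=bi > 0), "act1": _nn.ELU(),
                "conv2": C(f, f, 3, nd, rng, dtype), "act2": _nn.ELU(),
                "pool": _nn.MaxPoolND(nd),
            }
            self.encoder.append(block)
            c = f
        self.decoder = []
        for f in reversed(cfg.encoder_filters):
            block = {"act_up": _nn.ELU(),
                     "conv1": C(2 * f, f, 3, nd, rng, dtype), "act1": _nn.ELU(),
                     "conv2": C(f, f, 3, nd, rng, dtype), "act2": _nn.ELU()}
            if cfg.upsample_mode == "nearest":
                block["up"] = _nn.UpsampleND(nd)
                block["upconv"] = C(c, f, 3, nd, rng, dtype)
            else:
                block["upconv"] = _nn.ConvTransposeND(c, f, nd, rng, dtype)
            self.decoder.append(block)
            c = f
        self.head = C(c, 1, 1, nd, rng, dtype)

    # -- introspection -----------------------------------------------------
    def layers(self):
        out = []
        for block in self.encoder + self.decoder:
            out.extend(v for v in block.values())
        out.append(self.head)
        return out

    def n_parameters(self) -> int:
        return _nn.n_parameters(self.layers())

    def describe(self, input_extent: int):
        """Per-stage record of spatial extent and channel counts, derived
        from the actual weight arrays."""
        stages = []
        ext = input_extent
        for i, block in enumerate(self.encoder):
            c_in = block["conv1"].c_in
            c_out = block["conv2"].c_out
            stages.append({"stage": f"enc{i}", "extent_in": ext, "extent_out": ext // 2,
                           "channels_in": c_in, "channels_out": c_out})
            ext //= 2
        stages.append({"stage": "bottleneck", "extent_in": ext, "extent_out": ext,
                       "channels_in": self.encoder[-1]["conv2"].c_out,
                       "channels_out": self.encoder[-1]["conv2"].c_out})
        for i, block in enumerate(self.decoder):
            up = block["upconv"]
            merged = block["conv1"].c_in  # channels entering the post-concat conv
            stages.append({"stage": f"dec{i}", "extent_in": ext, "extent_out": ext * 2,
                           "channels_in": up.c_in, "channels_after_up": up.c_out,
                           "channels_after_concat": merged,
                           "channels_out": block["conv2"].c_out})
            ext *= 2
        stages.append({"stage": "head", "extent_in": ext, "extent_out": ext,
                       "channels_in": self.head.c_in, "channels_out": 1})
        return stages

    # -- forward / backward ------------------------------------------------
    def forward(self, x, train=False):
        skips = []
        h = x
        for block in self.encoder:
            h = block["act1"].forward(block["conv1"].forward(h, train), train)
            h = block["act2"].forward(block["conv2"].forward(h, train), train)
            skips.append(h)
            h = block["pool"].forward(h, train)
        self._skip_channels = [s.shape[-1] for s in skips]
        for block, skip in zip(self.decoder, reversed(skips)):
            if "up" in block:
                h = block["up"].forward(h, train)
            h = block["act_up"].forward(block["upconv"].forward(h, train), train)
            h = np.concatenate([h, skip], axis=-1)
            h = block["act1"].forward(block["conv1"].forward(h, train), train)
            h = block["act2"].forward(block["conv2"].forward(h, train), train)
        return self.head.forward(h, train)  # logits, (B, s, s, s, 1)

    def backward(self, dlogits):
        d = self.head.backward(dlogits)
        dskips = []
        for block in reversed(self.decoder):
            d = block["conv2"].backward(block["act2"].backward(d))
            d = block["conv1"].backward(block["act1"].backward(d))
            f = block["upconv"].c_out
            d, dskip = d[..., :f], d[..., f:]
            dskips.append(dskip)
            d = block["upconv"].backward(block["act_up"].backward(d))
            if "up" in block:
                d = block["up"].backward(d)
        # dskips were collected shallow-to-deep; encoder is walked deep-to-shallow
        for block, dskip in zip(reversed(self.encoder), reversed(dskips)):
            d = block["pool"].backward(d) + dskip
            d = block["conv2"].backward(block["act2"].backward(d))
            d = block["conv1"].backward(block["act1"].backward(d))
        return d


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around the 3-D U-Net.

    Parameters mirror :class:`SegmenterConfig` and :class:`TrainConfig`;
    fitted attributes carry a trailing underscore (``model_``,
    ``history_``, ``n_parameters_``).
    """

    def __init__(self, depth=4, encoder_filters=(8, 16, 32, 64),
                 upsample_mode="nearest", learning_rate=1e-3, epochs=30,
                 batch_size=16, l2_lambda=4e-4, loss="bce", threshold=0.5,
                 random_state=0):
        self.depth = depth
        self.encoder_filters = encoder_filters
        self.upsample_mode = upsample_mode
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.l2_lambda = l2_lambda
        self.loss = loss
        self.threshold = threshold
        self.random_state = random_state

    # -- construction ------------------------------------------------------
    def _configs(self):
        seg = SegmenterConfig(depth=self.depth, encoder_filters=tuple(self.encoder_filters),
                              upsample_mode=self.upsample_mode)
        tc = TrainConfig(learning_rate=self.learning_rate, epochs=self.epochs,
                         batch_size=self.batch_size, l2_lambda=self.l2_lambda,
                         loss=self.loss, seed=self.random_state or 0,
                         mask_threshold=self.threshold)
        return seg, tc

    def build(self, input_extent=32):
        """Initialize the network without training (weights drawn from
        ``random_state``); returns self."""
        seg, tc = self._configs()
        if input_extent % (2 ** seg.depth) != 0:
            raise ConfigError(
                f"input extent {input_extent} not divisible by 2^{seg.depth}")
        rng = np.random.default_rng(tc.seed)
        self.model_ = _UNetCore(seg, rng)
        self.input_extent_ = int(input_extent)
        self.n_parameters_ = self.model_.n_parameters()
        return self

    # -- data validation ---------------------------------------------------
    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4:
            X = X[None]
        if X.ndim != 5 or X.shape[1] != 4:
            raise ShapeError(f"expected (n, 4, s, s, s), got {X.shape}")
        s = X.shape[2]
        if X.shape[3] != s or X.shape[4] != s:
            raise ShapeError(f"expected cubic volumes, got {X.shape[2:]}")
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite values in X")
        return X

    def fit(self, X, y):
        """Train on volumes ``X`` (n, 4, s, s, s) and binary voxel targets
        ``y`` (n, s, s, s)."""
        X = self._check_X(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise ShapeError(f"targets {y.shape} do not match inputs {X.shape}")
        if X.shape[0] == 0:
            raise DataError("empty training set")
        if not np.isin(np.unique(y), [0, 1]).all():
            raise DataError("segmentation targets must be binary")
        self.build(input_extent=X.shape[2])
        seg, tc = self._configs()

        xl = np.moveaxis(X, 1, -1)  # channels-last
        yl = y.astype(np.float32)[..., None]
        rng = np.random.default_rng(tc.seed + 1)
        params = _nn.collect_params(self.model_.layers())
        opt = _nn.Adam(params, lr=tc.learning_rate, l2=tc.l2_lambda)
        loss_fn = _nn.bce_loss_grad if tc.loss == "bce" else _nn.soft_dice_loss_grad

        n = xl.shape[0]
        history = []
        for epoch in range(tc.epochs):
            order = rng.permutation(n)
            losses = []
            tp = fp = fn = 0
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                xb, yb = xl[idx], yl[idx]
                logits = self.model_.forward(xb, train=True)
                loss, grad, p = loss_fn(logits, yb)
                opt.zero_grad()
                self.model_.backward(grad)
                opt.step()
                losses.append(loss)
                pred = p >= tc.mask_threshold
                t = yb > 0.5
                tp += int(np.count_nonzero(pred & t))
                fp += int(np.count_nonzero(pred & ~t))
                fn += int(np.count_nonzero(~pred & t))
            d = dice_metric(ConfusionCounts(tp=tp, fp=fp, tn=0, fn=fn))
            history.append({"epoch": epoch, "loss": float(np.mean(losses)), "dice": d})
        self.history_ = pd.DataFrame(history)
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Voxel tumor probabilities, shape (n, s, s, s), values in [0, 1]."""
        if not hasattr(self, "model_"):
            raise DataError("model is not built; call fit() or build()")
        X = self._check_X(X)
        if X.shape[2] != self.input_extent_:
            raise ShapeError(
                f"extent {X.shape[2]} != model input extent {self.input_extent_}")
        out = []
        for start in range(0, X.shape[0], max(1, int(self.batch_size))):
            xb = np.moveaxis(X[start:start + max(1, int(self.batch_size))], 1, -1)
            logits = self.model_.forward(xb, train=False)
            out.append(_nn.sigmoid(logits)[..., 0])
        return np.concatenate(out, axis=0)

    def predict(self, X, threshold=None) -> np.ndarray:
        """Binary masks at ``threshold`` (default: the estimator's)."""
        thr = self.threshold if threshold is None else threshold
        if not (0.0 < thr < 1.0):
            raise ConfigError(f"threshold must lie in (0, 1), got {thr}")
        return (self.predict_proba(X) >= thr).astype(np.uint8)

    # -- persistence -------------------------------------------------------
    def save(self, path):
        """Serialize parameters + config to a ``.npz`` checkpoint."""
        arrays = {}
        for i, p in enumerate(_nn.collect_params(self.model_.layers())):
            arrays[f"p{i}"] = p.value
        meta = json.dumps({"params": self.get_params(),
                           "input_extent": self.input_extent_})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            est = cls(**meta["params"])
            est.build(input_extent=meta["input_extent"])
            params = _nn.collect_params(est.model_.layers())
            for i, p in enumerate(params):
                p.value[...] = data[f"p{i}"]
        return est


# ---------------------------------------------------------------------------
# thin functional wrappers (operation-style surface)
# ---------------------------------------------------------------------------

def build_segmenter(cfg: SegmenterConfig = None, input_extent: int = 32,
                    random_state: int = 0) -> UNetSegmenter:
    cfg = cfg or SegmenterConfig()
    est = UNetSegmenter(depth=cfg.depth, encoder_filters=cfg.encoder_filters,
                        upsample_mode=cfg.upsample_mode, random_state=random_state)
    return est.build(input_extent=input_extent)


def train_segmenter(est: UNetSegmenter, X, y, tc: TrainConfig = None) -> UNetSegmenter:
    if tc is not None:
        est.set_params(learning_rate=tc.learning_rate, epochs=tc.epochs,
                       batch_size=tc.batch_size, l2_lambda=tc.l2_lambda,
                       loss=tc.loss, threshold=tc.mask_threshold,
                       random_state=tc.seed)
    return est.fit(X, y)


def forward(est: UNetSegmenter, x) -> np.ndarray:
    """Probability map for a single (4, s, s, s) volume -> (1, s, s, s)."""
    return est.predict_proba(np.asarray(x)[None])


def predict_mask(est: UNetSegmenter, x, threshold: float = None) -> BinaryMask:
    mask = est.predict(np.asarray(x)[None], threshold=threshold)[0]
    return BinaryMask(mask=mask, region="complete")
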