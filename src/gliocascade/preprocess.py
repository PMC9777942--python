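"""Resampling and intensity normalization ahead of the networks.

Full-resolution scans (e.g. 240 x 240 x 155) are scaled down to the
network input grid (default 32^3).  Intensity volumes are resampled
trilinearly; label volumes use nearest-neighbor so no new label values
appear.  Each channel is normalized independently (z-score by default),
since the four MR sequences live on unrelated intensity scales.  An
optional median filter is available for noise removal but is off by
default — the segmentation network itself is the denoiser of record and
should not be confounded by extra filtering.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .io_volumes import LabelVolume, MultiSequenceScan

_NORMS = ("zscore", "minmax", "none")


@dataclasses.dataclass
class PreprocessConfig:
    """Target grid and normalization choices.

    ``target_shape`` components must be >= 2; when feeding the U-Net
    they should be powers of two so repeated 2x pooling stays exact.
    """

    target_shape: tuple = (32, 32, 32)
    normalize: str = "zscore"
    denoise: str = "none"
    median_radius: int = 1

    def __post_init__(self):
        self.target_shape = tuple(int(s) for s in self.target_shape)
        if any(s < 2 for s in self.target_shape):
            raise ConfigError(f"target_shape components must be >= 2: {self.target_shape}")
        if self.normalize not in _NORMS:
            raise ConfigError(f"normalize must be one of {_NORMS}")
        if self.denoise not in ("none", "median"):
            raise ConfigError("denoise must be 'none' or 'median'")


def _target_coords(src_shape, target_shape):
    """Pixel-center aligned source coordinates for each target voxel."""
    axes = [
        (np.arange(t) + 0.5) * (s / t) - 0.5
        for s, t in zip(src_shape, target_shape)
    ]
    return np.meshgrid(*axes, indexing="ij")


def resample(vol: np.ndarray, target_shape, kind: str = "intensity") -> np.ndarray:
    """Resample a 3-D grid to ``target_shape``.

    ``kind="intensity"`` interpolates trilinearly; ``kind="label"`` uses
    nearest-neighbor, so the output label set is a subset of the input's.
    """
    vol = np.asarray(vol)
    if vol.ndim != 3 or vol.size == 0:
        raise ConfigError("resample expects a nonempty 3-D volume")
    target_shape = tuple(int(s) for s in target_shape)
    if any(s <= 0 for s in target_shape):
        raise ConfigError(f"invalid target_shape {target_shape}")
    if vol.shape == target_shape:
        return vol.copy()
    coords = _target_coords(vol.shape, target_shape)
    if kind == "intensity":
        return ndimage.map_coordinates(vol.astype(np.float64), coords, order=1,
                                       mode="nearest")
    if kind == "label":
        idx = [np.clip(np.round(c).astype(np.intp), 0, s - 1)
               for c, s in zip(coords, vol.shape)]
        return vol[tuple(idx)]
    raise ConfigError(f"kind must be 'intensity' or 'label', got {kind!r}")


def normalize(vol: np.ndarray, method: str = "zscore") -> np.ndarray:
    """Normalize a volume in place of its native scale.

    zscore -> mean 0, population sd 1; a constant volume maps to all
    zeros (documented convention rather than an error, so tumor-free or
    air-only channels stay usable).  minmax -> range [0, 1], same
    all-zero convention when max == min.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if method == "zscore":
        sd = vol.std()
        if sd == 0:
            return np.zeros_like(vol)
        return (vol - vol.mean()) / sd
    if method == "minmax":
        lo, hi = vol.min(), vol.max()
        if hi == lo:
            return np.zeros_like(vol)
        return (vol - lo) / (hi - lo)
    if method == "none":
        return vol.copy()
    raise ConfigError(f"unknown normalization {method!r}")


def median_denoise(vol: np.ndarray, radius: int = 1) -> np.ndarray:
    """Median filter with a cubic footprint of half-width ``radius``."""
    size = 2 * int(radius) + 1
    return ndimage.median_filter(np.asarray(vol, dtype=np.float64), size=size)


def preprocess_case(scan: MultiSequenceScan, truth: LabelVolume = None,
                    cfg: PreprocessConfig = None):
    """Scan (+ optional truth) -> (4, *target_shape) tensor and resampled labels.

    Channels are stacked in canonical order (FLAIR, T1, T1c, T2), each
    resampled and normalized independently; labels are resampled
    nearest-neighbor.  Returns ``(tensor, labels-or-None)``.
    """
    cfg = cfg or PreprocessConfig()
    channels = []
    for name, vol in scan.channels.items():
        v = vol
        if cfg.denoise == "median":
            v = median_denoise(v, cfg.median_radius)
        v = resample(v, cfg.target_shape, kind="intensity")
        if cfg.normalize != "none":
            v = normalize(v, cfg.normalize)
        channels.append(v)
    tensor = np.stack(channels, axis=0).astype(np.float32)
    labels = None
    if truth is not None:
        labels = LabelVolume(labels=resample(truth.labels, cfg.target_shape, kind="label"))
    return tensor, labels
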