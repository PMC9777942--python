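"""Multimodal volume I/O and tumor-region semantics.

Reads and writes four-sequence brain MR scans (FLAIR, T1, T1c, T2) and
their voxel label maps in MetaImage (``.mha``, the default) or NIfTI-1
(``.nii``/``.nii.gz``) form, and derives the three standard evaluation
regions from the raw tissue labels:

* **complete** tumor — every tumor class (necrosis, edema, non-enhancing,
  enhancing);
* **core** tumor — everything except edema;
* **enhancing** tumor — the enhancing class alone.

Label coding follows the BRATS convention: 0 background, 1 necrosis,
2 edema, 3 non-enhancing, 4 enhancing.  Arrays are stored (x, y, z),
0-based; the (z, y, x) layout of ITK images is normalized at read time.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import SimpleITK as sitk

from .errors import (
    FormatError,
    GeometryMismatchError,
    LabelDomainError,
    MissingSequenceError,
    RegionNameError,
)

#: Canonical sequence order used everywhere in the package.
SEQUENCES = ("FLAIR", "T1", "T1c", "T2")

#: Tissue-class integer codes (BRATS convention).
LABEL_CODES = {
    "background": 0,
    "necrosis": 1,
    "edema": 2,
    "non-enhancing": 3,
    "enhancing": 4,
}

#: Label sets defining each evaluation region.
REGION_LABELS = {
    "complete": frozenset({1, 2, 3, 4}),
    "core": frozenset({1, 3, 4}),
    "enhancing": frozenset({4}),
}

_VOLUME_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")


@dataclasses.dataclass
class MultiSequenceScan:
    """A four-channel 3-D intensity volume with voxel-spacing metadata.

    Parameters
    ----------
    channels
        Mapping sequence-name -> (x, y, z) float array.  Must contain
        exactly the four canonical sequences; order is normalized to
        FLAIR, T1, T1c, T2.
    spacing
        Per-axis voxel size in millimetres.
    """

    channels: dict
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        missing = [s for s in SEQUENCES if s not in self.channels]
        if missing:
            raise MissingSequenceError(f"missing sequences: {missing}")
        extra = set(self.channels) - set(SEQUENCES)
        if extra:
            raise GeometryMismatchError(f"unknown sequences: {sorted(extra)}")
        # normalize order and dtype
        arrays = {}
        for name in SEQUENCES:
            arr = np.asarray(self.channels[name], dtype=np.float64)
            if arr.ndim != 3:
                raise GeometryMismatchError(f"{name}: expected 3-D array, got {arr.ndim}-D")
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"{name}: non-finite intensities")
            arrays[name] = arr
        shapes = {a.shape for a in arrays.values()}
        if len(shapes) != 1:
            raise GeometryMismatchError(f"channel shapes differ: {sorted(shapes)}")
        self.channels = arrays
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def stack(self) -> np.ndarray:
        """Channels stacked into a (4, x, y, z) tensor in canonical order."""
        return np.stack([self.channels[s] for s in SEQUENCES], axis=0)


@dataclasses.dataclass
class LabelVolume:
    """Integer voxel labels in {0..4} on an (x, y, z) grid."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise LabelDomainError("label volume has non-integral values")
            arr = np.round(arr).astype(np.int16)
        else:
            arr = arr.astype(np.int16)
        if arr.ndim != 3:
            raise LabelDomainError(f"expected 3-D labels, got {arr.ndim}-D")
        bad = np.setdiff1d(np.unique(arr), [0, 1, 2, 3, 4])
        if bad.size:
            raise LabelDomainError(f"labels outside {{0..4}}: {bad.tolist()}")
        self.labels = arr

    @property
    def shape(self) -> tuple:
        return self.labels.shape


@dataclasses.dataclass
class BinaryMask:
    """A 3-D {0,1} mask tagged with the region it represents."""

    mask: np.ndarray
    region: str = "custom"

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if not np.isin(np.unique(arr), [0, 1]).all():
            raise LabelDomainError("mask values must be 0/1")
        self.mask = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.mask.shape


def region_mask(lv: LabelVolume, region: str) -> BinaryMask:
    """Binary mask of one evaluation region of a label volume.

    ``complete`` selects labels {1,2,3,4}; ``core`` {1,3,4} (edema
    excluded); ``enhancing`` {4}.
    """
    try:
        labels = REGION_LABELS[region]
    except KeyError:
        raise RegionNameError(
            f"unknown region {region!r}; expected one of {sorted(REGION_LABELS)}"
        ) from None
    mask = np.isin(lv.labels, sorted(labels)).astype(np.uint8)
    return BinaryMask(mask=mask, region=region)


# ---------------------------------------------------------------------------
# file I/O (SimpleITK handles both MetaImage and NIfTI)
# ---------------------------------------------------------------------------

def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(f"unsupported volume format: {path.name}")


def _read_image(path) -> tuple:
    """Read one volume -> ((x,y,z) array, spacing)."""
    path = Path(path)
    if not path.exists():
        raise MissingSequenceError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # unreadable/corrupt header
        raise FormatError(f"cannot read {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {arr.ndim}-D")
    return np.ascontiguousarray(arr.transpose(2, 1, 0)), tuple(img.GetSpacing())


def _write_image(arr: np.ndarray, spacing, path) -> None:
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_scan(paths: Mapping[str, str]) -> MultiSequenceScan:
    """Read a four-sequence scan from per-sequence volume files.

    Parameters
    ----------
    paths
        Mapping sequence-name -> file path; all of FLAIR, T1, T1c, T2
        must be present.

    Raises
    ------
    MissingSequenceError
        A sequence is absent from the mapping or its file does not exist.
    GeometryMismatchError
        The four volumes do not share shape and spacing.
    FormatError
        A file is not a readable supported volume.
    """
    missing = [s for s in SEQUENCES if s not in paths]
    if missing:
        raise MissingSequenceError(f"missing sequences: {missing}")
    channels, spacings = {}, {}
    for name in SEQUENCES:
        arr, spacing = _read_image(paths[name])
        channels[name], spacings[name] = arr, spacing
    shapes = {a.shape for a in channels.values()}
    if len(shapes) != 1:
        raise GeometryMismatchError(f"sequence shapes differ: {sorted(shapes)}")
    if len({tuple(np.round(s, 6)) for s in spacings.values()}) != 1:
        raise GeometryMismatchError(f"sequence spacings differ: {spacings}")
    return MultiSequenceScan(channels=channels, spacing=spacings["FLAIR"])


def read_labels(path) -> LabelVolume:
    """Read a ground-truth label volume (values must lie in {0..4})."""
    arr, _ = _read_image(path)
    return LabelVolume(labels=arr)


def write_scan(scan: MultiSequenceScan, out_dir, fmt: str = "mha") -> dict:
    """Write a scan as ``<out_dir>/<sequence>.<fmt>``; returns the paths."""
    out_dir = Path(out_dir)
    suffix = {"mha": ".mha", "nii": ".nii", "nii.gz": ".nii.gz"}.get(fmt)
    if suffix is None:
        raise FormatError(f"unsupported output format: {fmt!r}")
    written = {}
    for name in SEQUENCES:
        p = out_dir / f"{name}{suffix}"
        _write_image(scan.channels[name].astype(np.float32), scan.spacing, p)
        written[name] = p
    return written


def write_labels(lv: LabelVolume, path, spacing=(1.0, 1.0, 1.0)) -> Path:
    """Write a label volume losslessly (int16)."""
    path = Path(path)
    _write_image(lv.labels.astype(np.int16), spacing, path)
    return path


def case_paths(case_dir, fmt: str = "mha") -> dict:
    """Directory convention: ``<case>/<sequence>.mha`` + ``<case>/truth.mha``."""
    case_dir = Path(case_dir)
    suffix = {"mha": ".mha", "nii": ".nii", "nii.gz": ".nii.gz"}[fmt]
    paths = {name: case_dir / f"{name}{suffix}" for name in SEQUENCES}
    paths["truth"] = case_dir / f"truth{suffix}"
    return paths


def read_case(case_dir, fmt: str = "mha", with_truth: bool = True):
    """Read ``(scan, truth-or-None)`` from a case directory."""
    paths = case_paths(case_dir, fmt)
    truth_path = paths.pop("truth")
    scan = read_scan(paths)
    truth = None
    if with_truth and truth_path.exists():
        truth = read_labels(truth_path)
    return scan, truth
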