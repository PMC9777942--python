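"""Synthetic multimodal brain-tumor phantoms.

Each phantom case mimics the structure of a multimodal glioma scan: a
spherical "brain" of uniform parenchyma inside an empty background, with
a tumor built from nested ellipsoids — edema outermost, then
non-enhancing tumor, an enhancing shell, and a necrotic core innermost.
The four MR sequences are rendered from a per-sequence/per-tissue
contrast table plus additive Gaussian noise, qualitatively echoing the
real sequences' roles (edema bright on FLAIR/T2, the enhancing shell
bright on T1c).  High-grade cases carry all four tissue classes; the
low-grade default is a smaller tumor without an enhancing shell, which
gives a grade classifier a learnable geometric/contrast signal.

Phantoms are deliberately simple — no anatomy, bias fields or partial
volume — but they exercise every downstream contract: nested region
semantics, multi-channel contrast, noise robustness, and determinism
(labels depend only on geometry, never on the noise draw).
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError, GeometryError
from .io_volumes import LabelVolume, MultiSequenceScan, SEQUENCES, write_labels, write_scan

#: Default mean intensity per sequence x tissue.  Values are arbitrary
#: units chosen so every tissue is distinct on every sequence; only the
#: qualitative ordering (edema bright on FLAIR/T2, enhancing bright on
#: T1c) is meaningful.
DEFAULT_CONTRAST = {
    "FLAIR": {"air": 0.0, "brain": 100.0, "necrosis": 120.0, "edema": 185.0,
              "non-enhancing": 160.0, "enhancing": 170.0},
    "T1":    {"air": 0.0, "brain": 120.0, "necrosis": 60.0, "edema": 90.0,
              "non-enhancing": 100.0, "enhancing": 110.0},
    "T1c":   {"air": 0.0, "brain": 110.0, "necrosis": 50.0, "edema": 100.0,
              "non-enhancing": 120.0, "enhancing": 200.0},
    "T2":    {"air": 0.0, "brain": 90.0, "necrosis": 170.0, "edema": 190.0,
              "non-enhancing": 140.0, "enhancing": 150.0},
}

_TISSUE_OF_LABEL = {0: "air", 1: "necrosis", 2: "edema", 3: "non-enhancing", 4: "enhancing"}


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic case.

    Parameters
    ----------
    shape
        Volume extent in voxels.
    brain_radius_frac
        Brain-sphere radius as a fraction of the half-extent.
    tumor_center
        Voxel coordinates of the tumor center, or ``"random"`` to place
        it uniformly inside the brain (subject to fitting in bounds).
    tumor_radii
        Per-axis semi-axes (voxels) of the outer (edema) ellipsoid.
        All zero produces a tumor-free case.
    shell_fracs
        Radii fractions, strictly decreasing, of the nested
        (non-enhancing, enhancing, necrosis) ellipsoids relative to the
        outer one.  An entry of ``None`` omits that shell (the LGG
        default omits the enhancing shell).
    contrast
        sequence -> tissue -> mean intensity table.
    noise_sd
        Standard deviation of additive Gaussian noise.
    grade
        ``"HGG"`` or ``"LGG"``; affects defaults only, via
        :meth:`for_grade`.
    """

    shape: tuple = (64, 64, 64)
    brain_radius_frac: float = 0.9
    tumor_center: object = "random"  # "random" or (x, y, z) voxel coords
    tumor_radii: tuple = (12.0, 10.0, 11.0)
    shell_fracs: tuple = (0.75, 0.55, 0.35)
    contrast: dict = dataclasses.field(default_factory=lambda: DEFAULT_CONTRAST)
    noise_sd: float = 8.0
    grade: str = "HGG"

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 1 for s in self.shape):
            raise ConfigError(f"invalid shape {self.shape}")
        self.tumor_radii = tuple(float(r) for r in self.tumor_radii)
        if any(r < 0 for r in self.tumor_radii):
            raise ConfigError("tumor_radii must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        fracs = [f for f in self.shell_fracs if f is not None]
        if any(not (0 < f <= 1) for f in fracs):
            raise ConfigError("shell_fracs must lie in (0, 1]")
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise ConfigError("shell_fracs must be strictly decreasing inward")
        if self.grade not in ("HGG", "LGG"):
            raise ConfigError(f"grade must be HGG or LGG, got {self.grade!r}")

    @classmethod
    def for_grade(cls, grade: str, shape=(64, 64, 64), **overrides) -> "PhantomSpec":
        """Grade-specific defaults: HGG = large tumor, all four classes;
        LGG = smaller tumor, no enhancing shell.  Tumor radii scale with
        the volume extent (at 64^3: HGG ~(12, 10, 11), LGG ~(7, 6, 6.5))."""
        if grade == "HGG":
            fracs = (0.19, 0.16, 0.17)
            base = dict(shell_fracs=(0.75, 0.55, 0.35))
        elif grade == "LGG":
            fracs = (0.11, 0.095, 0.10)
            base = dict(shell_fracs=(0.7, None, 0.35))
        else:
            raise ConfigError(f"unknown grade {grade!r}")
        base["tumor_radii"] = tuple(round(f * s, 1) for f, s in zip(fracs, shape))
        base.update(overrides)
        return cls(shape=shape, grade=grade, **base)


@dataclasses.dataclass
class PhantomCase:
    """One generated case: scan + ground truth + provenance."""

    scan: MultiSequenceScan
    truth: LabelVolume
    grade: str
    seed: int


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    """Voxel centers satisfying sum(((i - c)/r)^2) <= 1; empty if any r == 0."""
    if any(r <= 0 for r in radii):
        return np.zeros(shape, dtype=bool)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def generate_case(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Render one phantom case deterministically from ``(spec, seed)``.

    The label volume is a function of geometry alone; noise affects only
    intensities.  Raises :class:`GeometryError` if the tumor ellipsoid
    does not fit inside the volume bounds.
    """
    rng = np.random.default_rng(seed)
    shape = spec.shape
    half = np.array(shape, dtype=float) / 2.0
    brain_center = half - 0.5
    brain_radii = spec.brain_radius_frac * half

    radii = np.array(spec.tumor_radii, dtype=float)
    has_tumor = np.all(radii > 0)
    if spec.tumor_center == "random":
        if has_tumor:
            # uniform center, rejection-sampled so the tumor stays inside
            # the brain sphere's bounding region and the volume bounds
            lo = np.maximum(radii, brain_center - 0.55 * brain_radii)
            hi = np.minimum(np.array(shape) - 1 - radii, brain_center + 0.55 * brain_radii)
            if np.any(lo > hi):
                raise GeometryError(
                    f"tumor radii {tuple(radii)} do not fit inside shape {shape}")
            center = lo + rng.random(3) * (hi - lo)
        else:
            center = brain_center.copy()
    else:
        center = np.array(spec.tumor_center, dtype=float)
        if has_tumor and (np.any(center - radii < 0)
                          or np.any(center + radii > np.array(shape) - 1)):
            raise GeometryError(
                f"tumor at {tuple(center)} with radii {tuple(radii)} exceeds bounds {shape}")

    brain = _ellipsoid_mask(shape, brain_center, brain_radii)
    labels = np.zeros(shape, dtype=np.int16)
    if has_tumor:
        # outer -> inner: edema(2), non-enhancing(3), enhancing(4), necrosis(1)
        order = [(2, 1.0)]
        for label, frac in zip((3, 4, 1), spec.shell_fracs):
            if frac is not None:
                order.append((label, float(frac)))
        for label, frac in order:
            m = _ellipsoid_mask(shape, center, radii * frac) & brain
            labels[m] = label

    # render intensities: contrast lookup per tissue + Gaussian noise
    tissue_index = np.where(labels > 0, labels, np.where(brain, -1, 0))
    channels = {}
    for name in SEQUENCES:
        table = spec.contrast[name]
        lut = np.empty(6)
        lut[0] = table["air"]
        lut[5] = table["brain"]           # slot 5 holds tissue "brain" (-1 below)
        for code in (1, 2, 3, 4):
            lut[code] = table[_TISSUE_OF_LABEL[code]]
        idx = np.where(tissue_index == -1, 5, tissue_index)
        vol = lut[idx]
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
        channels[name] = vol
    scan = MultiSequenceScan(channels=channels)
    return PhantomCase(scan=scan, truth=LabelVolume(labels=labels), grade=spec.grade,
                       seed=int(seed))


def case_seed(master_seed: int, index: int) -> int:
    """Deterministic per-case seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(n_cases: int, spec_template: Optional[PhantomSpec] = None,
                     grade_mix: float = 0.8, seed: int = 0,
                     out_dir=None, shape=(64, 64, 64)):
    """Generate ``n_cases`` phantoms; optionally write them to disk.

    Cases are drawn with :func:`case_seed`-derived per-case seeds, the
    first ``round(n_cases * grade_mix)`` as HGG and the rest LGG (the
    manifest records the interleaved, shuffled order).  When ``out_dir``
    is given, each case is written in the standard directory layout
    (``case_XXX/<sequence>.mha`` + ``truth.mha``) next to a
    ``manifest.csv`` with columns case_id, grade, seed, path.

    Returns ``(cases, manifest_rows)`` where ``cases`` is the in-memory
    list of :class:`PhantomCase`.
    """
    if n_cases < 1:
        raise ConfigError("n_cases must be >= 1")
    if not (0.0 <= grade_mix <= 1.0):
        raise ConfigError("grade_mix must lie in [0, 1]")
    n_hgg = int(round(n_cases * grade_mix))
    grades = ["HGG"] * n_hgg + ["LGG"] * (n_cases - n_hgg)
    rng = np.random.default_rng(case_seed(seed, 2 ** 20))
    order = rng.permutation(n_cases)
    grades = [grades[i] for i in order]

    cases, rows = [], []
    for i, grade in enumerate(grades):
        s = case_seed(seed, i)
        if spec_template is not None:
            spec = dataclasses.replace(spec_template, grade=grade)
        else:
            spec = PhantomSpec.for_grade(grade, shape=shape)
        case = generate_case(spec, s)
        case_id = f"case_{i:03d}"
        path = ""
        if out_dir is not None:
            case_dir = Path(out_dir) / case_id
            write_scan(case.scan, case_dir)
            write_labels(case.truth, case_dir / "truth.mha")
            path = case_id  # relative to the dataset root, keeps manifests portable
        cases.append(case)
        rows.append({"case_id": case_id, "grade": grade, "seed": s, "path": path})

    if out_dir is not None:
        manifest = Path(out_dir) / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["case_id", "grade", "seed", "path"])
            writer.writeheader()
            writer.writerows(rows)
    return cases, rows
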