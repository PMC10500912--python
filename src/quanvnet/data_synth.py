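"""Datasets: a synthetic 4-class image generator plus DICOM/PNG readers.

The synthetic generator emulates the *statistical* structure of a
4-class grayscale medical-imaging task — four balanced classes, each a
distinct deterministic geometric base pattern (centered disc, off-center
disc, ring, uniform background) corrupted by zero-mean Gaussian noise
and clipped to [0, 1].  The patterns are stand-ins, not tumor
simulacra: they make every downstream module testable without any
download, with class separability controlled by ``noise_sd``.

Real data enter through class-per-subfolder image trees in DICOM or
PNG/JPEG form, min-max normalized and area-average resized to the
configured side length.  Splitting is a stratified 80/20 shuffle.
"""

from __future__ import annotations

import json
import logging
import warnings
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .evaluation import minmax_normalize

logger = logging.getLogger(__name__)

DEFAULT_CLASS_NAMES = ("centered_disc", "offset_disc", "ring", "background")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters: per-class count, image side, noise level, seed."""

    n_per_class: int = 100
    m: int = 8
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.m < 4:
            raise ValueError("image side m must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class LabeledImageSet:
    images: np.ndarray  # (n, m, m) in [0, 1]
    labels: np.ndarray  # (n,) ints in {0..3}
    class_names: tuple
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if len(self.labels) and not (
            0 <= self.labels.min() and self.labels.max() < len(self.class_names)
        ):
            raise ValueError("labels outside the declared class range")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(
            self.images[indices], self.labels[indices],
            self.class_names, self.provenance,
        )

    def save(self, path, spec: SyntheticSpec | None = None) -> None:
        """Compressed archive: JSON manifest + the pixel/label arrays."""
        manifest = {
            "provenance": self.provenance,
            "class_names": list(self.class_names),
            "n": len(self),
            "spec": None if spec is None else spec.__dict__,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as archive:
            archive.writestr("manifest.json", json.dumps(manifest, indent=2))
            for name, arr in (("images", self.images), ("labels", self.labels)):
                buf = BytesIO()
                np.save(buf, arr)
                archive.writestr(f"{name}.npy", buf.getvalue())

    @classmethod
    def load(cls, path) -> "LabeledImageSet":
        with zipfile.ZipFile(path) as archive:
            manifest = json.loads(archive.read("manifest.json"))
            images = np.load(BytesIO(archive.read("images.npy")))
            labels = np.load(BytesIO(archive.read("labels.npy")))
        return cls(images, labels, tuple(manifest["class_names"]),
                   manifest["provenance"])


# ---------------------------------------------------------------------------
# synthetic generation
# ---------------------------------------------------------------------------

def _base_pattern(label: int, m: int) -> np.ndarray:
    """Deterministic class prototypes on an m x m grid, values in [0, 1]."""
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    center = (m - 1) / 2.0
    r = np.hypot(yy - center, xx - center)
    if label == 0:  # centered bright disc
        return np.where(r <= m / 4.0, 0.9, 0.1)
    if label == 1:  # disc shifted toward the upper-left corner
        r_off = np.hypot(yy - m / 4.0, xx - m / 4.0)
        return np.where(r_off <= m / 4.0, 0.9, 0.1)
    if label == 2:  # ring
        return np.where((r >= m / 5.0) & (r <= m / 2.8), 0.9, 0.1)
    if label == 3:  # uniform mid-gray background
        return np.full((m, m), 0.4)
    raise ValueError(f"label {label} outside {{0..3}}")


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Balanced 4-class synthetic set; a pure function of the spec."""
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for label in range(4):
        base = _base_pattern(label, spec.m)
        noise = rng.normal(0.0, spec.noise_sd,
                           size=(spec.n_per_class, spec.m, spec.m))
        images.append(np.clip(base[None] + noise, 0.0, 1.0))
        labels.append(np.full(spec.n_per_class, label))
    return LabeledImageSet(
        np.concatenate(images), np.concatenate(labels),
        DEFAULT_CLASS_NAMES, "synthetic",
    )


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    loaded: int = 0
    skipped: list = field(default_factory=list)


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    pixels = ds.pixel_array.astype(float)
    # apply the modality rescale when present; windowing metadata ignored
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return pixels * slope + intercept


def _read_png(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    pixels = iio.imread(path).astype(float)
    if pixels.ndim == 3:  # collapse RGB(A) to grayscale
        pixels = pixels[..., :3].mean(axis=-1)
    return pixels


def load_image_folder(
    path, format: str = "png", m: int = 8
) -> tuple[LabeledImageSet, LoadReport]:
    """Read a class-per-subfolder image tree.

    Each subdirectory of ``path`` is one class (sorted name order gives
    the label).  Unreadable files are skipped with a warning and counted
    in the returned :class:`LoadReport`; an empty tree is an error.
    Pixel grids are min-max normalized and resized to ``m`` x ``m``.
    """
    from .quanvolution import preprocess_image

    if format not in ("dicom", "png"):
        raise ValueError(f"unknown format {format!r}; expected 'dicom' or 'png'")
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset folder {root} does not exist")
    reader = _read_dicom if format == "dicom" else _read_png
    suffixes = (".dcm",) if format == "dicom" else (".png", ".jpg", ".jpeg")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels, report = [], [], LoadReport()
    for label, class_dir in enumerate(class_dirs):
        for file in sorted(class_dir.iterdir()):
            if file.suffix.lower() not in suffixes:
                continue
            try:
                raw = reader(file)
                images.append(preprocess_image(raw, m).pixels)
                labels.append(label)
                report.loaded += 1
            except Exception as exc:  # noqa: BLE001 - skip-and-log contract
                warnings.warn(f"skipping unreadable file {file}: {exc}",
                              stacklevel=2)
                report.skipped.append(str(file))
    if not images:
        raise ValueError(f"no readable {format} files under {root}")
    dataset = LabeledImageSet(
        np.asarray(images), np.asarray(labels),
        tuple(d.name for d in class_dirs), format,
    )
    return dataset, report


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_train_test(
    data: LabeledImageSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified shuffle split; disjoint, union equals the input."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    splitter = StratifiedShuffleSplit(
        n_splits=1, train_size=train_fraction, random_state=seed
    )
    train_idx, test_idx = next(splitter.split(data.images, data.labels))
    return data.subset(np.sort(train_idx)), data.subset(np.sort(test_idx))
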