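"""Synthetic textured datasets and folder-of-images loading.

The synthetic generator produces class-discriminable oriented textures:
each class is an anisotropic sinusoidal grating at a class-specific
orientation (evenly spaced over [0, 180) degrees) plus seeded Gaussian
noise, min-max rescaled to [0, 1].  Because shearlet subbands index
orientation, class identity maps directly onto the dominant directional
subband, which makes end-to-end recovery tests sharp.

Defaults emulate a small but non-trivial recognition problem: 4 classes x
50 images of 128 x 128 pixels, 24 cycles per image, contrast 1 and noise
standard deviation 0.3 (roughly 0.6 x the grating amplitude before
rescaling).  Per-image seeds are derived from the master seed through
``numpy.random.SeedSequence`` spawn keys, so datasets are bit-reproducible
and adding classes or images never reshuffles existing ones.

Real corpora are read with :func:`load_image_folder`: one sub-folder per
class containing PNG/TIFF/JPEG images, traversed in deterministic
lexicographic order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import LoaderError, ParameterError
from .shearlet import to_grayscale

__all__ = [
    "TextureClassSpec",
    "SyntheticDataset",
    "generate_texture",
    "generate_dataset",
    "load_image_folder",
    "save_dataset",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclasses.dataclass(frozen=True)
class TextureClassSpec:
    """Parameters of one texture class.

    orientation is the wave-vector angle in degrees; frequency is in cycles
    per image width and must stay below Nyquist (size / 2).
    """

    orientation: float
    frequency: float
    contrast: float = 1.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.frequency <= 0:
            raise ParameterError("frequency must be positive")


@dataclasses.dataclass
class SyntheticDataset:
    images: list[np.ndarray]
    labels: np.ndarray
    class_specs: tuple[TextureClassSpec, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.images)


def generate_texture(
    spec: TextureClassSpec,
    size: int | tuple[int, int] = 128,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """One oriented grating-plus-noise image, min-max rescaled to [0, 1]."""
    rows, cols = (size, size) if isinstance(size, int) else size
    if spec.frequency >= min(rows, cols) / 2:
        raise ParameterError(
            f"frequency {spec.frequency} at or above Nyquist ({min(rows, cols) / 2})"
        )
    rng = np.random.default_rng(seed)
    angle = np.deg2rad(spec.orientation)
    x = np.arange(cols)[None, :]
    y = np.arange(rows)[:, None]
    phase = 2.0 * np.pi * spec.frequency * (x * np.cos(angle) + y * np.sin(angle)) / cols
    img = 0.5 * spec.contrast * np.cos(phase)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(rows, cols))
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.full((rows, cols), 0.5)
    return (img - lo) / (hi - lo)


def generate_dataset(
    n_classes: int = 4,
    n_per_class: int = 50,
    size: int = 128,
    seed: int = 0,
    frequency: float = 24.0,
    contrast: float = 1.0,
    noise_sd: float = 0.3,
) -> SyntheticDataset:
    """Balanced oriented-texture dataset with evenly spaced orientations.

    Class ``c`` uses orientation ``c * 180 / n_classes`` degrees; labels are
    the class indices 0..n_classes-1.  Image ``i`` of class ``c`` is seeded
    by ``SeedSequence(seed, spawn_key=(c, i))``.
    """
    if n_classes < 2:
        raise ParameterError("n_classes must be >= 2")
    specs = tuple(
        TextureClassSpec(
            orientation=c * 180.0 / n_classes,
            frequency=frequency,
            contrast=contrast,
            noise_sd=noise_sd,
        )
        for c in range(n_classes)
    )
    images = []
    labels = []
    for c, spec in enumerate(specs):
        for i in range(n_per_class):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(c, i))
            images.append(generate_texture(spec, size, child))
            labels.append(c)
    return SyntheticDataset(
        images=images, labels=np.array(labels), class_specs=specs, seed=seed
    )


def save_dataset(dataset: SyntheticDataset, root: str | Path) -> None:
    """Write a dataset as 8-bit PNGs in folder-per-class layout."""
    root = Path(root)
    for c in np.unique(dataset.labels):
        (root / f"class{c}").mkdir(parents=True, exist_ok=True)
    counters: dict[int, int] = {}
    for img, label in zip(dataset.images, dataset.labels):
        i = counters.get(int(label), 0)
        counters[int(label)] = i + 1
        out = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
        Image.fromarray(out).save(root / f"class{label}" / f"img{i:04d}.png")


def load_image_folder(root: str | Path) -> tuple[list[np.ndarray], np.ndarray]:
    """Load a folder-per-class image corpus as grayscale [0, 1] arrays.

    Sub-folder names become class labels; folders and files are visited in
    lexicographic order, so repeated runs yield identical ordering.
    """
    root = Path(root)
    if not root.is_dir():
        raise LoaderError(f"{root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise LoaderError(f"{root} contains no class sub-folders")
    images: list[np.ndarray] = []
    labels: list[str] = []
    for class_dir in class_dirs:
        files = sorted(
            p for p in class_dir.iterdir()
            if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise LoaderError(f"class folder {class_dir} contains no images")
        for path in files:
            try:
                with Image.open(path) as handle:
                    arr = np.asarray(handle)
            except (OSError, UnidentifiedImageError) as exc:
                raise LoaderError(f"could not read image {path}: {exc}") from exc
            images.append(to_grayscale(arr))
            labels.append(class_dir.name)
    return images, np.array(labels)
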