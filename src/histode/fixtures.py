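"""Synthetic labelled data with planted ground truth.

Feature matrices are class-conditional Gaussians: on a chosen set of
*informative* columns the class means are spaced ``effect_size`` apart
(class k centred at ``effect_size * k``), while every other column is a
standard Gaussian independent of class.  The planted column set is returned
as a binary mask, so selection methods can be scored against known truth.

Toy image trees use per-class procedural textures (stripe frequency,
orientation and brightness vary by class) — enough for a feature extractor
to separate classes in a smoke test, with no pretence of tissue morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .de_select import BinaryMask
from .errors import InvalidSpecError
from .io import FeatureMatrix

__all__ = ["SyntheticSpec", "generate_features", "generate_images"]


@dataclass
class SyntheticSpec:
    """Recipe for a planted-signal feature matrix.

    effect_size is the separation δ between adjacent class means on the
    informative dimensions; noise_sd is the within-class standard deviation
    on those dimensions.  One seed drives all randomness.
    """

    n_per_class: int = 100
    n_classes: int = 2
    d: int = 32
    informative_idx: frozenset[int] = field(default_factory=frozenset)
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.d < 1:
            raise InvalidSpecError("d must be >= 1")
        if self.n_per_class < 2:
            raise InvalidSpecError("n_per_class must be >= 2")
        if self.n_classes < 2:
            raise InvalidSpecError("n_classes must be >= 2")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be > 0")
        bad = [j for j in self.informative_idx if not 0 <= j < self.d]
        if bad:
            raise IndexError(f"informative indices out of range [0, {self.d}): {bad}")


def generate_features(spec: SyntheticSpec) -> tuple[FeatureMatrix, BinaryMask]:
    """Generate the planted-signal matrix and its ground-truth mask.

    Rows are class-blocked (all of class 0, then class 1, ...); labels are
    ``class0..class{K-1}``.  Bitwise reproducible for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * spec.n_classes
    X = rng.standard_normal((n, spec.d))
    labels = np.repeat([f"class{k}" for k in range(spec.n_classes)], spec.n_per_class)
    info = sorted(spec.informative_idx)
    if info:
        for k in range(spec.n_classes):
            rows = slice(k * spec.n_per_class, (k + 1) * spec.n_per_class)
            X[rows, :][:, info] = spec.effect_size * k + spec.noise_sd * rng.standard_normal(
                (spec.n_per_class, len(info))
            )
    mask = BinaryMask.from_indices(spec.d, info)
    return FeatureMatrix(X, labels), mask


def _texture(k: int, n_classes: int, side: int, rng: np.random.Generator) -> np.ndarray:
    """Class-k texture: oriented stripes whose frequency, angle and mean
    brightness all step with k, plus mild pixel noise."""
    y, x = np.mgrid[0:side, 0:side] / side
    theta = np.pi * k / max(n_classes, 1)
    freq = 4.0 * (k + 1)
    phase = 2 * np.pi * freq * (x * np.cos(theta) + y * np.sin(theta))
    base = 0.5 + 0.35 * np.sin(phase)
    bright = 0.25 + 0.5 * (k / max(n_classes - 1, 1))
    img = 0.6 * base + 0.4 * bright + 0.05 * rng.standard_normal((side, side))
    rgb = np.stack(
        [
            img,
            np.roll(img, side // (k + 2), axis=0),
            np.full_like(img, bright),
        ],
        axis=-1,
    )
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def generate_images(
    n_per_class: int,
    n_classes: int,
    side: int,
    seed: int,
    out_dir: str | Path,
) -> list[Path]:
    """Write a class-per-subdirectory PNG tree of procedural textures.

    Returns the written paths (sorted).  Deterministic per seed.
    """
    if side < 32:
        raise InvalidSpecError("side must be >= 32 pixels")
    if n_classes < 1 or n_per_class < 1:
        raise InvalidSpecError("need at least one class and one image per class")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    paths: list[Path] = []
    for k in range(n_classes):
        cls_dir = out_dir / f"class{k}"
        try:
            cls_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create class directory {cls_dir}: {exc}") from exc
        for i in range(n_per_class):
            arr = _texture(k, n_classes, side, rng)
            p = cls_dir / f"img_{i:04d}.png"
            Image.fromarray(arr, mode="RGB").save(p)
            paths.append(p)
    return sorted(paths)
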