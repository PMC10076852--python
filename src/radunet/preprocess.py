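"""CT intensity windowing and flip augmentation.

A CT window is the standard display transform: ``window_level`` (center)
and ``window_width`` (span) select the Hounsfield-unit range of interest,
which is mapped linearly onto [0, 1] with clipping outside.  The lung
setting used for LIDC-style data is level 250 HU, width 1490 HU; values
at or below level - width/2 map to 0 and values at or above
level + width/2 map to 1.

Flip augmentation applies left-right and/or up-down flips jointly to an
image and its mask, preserving their geometric correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: lung window for LIDC-style scans (level/center 250 HU, width 1490 HU)
LUNG_WINDOW_LIDC = (250.0, 1490.0)


@dataclass(frozen=True)
class WindowSpec:
    """Window level (center) and width, in Hounsfield units."""

    window_level: float
    window_width: float

    def __post_init__(self):
        if self.window_width <= 0:
            raise ValueError(f"window_width must be positive, got {self.window_width}")

    @classmethod
    def lidc_lung(cls) -> "WindowSpec":
        return cls(*LUNG_WINDOW_LIDC)

    @classmethod
    def identity(cls) -> "WindowSpec":
        """Maps [0, 1] onto itself — for inputs that are already normalized."""
        return cls(window_level=0.5, window_width=1.0)

    @property
    def lo(self) -> float:
        return self.window_level - self.window_width / 2.0

    @property
    def hi(self) -> float:
        return self.window_level + self.window_width / 2.0


def window_normalize(image: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Map HU intensities linearly onto [0, 1] through the given window.

    The ramp sends ``window.lo`` to 0, the level to 0.5 and ``window.hi``
    to 1; values outside the window are clipped.  Monotone non-decreasing
    in the input.
    """
    image = np.asarray(image, dtype=np.float32)
    out = (image - window.lo) / window.window_width
    return np.clip(out, 0.0, 1.0)


def flip_augment(
    image: np.ndarray, mask: np.ndarray, horizontal: bool = False, vertical: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Flip image and mask along the same axes (left-right and/or up-down)."""
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    axes = []
    if vertical:
        axes.append(0)
    if horizontal:
        axes.append(1)
    if not axes:
        return image, mask
    return np.flip(image, axis=axes).copy(), np.flip(mask, axis=axes).copy()


def random_flip(
    image: np.ndarray, mask: np.ndarray, rng: np.random.Generator, p: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Apply each flip independently with probability ``p`` (train-time use)."""
    return flip_augment(image, mask, horizontal=rng.random() < p, vertical=rng.random() < p)
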