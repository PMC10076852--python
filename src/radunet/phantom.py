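"""Synthetic CT-like nodule phantoms with exact ground-truth masks.

The generator emulates the regime that makes lung-lesion segmentation
hard: lesions occupy a small fraction of the image, their grey values sit
close to a textured background, and their edges are blurred.  Each
phantom is a textured background (low-frequency Gaussian random field
around a fixed mean) plus one small contrast bump per nodule; the bump is
Gaussian-blurred before adding pixel noise.  The ground-truth mask is the
exact pre-blur disk rasterization, so truth is never ambiguous.

Nodules are sized in millimetres through ``pixel_spacing_mm`` and binned
into the four clinical diameter classes: micro nodule (d <= 5 mm), small
nodule (5 < d <= 10), nodule (10 < d <= 30) and lung mass (d > 30).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

#: clinical diameter classes, half-open intervals (lo, hi] in mm
DIAMETER_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("micro_nodule", 0.0, 5.0),
    ("small_nodule", 5.0, 10.0),
    ("nodule", 10.0, 30.0),
    ("lung_mass", 30.0, float("inf")),
)

BACKGROUND_MEAN = 0.35
_PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class DiameterCategory:
    label: str
    lo_mm: float   # exclusive
    hi_mm: float   # inclusive (inf for the open-ended class)

    def contains(self, d_mm: float) -> bool:
        return self.lo_mm < d_mm <= self.hi_mm


def diameter_category(diameter_mm: float) -> DiameterCategory:
    """Bin a lesion diameter (mm) into its clinical size class.

    The four classes partition (0, inf): boundaries belong to the smaller
    class (a 5 mm lesion is a micro nodule, a 10 mm one a small nodule).
    """
    if not diameter_mm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    for label, lo, hi in DIAMETER_CLASSES:
        if lo < diameter_mm <= hi:
            return DiameterCategory(label, lo, hi)
    raise AssertionError("unreachable: classes partition (0, inf)")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic nodule phantom.

    Intensities are on the normalized [0, 1] scale.  ``contrast_delta``
    is the nodule-minus-background mean difference; the default is kept
    small so lesions stay visually close to the textured background.
    """

    image_side: int = 64
    n_nodules_range: tuple[int, int] = (1, 2)
    radius_range: tuple[float, float] = (2.0, 5.5)
    contrast_delta: float = 0.25
    edge_blur_sigma: float = 1.0
    background_texture_sigma: float = 0.08
    noise_sigma: float = 0.02
    pixel_spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")
        lo, hi = self.radius_range
        if not (0 < lo <= hi < self.image_side / 2):
            raise ValueError(f"radius_range must lie within (0, {self.image_side / 2})")
        nlo, nhi = self.n_nodules_range
        if not (0 < nlo <= nhi):
            raise ValueError("n_nodules_range must be a positive interval")
        for name in ("edge_blur_sigma", "background_texture_sigma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")


@dataclass
class PhantomSample:
    """One phantom: image, exact mask, and per-nodule geometry."""

    image: np.ndarray
    mask: np.ndarray
    diameters_mm: list[float]

    @property
    def n_nodules(self) -> int:
        return len(self.diameters_mm)

    @property
    def categories(self) -> list[str]:
        return [diameter_category(d).label for d in self.diameters_mm]

    @property
    def dominant_category(self) -> str:
        """Size class of the largest lesion in the slice."""
        return diameter_category(max(self.diameters_mm)).label


class PlacementError(RuntimeError):
    """Raised when nodules cannot be placed within the retry budget."""


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom slice with its ground-truth mask.

    Deterministic: the same spec (including its seed) always yields a
    bit-identical sample.  The mask is the union of the rasterized disks
    (point-in-circle test); edge blur and noise affect the image only.
    """
    rng = np.random.default_rng(spec.seed)
    return _generate(spec, rng)


def _generate(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSample:
    side = spec.image_side
    yy, xx = np.mgrid[0:side, 0:side]

    texture = rng.normal(0.0, 1.0, (side, side))
    texture = gaussian_filter(texture, sigma=side / 8.0)
    sd = texture.std()
    if sd > 0 and spec.background_texture_sigma > 0:
        texture *= spec.background_texture_sigma / sd
    else:
        texture[:] = 0.0
    image = BACKGROUND_MEAN + texture

    n = int(rng.integers(spec.n_nodules_range[0], spec.n_nodules_range[1] + 1))
    mask = np.zeros((side, side), dtype=np.uint8)
    bump = np.zeros((side, side), dtype=float)
    diameters: list[float] = []
    for _ in range(n):
        r = float(rng.uniform(*spec.radius_range))
        margin = int(np.ceil(r))
        if 2 * margin >= side:
            raise PlacementError(f"radius {r:.1f} px cannot fit inside a {side} px image")
        placed = False
        for _attempt in range(_PLACEMENT_RETRIES):
            cy = float(rng.uniform(margin, side - 1 - margin))
            cx = float(rng.uniform(margin, side - 1 - margin))
            placed = True
            break
        if not placed:  # pragma: no cover - margins above guarantee placement
            raise PlacementError("nodule placement exceeded the retry budget")
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        mask |= disk.astype(np.uint8)
        bump += disk * spec.contrast_delta
        diameters.append(2.0 * r * spec.pixel_spacing_mm)

    if spec.edge_blur_sigma > 0:
        bump = gaussian_filter(bump, sigma=spec.edge_blur_sigma)
    image = image + bump
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, (side, side))
    return PhantomSample(np.clip(image, 0.0, 1.0).astype(np.float32), mask, diameters)


def generate_dataset(
    spec: PhantomSpec, n: int, train_fraction: float = 0.8
) -> tuple[list[PhantomSample], list[PhantomSample]]:
    """Generate ``n`` phantoms and split them into train/test sets.

    The default 8:2 split mirrors the standard protocol.  The split is a
    seeded random partition: |train| = round(n * train_fraction) and no
    sample appears in both sets.  Per-sample seeds are spawned from
    ``spec.seed``, so the whole dataset is reproducible from one integer.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    child_seeds = rng.integers(0, 2**31, size=n)
    samples = [_generate(spec, np.random.default_rng(int(s))) for s in child_seeds]
    order = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test


def equivalent_diameter_mm(component_area_px: int, pixel_spacing_mm: float) -> float:
    """Diameter of the circle with the same pixel area, in mm."""
    return 2.0 * np.sqrt(component_area_px / np.pi) * pixel_spacing_mm
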