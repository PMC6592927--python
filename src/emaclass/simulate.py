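"""Seeded synthetic immunofluorescence-like images for the four EmA classes.

Clinical EmA image sets are private, so this module renders stylized
stand-ins that differ in exactly the cues an expert reads on a stained
umbilical-cord section:

* **I (positive)** — bright elliptical ring outlines (vessel walls), short
  oriented bright line segments (reticulin fibers) and a mottled mid-level
  background (Wharton's jelly).
* **II (negative)** — dim background with sparse punctate speckle and no
  ring/fiber morphology.
* **III (IgA deficient)** — near-dark field.
* **IV (equivocal)** — class-I morphology at strongly reduced brightness and
  contrast (weak, uncertain staining).

Texture, not photorealism, is the point: the downstream descriptor consumes
local-contrast statistics only.  Because the descriptor is invariant to the
*sign pattern* of intensity differences, purely i.i.d. noise at different
amplitudes is invisible to it; the negative class therefore carries spatially
structured speckle rather than amplitude-only noise.  A ``separability``
dial linearly interpolates every class's parameters toward the across-class
mean: at 1 the classes are as distinct as the defaults make them, at 0 all
four classes share one parameter set and are distributionally identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse_perimeter, line

from .features import minimum_image_side
from .metrics import CLASSES

#: Class proportions of a celiac-suspect clinical cross-section (positive, negative, deficient, equivocal).
CLINICAL_PROFILE_COUNTS: tuple[int, ...] = (274, 2260, 13, 50)


@dataclass(frozen=True)
class ClassTextureParams:
    """Render parameters for one class; intensities are in [0, 1]."""

    ring_count: float = 0.0
    ring_brightness: float = 0.0
    fiber_density: float = 0.0  # fibers per 1000 px^2
    fiber_brightness: float = 0.0
    background_level: float = 0.1
    noise_sd: float = 0.03
    speckle_density: float = 0.0  # punctate dots per 1000 px^2
    speckle_brightness: float = 0.0
    mottle_sd: float = 0.0  # amplitude of low-pass correlated background mottle

    def __post_init__(self) -> None:
        for name in (
            "ring_brightness",
            "fiber_brightness",
            "background_level",
            "speckle_brightness",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0 or self.mottle_sd < 0:
            raise ValueError("noise_sd and mottle_sd must be >= 0")
        if self.ring_count < 0 or self.fiber_density < 0 or self.speckle_density < 0:
            raise ValueError("counts/densities must be >= 0")


DEFAULT_CLASS_PARAMS: dict[str, ClassTextureParams] = {
    "I": ClassTextureParams(
        ring_count=3,
        ring_brightness=0.55,
        fiber_density=6.0,
        fiber_brightness=0.45,
        background_level=0.25,
        noise_sd=0.05,
        speckle_density=0.0,
        speckle_brightness=0.0,
        mottle_sd=0.08,
    ),
    "II": ClassTextureParams(
        ring_count=0,
        ring_brightness=0.0,
        fiber_density=0.0,
        fiber_brightness=0.0,
        background_level=0.10,
        noise_sd=0.04,
        speckle_density=8.0,
        speckle_brightness=0.20,
        mottle_sd=0.03,
    ),
    # A truly dark field: residual detector noise only, no stained structure,
    # so the texture is i.i.d.-noise dominated rather than a dim copy of IV.
    "III": ClassTextureParams(
        ring_count=0,
        ring_brightness=0.0,
        fiber_density=0.0,
        fiber_brightness=0.0,
        background_level=0.03,
        noise_sd=0.012,
        speckle_density=0.0,
        speckle_brightness=0.0,
        mottle_sd=0.0,
    ),
    "IV": ClassTextureParams(
        ring_count=2,
        ring_brightness=0.15,
        fiber_density=2.5,
        fiber_brightness=0.18,
        background_level=0.15,
        noise_sd=0.05,
        speckle_density=0.0,
        speckle_brightness=0.0,
        mottle_sd=0.06,
    ),
}

_PARAM_FIELDS = tuple(ClassTextureParams.__dataclass_fields__)


@dataclass(frozen=True)
class DatasetSpec:
    """What to generate: class counts (or proportions), size, separability."""

    n_per_class: tuple[int, int, int, int] | None = (100, 100, 100, 100)
    proportions: tuple[float, float, float, float] | None = None
    total: int | None = None
    image_size: int = 96
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < minimum_image_side():
            raise ValueError(
                f"image_size must be >= {minimum_image_side()}, got {self.image_size}"
            )
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if self.proportions is not None:
            if self.total is None:
                raise ValueError("proportions require a total")
        elif self.n_per_class is None:
            raise ValueError("either n_per_class or proportions must be given")

    def class_counts(self) -> tuple[int, ...]:
        if self.proportions is not None:
            return apportion(self.proportions, self.total)
        return tuple(int(n) for n in self.n_per_class)


def apportion(proportions, total: int) -> tuple[int, ...]:
    """Integer class counts from shares by the largest-remainder method."""
    p = np.asarray(proportions, dtype=np.float64)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("proportions must be non-negative with positive sum")
    p = p / p.sum()
    raw = p * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return tuple(int(c) for c in counts)


def blend_params(
    cls: str,
    separability: float,
    base: dict[str, ClassTextureParams] | None = None,
) -> ClassTextureParams:
    """Interpolate a class's parameters toward the across-class mean.

    At ``separability == 1`` the class defaults are returned unchanged; at 0
    every class collapses onto one shared parameter set (the field-wise mean
    of the four defaults), making the classes distributionally identical.
    """
    base = base if base is not None else DEFAULT_CLASS_PARAMS
    if separability == 1.0:
        return base[cls]
    mean = {
        f: float(np.mean([getattr(base[c], f) for c in CLASSES]))
        for f in _PARAM_FIELDS
    }
    p = base[cls]
    s = separability
    return ClassTextureParams(
        **{f: mean[f] + s * (getattr(p, f) - mean[f]) for f in _PARAM_FIELDS}
    )


def _sprinkle_segments(
    canvas: np.ndarray, n: int, rng: np.random.Generator, brightness: float
) -> None:
    """Add short line segments (reticulin-fiber stand-ins) in place."""
    size = canvas.shape[0]
    for _ in range(n):
        r0, c0 = rng.integers(0, size, 2)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(5, 15)
        r1 = int(np.clip(r0 + length * np.sin(angle), 0, size - 1))
        c1 = int(np.clip(c0 + length * np.cos(angle), 0, size - 1))
        rr, cc = line(int(r0), int(c0), r1, c1)
        canvas[rr, cc] = np.maximum(canvas[rr, cc], brightness)


def generate_image(
    cls: str,
    p: ClassTextureParams | None = None,
    size: int = 96,
    seed: int = 0,
) -> np.ndarray:
    """Render one class-conditional field; bit-identical for equal arguments."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
    if size < minimum_image_side():
        raise ValueError(f"size must be >= {minimum_image_side()}, got {size}")
    if p is None:
        p = DEFAULT_CLASS_PARAMS[cls]
    rng = np.random.default_rng(seed)

    img = np.full((size, size), p.background_level, dtype=np.float64)
    # Wharton's-jelly-like mottle: low-pass correlated fluctuation around bg.
    if p.mottle_sd > 0:
        raw = ndimage.gaussian_filter(rng.standard_normal((size, size)), 3.0)
        img += p.mottle_sd * raw / raw.std()

    n_rings = rng.poisson(p.ring_count) if p.ring_count > 0 else 0
    if n_rings > 0 and p.ring_brightness > 0:
        ring_mask = np.zeros((size, size), dtype=np.float64)
        for _ in range(n_rings):
            r0, c0 = rng.integers(size // 6, size - size // 6, 2)
            a = int(rng.uniform(size / 10, size / 4))
            b = int(rng.uniform(size / 10, size / 4))
            orient = rng.uniform(-np.pi / 2, np.pi / 2)
            rr, cc = ellipse_perimeter(
                int(r0), int(c0), a, b, orientation=orient, shape=(size, size)
            )
            ring_mask[rr, cc] = 1.0
        img += p.ring_brightness * ndimage.gaussian_filter(ring_mask, 0.8) * 2.0

    n_fibers = rng.poisson(p.fiber_density * size * size / 1000.0)
    if n_fibers > 0 and p.fiber_brightness > 0:
        fiber_mask = np.zeros((size, size), dtype=np.float64)
        _sprinkle_segments(fiber_mask, n_fibers, rng, 1.0)
        img += p.fiber_brightness * ndimage.gaussian_filter(fiber_mask, 0.6) * 1.5

    n_speckle = rng.poisson(p.speckle_density * size * size / 1000.0)
    if n_speckle > 0 and p.speckle_brightness > 0:
        spk = np.zeros((size, size), dtype=np.float64)
        rr = rng.integers(0, size, n_speckle)
        cc = rng.integers(0, size, n_speckle)
        spk[rr, cc] = 1.0
        img += p.speckle_brightness * ndimage.gaussian_filter(spk, 0.6) * 2.0

    img += rng.normal(0.0, p.noise_sd, (size, size))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    spec: DatasetSpec,
) -> tuple[list[np.ndarray], list[str], dict]:
    """Generate a shuffled, seeded dataset of class-conditional images.

    Returns (images, labels, manifest); the manifest records counts, the
    blended per-class parameters, the seed and the separability, and is
    identical across seeds except for the seed entry.
    """
    counts = spec.class_counts()
    if sum(counts) < 1:
        raise ValueError("dataset must contain at least one image")
    params = {c: blend_params(c, spec.separability) for c in CLASSES}
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    for c, n in zip(CLASSES, counts):
        for _ in range(n):
            images.append(
                generate_image(
                    c, params[c], spec.image_size, int(rng.integers(2**31))
                )
            )
            labels.append(c)
    order = rng.permutation(len(images))
    images = [images[i] for i in order]
    labels = [labels[i] for i in order]
    manifest = {
        "class_counts": {c: int(n) for c, n in zip(CLASSES, counts)},
        "image_size": spec.image_size,
        "separability": spec.separability,
        "seed": spec.seed,
        "params": {
            c: {f: getattr(params[c], f) for f in _PARAM_FIELDS} for c in CLASSES
        },
    }
    if any(n == 0 for n in counts):
        manifest["warnings"] = [
            "zero-count class present; downstream stratified splitting will fail"
        ]
    return images, labels, manifest


def clinical_profile_spec(total: int, image_size: int = 96, seed: int = 0,
                separability: float = 1.0) -> DatasetSpec:
    """A DatasetSpec emulating the imbalanced class profile of a celiac-suspect clinical cross-section."""
    props = tuple(c / sum(CLINICAL_PROFILE_COUNTS) for c in CLINICAL_PROFILE_COUNTS)
    return DatasetSpec(
        n_per_class=None,
        proportions=props,
        total=total,
        image_size=image_size,
        separability=separability,
        seed=seed,
    )
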