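"""Noise field simulation for quantum-dot / porous-silicon fluorescence images.

The central noise model is multiplicative gamma ("speckle-like") noise: the
observed image is ``F = U * N`` where ``U`` is the clean image and ``N`` is an
i.i.d. gamma field with mean 1 and variance ``1/L`` (``L = 1/variance``).
Nine other noise families (and mixtures) are supported so that a labelled
10-class dataset can be generated for noise-type identification.

Images are kept at full float precision; quantization to 8 bits (with
clipping to [0, 255]) is an explicit, separate step, because part of the
gray-level depression seen in 8-bit micrographs arises from clipping and
rounding rather than from the noise itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FAMILIES = (
    "poisson",
    "gamma",
    "rayleigh",
    "exponential",
    "uniform",
    "gaussian",
    "salt_pepper",
    "gaussian+exponential",
    "gaussian+salt_pepper",
    "gamma+salt_pepper",
)

#: Default per-family intensity grids for dataset generation.  Only the gamma
#: class (parameterized by the variance 1/L of the multiplicative field) is
#: consumed downstream; the remaining grids are fixed, sensible defaults.
DEFAULT_INTENSITIES: dict[str, tuple[float, ...]] = {
    "poisson": (0.125, 0.2, 0.25, 0.4, 0.5),        # photon scaling c: F = Pois(cU)/c
    "gamma": (0.1, 0.3, 0.5, 0.7, 0.9),             # variance of N (1/L)
    "rayleigh": (3.0, 4.0, 5.0, 6.0, 8.0),          # scale (gray levels)
    "exponential": (5.0, 10.0, 15.0, 20.0, 25.0),   # scale (gray levels)
    "uniform": (10.0, 20.0, 30.0, 40.0, 50.0),      # half-width a of U(-a, a)
    "gaussian": (10.0, 14.0, 18.0, 22.0, 26.0),     # sigma (gray levels)
    "salt_pepper": (0.02, 0.05, 0.1, 0.15, 0.2),    # impulse density
    "gaussian+exponential": (10.0, 14.0, 18.0, 22.0, 26.0),
    "gaussian+salt_pepper": (10.0, 14.0, 18.0, 22.0, 26.0),
    "gamma+salt_pepper": (0.1, 0.3, 0.5, 0.7, 0.9),
}

#: Secondary intensity used for the second component of a mixture class.
MIXTURE_SECOND_INTENSITY = {"exponential": 30.0, "salt_pepper": 0.05}


@dataclass(frozen=True)
class NoiseSpec:
    """Distribution family plus parameters for one of the 10 noise classes.

    ``intensity`` is the single family-specific strength parameter (see
    :data:`DEFAULT_INTENSITIES` for its meaning per family).  For the gamma
    family it is the variance ``v = 1/L`` of the multiplicative field, so the
    field has mean exactly 1 and variance exactly ``1/L`` by construction.
    """

    family: str
    intensity: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; choose from {FAMILIES}")
        if self.family in ("gamma", "gamma+salt_pepper") and not 0 < self.intensity <= 1:
            raise ValueError(f"gamma variance must be in (0, 1], got {self.intensity}")


def gamma_noise_field(
    height: int,
    width: int,
    variance: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw an i.i.d. multiplicative gamma noise field N.

    N ~ Gamma(shape=L, rate=L) with ``L = 1/variance``, so E[N] = 1 and
    Var[N] = 1/L = variance.  ``variance`` must lie in (0, 1] (L >= 1).
    """
    if not 0 < variance <= 1:
        raise ValueError(f"variance must be in (0, 1], got {variance}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = 1.0 / variance
    return rng.gamma(shape=L, scale=1.0 / L, size=(height, width))


def apply_multiplicative_noise(
    clean: np.ndarray,
    variance: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Return F = U * N with N a gamma field of mean 1 and the given variance.

    The product is returned at full float precision; use :func:`quantize_u8`
    to obtain the 8-bit view.
    """
    clean = np.asarray(clean, dtype=float)
    if clean.ndim != 2:
        raise ValueError("clean image must be 2-D")
    if np.any(clean < 0) or not np.all(np.isfinite(clean)):
        raise ValueError("clean image must be finite and non-negative")
    n = gamma_noise_field(*clean.shape, variance=variance, seed=seed)
    return clean * n


def quantize_u8(image: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round to uint8 (the export/display view)."""
    return np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255).astype(np.uint8)


def apply_noise(spec: NoiseSpec, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply one noise class to a clean image (mixtures in label order)."""
    clean = np.asarray(clean, dtype=float)
    if "+" in spec.family:
        first, second = spec.family.split("+")
        out = _apply_single(first, spec.intensity, clean, rng)
        second_intensity = MIXTURE_SECOND_INTENSITY[second]
        return _apply_single(second, second_intensity, out, rng)
    return _apply_single(spec.family, spec.intensity, clean, rng)


def _apply_single(family: str, intensity: float, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    shape = image.shape
    if family == "gamma":
        return image * gamma_noise_field(*shape, variance=intensity, seed=rng)
    if family == "poisson":
        c = intensity
        return rng.poisson(np.maximum(image, 0.0) * c).astype(float) / c
    if family == "gaussian":
        return np.maximum(image + rng.normal(0.0, intensity, shape), 0.0)
    if family == "rayleigh":
        draw = rng.rayleigh(intensity, shape)
        return np.maximum(image + draw - intensity * np.sqrt(np.pi / 2.0), 0.0)
    if family == "exponential":
        return np.maximum(image + rng.exponential(intensity, shape) - intensity, 0.0)
    if family == "uniform":
        return np.maximum(image + rng.uniform(-intensity, intensity, shape), 0.0)
    if family == "salt_pepper":
        out = image.copy()
        u = rng.random(shape)
        out[u < intensity / 2.0] = 0.0
        out[u > 1.0 - intensity / 2.0] = 255.0
        return out
    raise ValueError(f"unknown noise family {family!r}")


@dataclass
class NoiseDataset:
    """Labelled noisy-image dataset for noise-type identification.

    ``images`` are 8-bit quantized noise maps; ``manifest`` carries one row
    per image (family, gray_level, intensity, split).
    """

    images: list[np.ndarray]
    manifest: pd.DataFrame
    seed: int = 0

    @property
    def train_indices(self) -> np.ndarray:
        return np.flatnonzero((self.manifest["split"] == "train").to_numpy())

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero((self.manifest["split"] == "test").to_numpy())


def make_noise_dataset(
    gray_levels: tuple[int, ...] = (30, 40, 50, 60, 70, 80, 90, 100),
    intensities: dict[str, tuple[float, ...]] | None = None,
    per_class_count: int = 200,
    size: int = 128,
    test_fraction: float = 0.15,
    seed: int = 0,
) -> NoiseDataset:
    """Generate the 10-class labelled noise dataset.

    Defaults give 2000 images (200 per family) over base gray levels 30-100,
    split 1700 train / 300 test with per-class stratification and no leakage.
    Bit-reproducible under a fixed seed.
    """
    grids = dict(DEFAULT_INTENSITIES)
    if intensities:
        for fam in intensities:
            if fam not in FAMILIES:
                raise ValueError(f"unknown noise family {fam!r}")
        grids.update(intensities)

    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    rows: list[dict] = []
    for family in FAMILIES:
        grid = grids[family]
        for j in range(per_class_count):
            gray = gray_levels[j % len(gray_levels)]
            intensity = grid[(j // len(gray_levels)) % len(grid)]
            clean = np.full((size, size), float(gray))
            noisy = apply_noise(NoiseSpec(family, intensity), clean, rng)
            images.append(quantize_u8(noisy))
            rows.append({"family": family, "gray_level": gray, "intensity": intensity})

    manifest = pd.DataFrame(rows)
    split = np.empty(len(images), dtype=object)
    n_test = int(round(per_class_count * test_fraction))
    for family in FAMILIES:
        idx = np.flatnonzero((manifest["family"] == family).to_numpy())
        perm = rng.permutation(idx)
        split[perm[:n_test]] = "test"
        split[perm[n_test:]] = "train"
    manifest["split"] = split
    return NoiseDataset(images=images, manifest=manifest, seed=seed)
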