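"""Gray-value compression (GVC) preprocessing.

Multiplicative noise scatters pixel values around the underlying gray level.
GVC shrinks each pixel toward a non-local-means (NLM) reference image in
small steps: per iteration a pixel at intensity I moves toward the reference
Itilde by gamma * I / 10, where gamma = exp(-I / Itilde) is the compression
coefficient (singular bright pixels relative to their reference get small
gamma; dark outliers get gamma near 1).  The number of iterations is driven
by the coefficient of variation of the noisy image through a calibration
curve derived once, by simulation, so that after compression the histogram
peak of a constant-gray image lands within +/-0.5 of the true gray value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .noise import apply_multiplicative_noise
from .regions import estimate_cv


@dataclass(frozen=True)
class NLMParams:
    """Non-local-means parameters: 21x21 search window, 7x7 patches.

    ``h`` controls the exponential decay of the patch-similarity weights
    w = exp(-d2/h^2) with d2 the mean squared patch difference; larger h
    averages more aggressively.
    """

    search_size: int = 21
    patch_size: int = 7
    h: float = 10.0

    def __post_init__(self) -> None:
        if self.search_size % 2 == 0 or self.patch_size % 2 == 0:
            raise ValueError("search_size and patch_size must be odd")
        if self.patch_size >= self.search_size:
            raise ValueError("patch_size must be smaller than search_size")
        if self.h <= 0:
            raise ValueError(f"h must be positive, got {self.h}")


def nlm_smooth(
    image: np.ndarray,
    params: NLMParams | None = None,
    return_weight_sums: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Non-local-means smoothing: the GVC compression reference image.

    Every output pixel is the weight-normalized average of all pixels in its
    search window, with weights exp(-d2/h^2) from the mean squared difference
    between the 7x7 patches centred on the two pixels.  Normalization is
    exact: the returned weight sums (after division by the partition
    function) are identically 1.

    Vectorized over search-window offsets; borders use reflect padding.
    """
    params = params or NLMParams()
    image = np.asarray(image, dtype=float)
    sr = params.search_size // 2
    pr = params.patch_size // 2
    pad = sr + pr
    padded = np.pad(image, pad, mode="reflect")
    h, w = image.shape

    # center-aligned view with a patch-radius margin for the box filter
    center = padded[sr : sr + h + 2 * pr, sr : sr + w + 2 * pr]
    acc = np.zeros((h, w))
    zsum = np.zeros((h, w))
    h2 = params.h ** 2
    for dy in range(-sr, sr + 1):
        for dx in range(-sr, sr + 1):
            shifted = padded[sr + dy : sr + dy + h + 2 * pr, sr + dx : sr + dx + w + 2 * pr]
            d2 = uniform_filter((center - shifted) ** 2, size=params.patch_size)
            d2 = d2[pr : pr + h, pr : pr + w]
            wgt = np.exp(-d2 / h2)
            acc += wgt * shifted[pr : pr + h, pr : pr + w]
            zsum += wgt
    out = acc / zsum
    if return_weight_sums:
        return out, zsum  # partition function Z(i); normalized weights sum to 1
    return out


def compression_coefficient(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-pixel compression coefficient gamma = exp(-I / Itilde).

    Strictly decreasing in the ratio I/Itilde: pixels far above their
    reference are compressed gently per unit intensity, pixels at or below it
    more strongly.  The reference must be strictly positive.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference image has non-positive pixels; add a luminance floor")
    return np.exp(-image / reference)


def gvc_iterate(
    image: np.ndarray,
    reference: np.ndarray,
    k_max: int,
    step_divisor: float = 10.0,
) -> np.ndarray:
    """Run k_max gray-value compression iterations against a fixed reference.

    Per iteration, pixels at or above the reference move down by
    gamma * I / step_divisor and pixels below move up by the same amount,
    with gamma recomputed from the current image each iteration.  Intensities
    stay non-negative because the step is at most I / step_divisor.
    """
    if k_max < 0:
        raise ValueError(f"k_max must be non-negative, got {k_max}")
    out = np.asarray(image, dtype=float).copy()
    reference = np.asarray(reference, dtype=float)
    for _ in range(int(k_max)):
        gamma = compression_coefficient(out, reference)
        step = gamma * out / step_divisor
        out = np.where(out >= reference, out - step, out + step)
    return out


def histogram_peak(
    image: np.ndarray,
    tie_toward: float | None = None,
    subpixel: bool = False,
) -> float:
    """Peak location of the integer-binned gray histogram.

    With ``subpixel=False`` this is the mode of the rounded histogram, ties
    broken toward ``tie_toward`` (typically the reference mean).  With
    ``subpixel=True`` the peak is refined by a three-point parabolic fit
    around the mode, which removes the integer-bin flicker of the raw mode
    and is the form used by the iteration calibration.
    """
    vals = np.rint(np.asarray(image, dtype=float)).astype(int).ravel()
    vals = vals - vals.min() if vals.min() < 0 else vals
    counts = np.bincount(vals.ravel()).astype(float)
    best = np.flatnonzero(counts == counts.max())
    if tie_toward is not None and len(best) > 1:
        m = int(best[np.argmin(np.abs(best - tie_toward))])
    else:
        m = int(best[0])
    if not subpixel or m == 0 or m == len(counts) - 1:
        return float(m)
    den = counts[m - 1] - 2 * counts[m] + counts[m + 1]
    if den == 0:
        return float(m)
    return float(m + 0.5 * (counts[m - 1] - counts[m + 1]) / den)


def pooled_histogram_peak(images: list[np.ndarray], subpixel: bool = True) -> float:
    """Histogram peak of several realizations pooled into one histogram."""
    vals = np.concatenate([np.rint(np.asarray(im, dtype=float)).astype(int).ravel() for im in images])
    return histogram_peak(vals.reshape(1, -1), subpixel=subpixel)


# ---------------------------------------------------------------------------
# CV -> iteration-count calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Monotone non-decreasing map from coefficient of variation to k_max."""

    deltas: np.ndarray  # ascending breakpoints
    k_values: np.ndarray  # non-decreasing iteration counts

    def __call__(self, delta: float) -> int:
        return iterations_from_cv(delta, self)

    def to_csv(self, path) -> None:
        pd.DataFrame({"delta": self.deltas, "k_max": self.k_values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        df = pd.read_csv(path)
        return cls(deltas=df["delta"].to_numpy(float), k_values=df["k_max"].to_numpy(float))


def default_calibration_curve() -> CalibrationCurve:
    """Calibration curve shipped with the package (regenerable via
    ``psidenoise calibrate-gvc`` or ``scripts/calibrate_gvc.py``)."""
    with resources.files("psidenoise.data").joinpath("gvc_calibration.csv").open("r") as fh:
        return CalibrationCurve.from_csv(fh)


def iterations_from_cv(delta: float, curve: CalibrationCurve | None = None) -> int:
    """Map a coefficient of variation to a GVC iteration budget.

    Linear interpolation between calibrated breakpoints, anchored at
    (0, 0) — a noiseless image needs no compression — rounded up so the
    histogram-peak criterion keeps holding between breakpoints.  Values
    beyond the calibrated range are clamped with a warning.
    """
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    curve = curve or default_calibration_curve()
    if delta > curve.deltas[-1]:
        warnings.warn(
            f"delta={delta:.3f} above calibrated range (max {curve.deltas[-1]:.3f}); clamping",
            stacklevel=2,
        )
    xs = np.concatenate([[0.0], curve.deltas])
    ys = np.concatenate([[0.0], curve.k_values])
    return int(np.ceil(np.interp(delta, xs, ys) - 1e-12))


def auto_nlm_h(delta: float, mean_gray: float, factor: float = 8.0) -> float:
    """Noise-adaptive NLM smoothing strength h ~ factor * estimated sigma."""
    return max(factor * delta * mean_gray, 1e-6)


def calibrate_gvc(
    gray_levels: tuple[int, ...] = (50, 60),
    variances: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_seeds: int = 5,
    size: int = 256,
    tol: float = 0.5,
    k_cap: int = 400,
    step_divisor: float = 10.0,
    h_factor: float = 8.0,
    concentration: float = 0.99,
    band_fraction: float = 0.04,
    seed: int = 0,
) -> tuple[CalibrationCurve, pd.DataFrame]:
    """Derive the CV -> k_max curve by direct simulation.

    For each (gray level, variance), ``n_seeds`` constant images with
    multiplicative gamma noise are generated and compressed in lockstep; the
    smallest k is recorded at which (a) the pooled compressed-histogram peak
    (sub-bin refined) lies within +/-tol of the true gray and (b) the
    histogram has actually concentrated — at least ``concentration`` of all
    pixels sit within ``band_fraction`` of the reference level of their
    reference image.  Condition (b) makes the compression run until the
    noise mass has collapsed onto the reference rather than stopping at the
    first transient spike of the histogram.  One (delta, k) point per noise
    level; the curve is made monotone by a running maximum over ascending
    delta.
    """
    records = []
    base = np.random.default_rng(seed)
    for gray in gray_levels:
        clean = np.full((size, size), float(gray))
        for v in variances:
            imgs, refs, deltas = [], [], []
            for _ in range(n_seeds):
                sub = int(base.integers(0, 2**31 - 1))
                noisy = apply_multiplicative_noise(clean, v, seed=sub)
                delta = estimate_cv(noisy).delta
                ref = nlm_smooth(noisy, NLMParams(h=auto_nlm_h(delta, noisy.mean(), h_factor)))
                imgs.append(noisy)
                refs.append(ref)
                deltas.append(delta)
            bands = [band_fraction * float(rf.mean()) for rf in refs]
            k_needed = None
            for k in range(0, k_cap + 1):
                if k:
                    imgs = [gvc_iterate(im, rf, 1, step_divisor=step_divisor) for im, rf in zip(imgs, refs)]
                frac = float(np.mean([
                    np.mean(np.abs(im - rf) <= band) for im, rf, band in zip(imgs, refs, bands)
                ]))
                if frac >= concentration and abs(pooled_histogram_peak(imgs) - gray) <= tol:
                    k_needed = k
                    break
            records.append(
                {"gray": gray, "variance": v, "delta": float(np.mean(deltas)),
                 "k_needed": np.nan if k_needed is None else k_needed}
            )
    df = pd.DataFrame(records).dropna(subset=["k_needed"]).sort_values("delta")
    k_mono = np.maximum.accumulate(df["k_needed"].to_numpy(float))
    deltas = df["delta"].to_numpy(float)
    # keep the last (largest-delta) point of every k level -> step breakpoints
    keep = np.r_[k_mono[1:] != k_mono[:-1], True]
    curve = CalibrationCurve(deltas=deltas[keep], k_values=k_mono[keep])
    return curve, pd.DataFrame(records)
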