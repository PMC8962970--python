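"""Homogeneous-region selection and coefficient-of-variation estimation.

Noise statistics must be read from structure-free parts of an image.  A
high-frequency map is computed with an eight-direction Laplacian; square
windows are ranked by their high-frequency energy (sum of squared responses)
and the lowest-energy, pairwise non-overlapping windows are taken as
homogeneous samples.  The coefficient of variation delta = sigma/mu averaged
over those windows is the noise-level proxy that drives the gray-value
compression iteration count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: 3x3 Laplacian sensitive to all eight neighbor directions.
LAPLACIAN8_KERNEL = np.array(
    [[1.0, 1.0, 1.0],
     [1.0, -8.0, 1.0],
     [1.0, 1.0, 1.0]]
)


@dataclass
class HomogeneousWindows:
    """Non-overlapping square windows ranked by high-frequency energy.

    Coordinates are 0-based, top-left anchored; a window ``(r, c, s)`` covers
    rows ``r:r+s`` and columns ``c:c+s`` (half-open).
    """

    windows: list[tuple[int, int, int]]
    energies: np.ndarray
    window_size: int = 20

    def __iter__(self):
        return iter(self.windows)

    def __len__(self):
        return len(self.windows)


@dataclass
class CVEstimate:
    """Coefficient of variation averaged over P homogeneous regions."""

    delta: float
    per_region: list[tuple[float, float]]  # (variance, mean) per window
    P: int


def laplacian8(image: np.ndarray) -> np.ndarray:
    """Eight-direction Laplacian high-frequency map (reflect border).

    The kernel has -8 at the center and +1 at all 8 neighbors, so it
    annihilates constants and linear ramps and is linear in the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    return ndimage.convolve(image, LAPLACIAN8_KERNEL, mode="reflect")


def _window_energy_map(image: np.ndarray, window_size: int) -> np.ndarray:
    """Sum of squared laplacian8 values over every stride-1 window anchor."""
    hf2 = laplacian8(image) ** 2
    # summed-area table: energy of window anchored at (r, c)
    csum = np.cumsum(np.cumsum(hf2, axis=0), axis=1)
    padded = np.zeros((csum.shape[0] + 1, csum.shape[1] + 1))
    padded[1:, 1:] = csum
    s = window_size
    h, w = image.shape
    energy = (
        padded[s : h + 1, s : w + 1]
        - padded[: h + 1 - s, s : w + 1]
        - padded[s : h + 1, : w + 1 - s]
        + padded[: h + 1 - s, : w + 1 - s]
    )
    # snap cancellation noise to exactly zero so flat windows tie cleanly
    tol = 1e-9 * max(float(energy.max()), 1.0)
    energy[np.abs(energy) <= tol] = 0.0
    return energy


def select_homogeneous_windows(
    image: np.ndarray,
    window_size: int = 20,
    count: int = 20,
) -> HomogeneousWindows:
    """Greedily pick the ``count`` lowest-energy non-overlapping windows.

    Candidates are every stride-1 anchor; ties in energy are broken in
    row-major order, so the selection is deterministic.  Raises if the
    requested count cannot be placed without overlap.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if h < window_size or w < window_size:
        raise ValueError(f"image {image.shape} smaller than window size {window_size}")
    max_windows = (h // window_size) * (w // window_size)
    if count > max_windows:
        raise ValueError(
            f"cannot place {count} non-overlapping {window_size}x{window_size} "
            f"windows in a {h}x{w} image (at most {max_windows})"
        )
    energy = _window_energy_map(image, window_size)
    order = np.argsort(energy, axis=None, kind="stable")  # row-major tie-break
    anchors_r, anchors_c = np.unravel_index(order, energy.shape)

    chosen: list[tuple[int, int, int]] = []
    chosen_energy: list[float] = []
    s = window_size
    for r, c, in zip(anchors_r, anchors_c):
        ok = True
        for (rr, cc, _) in chosen:
            if abs(int(r) - rr) < s and abs(int(c) - cc) < s:
                ok = False
                break
        if ok:
            chosen.append((int(r), int(c), s))
            chosen_energy.append(float(energy[r, c]))
            if len(chosen) == count:
                break
    if len(chosen) < count:
        raise ValueError(f"only {len(chosen)} non-overlapping windows found, {count} requested")
    return HomogeneousWindows(windows=chosen, energies=np.asarray(chosen_energy), window_size=s)


def estimate_cv(
    image: np.ndarray,
    P: int = 8,
    window_size: int = 20,
    use_variance_over_mean: bool = False,
) -> CVEstimate:
    """Coefficient of variation delta averaged over P homogeneous windows.

    delta = (1/P) * sum_i s_i / mu_i with s_i the standard deviation and mu_i
    the mean of the i-th homogeneous window.  On a homogeneous noisy image
    this estimates the whole-image sigma/mu and increases monotonically with
    multiplicative noise variance.  ``use_variance_over_mean`` switches to the
    sigma^2/mu variant for sensitivity checks.
    """
    image = np.asarray(image, dtype=float)
    wins = select_homogeneous_windows(image, window_size=window_size, count=P)
    ratios = []
    per_region = []
    for (r, c, s) in wins:
        block = image[r : r + s, c : c + s]
        mu = float(block.mean())
        var = float(block.var())
        if mu == 0:
            raise ValueError(f"window at ({r}, {c}) has zero mean; degenerate dark region")
        per_region.append((var, mu))
        ratios.append((var if use_variance_over_mean else np.sqrt(var)) / mu)
    return CVEstimate(delta=float(np.mean(ratios)), per_region=per_region, P=P)


def windows_to_csv(windows: HomogeneousWindows, path) -> None:
    """Export selected windows as CSV (row, col, size, energy)."""
    import pandas as pd

    rows = [
        {"row": r, "col": c, "size": s, "energy": e}
        for (r, c, s), e in zip(windows.windows, windows.energies)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
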