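"""Noise-type identification from histogram features (optional tier).

Different noise families leave distinct fingerprints in the intensity
histogram of a homogeneous region: support width, skew, impulse spikes at 0
and 255, the lattice comb of scaled photon counts.  Features are normalized
256-bin histograms pooled (averaged) over homogeneous 20x20 windows; a
multilayer perceptron maps the pooled histogram to softmax posteriors over
the 10 noise families.  At inference, the histograms of ``n_windows``
homogeneous windows drawn from different positions are pooled and the
posterior argmax is the predicted family.

The denoising pipeline does not depend on this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPClassifier

from .noise import FAMILIES, NoiseDataset
from .regions import HomogeneousWindows, select_homogeneous_windows


@dataclass
class NoiseFeatures:
    """Normalized 256-bin histogram of one homogeneous window."""

    histogram: np.ndarray
    window: tuple[int, int, int]


@dataclass
class ClassPosterior:
    """Softmax posterior over the 10 noise families."""

    probs: np.ndarray
    families: tuple[str, ...] = FAMILIES

    @property
    def argmax(self) -> str:
        return self.families[int(np.argmax(self.probs))]


def _window_histogram(block: np.ndarray) -> np.ndarray:
    vals = np.clip(np.rint(np.asarray(block, dtype=float)), 0, 255).astype(np.intp)
    hist = np.bincount(vals.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def extract_features(image: np.ndarray, windows: HomogeneousWindows) -> list[NoiseFeatures]:
    """One normalized histogram per homogeneous window, order preserved."""
    if len(windows) == 0:
        raise ValueError("empty window list")
    image = np.asarray(image, dtype=float)
    return [
        NoiseFeatures(histogram=_window_histogram(image[r : r + s, c : c + s]), window=(r, c, s))
        for (r, c, s) in windows
    ]


def pooled_feature(image: np.ndarray, window_size: int = 20, count: int = 16) -> np.ndarray:
    """Mean histogram over ``count`` homogeneous windows (one feature vector).

    Pooling the window histograms before classification keeps the sampling
    noise of the 256-bin feature low even though individual 20x20 windows
    contain only 400 pixels.
    """
    windows = select_homogeneous_windows(np.asarray(image, dtype=float), window_size, count)
    feats = extract_features(image, windows)
    return np.mean([f.histogram for f in feats], axis=0)


@dataclass
class NoiseClassifierModel:
    mlp: MLPClassifier
    families: tuple[str, ...]
    window_size: int = 20
    windows_per_image: int = 16

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "NoiseClassifierModel":
        import joblib

        return joblib.load(path)


def train_classifier(
    dataset: NoiseDataset,
    lr: float = 0.001,
    epochs: int = 300,
    seed: int = 0,
    window_size: int = 20,
    windows_per_image: int = 16,
    hidden: tuple[int, ...] = (256, 128),
) -> NoiseClassifierModel:
    """Train the histogram-feature classifier on the training split.

    Each training image contributes one pooled-histogram feature built from
    ``windows_per_image`` homogeneous windows (dataset images are pure noise
    maps, so every window qualifies).  Deterministic under a fixed seed.
    """
    labels = sorted(dataset.manifest["family"].unique())
    if len(labels) != len(FAMILIES):
        raise ValueError(f"expected {len(FAMILIES)} classes, got {len(labels)}")
    fam = dataset.manifest["family"].to_numpy()
    idx = dataset.train_indices
    X = np.asarray([pooled_feature(dataset.images[i], window_size, windows_per_image) for i in idx])
    y = fam[idx]
    mlp = MLPClassifier(
        hidden_layer_sizes=hidden,
        learning_rate_init=lr,
        max_iter=epochs,
        random_state=seed,
        early_stopping=False,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warning at a fixed epoch budget
        mlp.fit(X, y)
    return NoiseClassifierModel(
        mlp=mlp, families=tuple(FAMILIES), window_size=window_size,
        windows_per_image=windows_per_image,
    )


def classify_noise(
    image: np.ndarray,
    model: NoiseClassifierModel,
    n_windows: int = 8,
) -> ClassPosterior:
    """Classify one image from the pooled histogram of n homogeneous windows."""
    feat = pooled_feature(image, model.window_size, n_windows)
    probs = model.mlp.predict_proba([feat])[0]
    col = {c: j for j, c in enumerate(model.mlp.classes_)}
    ordered = np.array([probs[col[f]] for f in model.families])
    return ClassPosterior(probs=ordered / ordered.sum(), families=model.families)


def heldout_accuracy(dataset: NoiseDataset, model: NoiseClassifierModel) -> float:
    """Per-image accuracy on the test split."""
    fam = dataset.manifest["family"].to_numpy()
    idx = dataset.test_indices
    hits = 0
    for i in idx:
        post = classify_noise(dataset.images[i], model, n_windows=model.windows_per_image)
        hits += post.argmax == fam[i]
    return hits / len(idx)
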