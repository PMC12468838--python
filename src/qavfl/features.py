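"""Modality-specific preprocessing and class rebalancing.

Text: TF-IDF x Word2Vec document embeddings (see :mod:`qavfl.textproc`),
z-scored per feature.  Images: resize to the encoder's input size and CLAHE
contrast enhancement on the luminance channel.  Signals: Savitzky-Golay
smoothing.  Class imbalance on the training split is handled by SMOTE
oversampling followed by Tomek-link removal.

Note on the Savitzky-Golay default: a window of k = p + 1 (e.g. k=3, p=2)
fits every window exactly and is therefore the identity filter; the package
default is k=7, p=2 so the filter actually denoises, with the identity
configuration still selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from skimage import color, exposure, transform
from sklearn.neighbors import NearestNeighbors

from .textproc import (  # noqa: F401  (re-exported module surface)
    EmbeddingModel,
    TextCorpusStats,
    build_corpus_stats,
    embed_text,
    tfidf_weights,
    tokenize,
    train_word2vec,
)

__all__ = [
    "tokenize", "build_corpus_stats", "tfidf_weights", "train_word2vec",
    "embed_text", "TextCorpusStats", "EmbeddingModel",
    "NormalizationParams", "fit_zscore", "zscore",
    "preprocess_image", "SGConfig", "sg_filter", "smote_tomek",
]

SIGMA_FLOOR = 1e-8


@dataclass
class NormalizationParams:
    """Per-feature mean/sd for z-scoring; sd floored at SIGMA_FLOOR so
    constant features map to zero instead of dividing by zero."""

    mu: np.ndarray
    sigma: np.ndarray


def fit_zscore(X: np.ndarray) -> NormalizationParams:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    mu = X.mean(axis=0)
    sigma = np.maximum(X.std(axis=0), SIGMA_FLOOR)
    return NormalizationParams(mu=mu, sigma=sigma)


def zscore(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != params.mu.shape[0]:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[-1]} features, params {params.mu.shape[0]}"
        )
    return (x - params.mu) / params.sigma


def preprocess_image(image: np.ndarray, target_size: int = 224) -> np.ndarray:
    """Resize to target_size^2 and apply CLAHE to the luminance channel.

    CLAHE uses clip limit 0.01 on an 8x8 tile grid; the image is converted
    to HSV, the value channel equalized, and converted back.  Output values
    lie in [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    resized = transform.resize(image, (target_size, target_size, 3),
                               anti_aliasing=True, preserve_range=True)
    hsv = color.rgb2hsv(np.clip(resized, 0.0, 1.0))
    kernel = max(1, target_size // 8)
    hsv[..., 2] = exposure.equalize_adapthist(
        hsv[..., 2], kernel_size=kernel, clip_limit=0.01
    )
    out = color.hsv2rgb(hsv)
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay window (odd) and polynomial order (p < k)."""

    window: int = 7
    polyorder: int = 2

    def validate(self) -> None:
        if self.window % 2 == 0:
            raise ValueError(f"window must be odd, got {self.window}")
        if self.polyorder >= self.window:
            raise ValueError(
                f"polyorder must be < window, got p={self.polyorder}, k={self.window}"
            )


def sg_filter(s: np.ndarray, cfg: SGConfig = SGConfig()) -> np.ndarray:
    """Least-squares polynomial smoothing over centered windows; edges are
    handled by polynomial extrapolation of the terminal windows."""
    cfg.validate()
    s = np.asarray(s, dtype=np.float64)
    if s.shape[-1] < cfg.window:
        raise ValueError(f"signal length {s.shape[-1]} < window {cfg.window}")
    return savgol_filter(s, cfg.window, cfg.polyorder, mode="interp")


def smote_tomek(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE oversampling of the minority class followed by Tomek-link
    removal of borderline majority samples.

    SMOTE: each synthetic sample interpolates a random minority point
    toward one of its k nearest minority neighbors at a Uniform(0,1)
    fraction, until the class counts are equal.  Tomek: any mutual-nearest-
    neighbor pair with opposite labels has its majority member deleted.
    Minority samples are never removed and majority samples never
    fabricated.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError(f"minority class needs >= 2 samples, got {n_min}")

    rng = np.random.default_rng(seed)
    X_min = X[y == minority]

    n_new = n_maj - n_min
    if n_new > 0:
        k = k_neighbors
        if k > n_min - 1:
            k = n_min - 1
            warnings.warn(
                f"k_neighbors clipped to {k} (minority size {n_min})",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, neigh = nn.kneighbors(X_min)   # column 0 is the point itself
        base = rng.integers(n_min, size=n_new)
        pick = neigh[base, rng.integers(1, k + 1, size=n_new)]
        u = rng.random(n_new)[:, None]
        X_new = X_min[base] + u * (X_min[pick] - X_min[base])
        X_all = np.vstack([X, X_new])
        y_all = np.concatenate([y, np.full(n_new, minority)])
    else:
        X_all, y_all = X.copy(), y.copy()

    # Tomek links: mutual nearest neighbors with opposite labels
    nn_all = NearestNeighbors(n_neighbors=2).fit(X_all)
    _, neigh_all = nn_all.kneighbors(X_all)
    nearest = neigh_all[:, 1]
    drop = np.zeros(len(X_all), dtype=bool)
    for i, j in enumerate(nearest):
        if nearest[j] == i and y_all[i] != y_all[j]:
            if y_all[i] == majority:
                drop[i] = True
            else:
                drop[j] = True
    return X_all[~drop], y_all[~drop]
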