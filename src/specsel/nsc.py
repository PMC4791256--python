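"""Nearest shrunken centroids (NSC) classification and feature ranking.

NSC standardizes each feature's class-centroid deviation from the overall
centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),

soft-thresholds it by Delta,

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0),

and classifies new samples against the reconstructed shrunken centroids.
Features whose deviations shrink to zero in every class drop out of the
classifier, so the threshold Delta simultaneously tunes the model and
selects features.  ``s_i`` is the pooled within-class standard deviation,
``s0`` its median over features (a guard against near-zero denominators),
and ``m_k`` a class-size factor making d_ik roughly a t-statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ranking import RankedFeatureList

__all__ = ["NSCModel", "fit_nsc", "predict_nsc", "rank_features_nsc", "delta_grid"]


@dataclass(frozen=True)
class NSCModel:
    """A fitted shrunken-centroid model."""

    feature_ids: tuple[str, ...]
    classes: tuple[str, ...]
    overall_centroid: np.ndarray      # (p,)
    class_centroids: np.ndarray       # (p, G) raw centroids
    pooled_sd: np.ndarray             # (p,)
    sd_offset: float                  # s0
    class_size_factor: np.ndarray     # (G,) m_k
    priors: np.ndarray                # (G,) sum to 1
    delta: float
    d: np.ndarray                     # (p, G) unshrunken statistics
    shrunken_d: np.ndarray            # (p, G)

    @property
    def shrunken_centroids(self) -> np.ndarray:
        """xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik, shape (p, G)."""
        scale = (self.pooled_sd + self.sd_offset)[:, None] * self.class_size_factor[None, :]
        return self.overall_centroid[:, None] + scale * self.shrunken_d

    def n_active_features(self) -> int:
        """Features with a nonzero shrunken deviation in some class."""
        return int(np.sum(np.abs(self.shrunken_d).max(axis=1) > 0))


def fit_nsc(X: np.ndarray, labels: np.ndarray, delta: float,
            feature_ids: tuple[str, ...] | None = None,
            size_factor: Literal["minus", "plus"] = "minus",
            priors: Literal["empirical", "uniform"] = "empirical") -> NSCModel:
    """Fit an NSC model on a samples-by-features matrix.

    ``size_factor="minus"`` uses m_k = sqrt(1/n_k - 1/n) (the variance of
    xbar_ik - xbar_i when the overall mean includes class k);
    ``"plus"`` switches to the sqrt(1/n_k + 1/n) convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    n, p = X.shape
    classes = tuple(dict.fromkeys(labels))
    G = len(classes)
    if G < 2:
        raise ValueError("need >=2 classes")
    n_k = np.array([np.sum(labels == c) for c in classes])
    if np.any(n_k < 2):
        raise ValueError("every class needs >=2 samples")
    if feature_ids is None:
        feature_ids = tuple(f"f{i}" for i in range(p))

    overall = X.mean(axis=0)
    centroids = np.column_stack([X[labels == c].mean(axis=0) for c in classes])
    ssw = np.zeros(p)
    for g, c in enumerate(classes):
        ssw += ((X[labels == c] - centroids[:, g]) ** 2).sum(axis=0)
    s = np.sqrt(ssw / (n - G))
    s0 = float(np.median(s))
    if size_factor == "minus":
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    elif size_factor == "plus":
        m_k = np.sqrt(1.0 / n_k + 1.0 / n)
    else:
        raise ValueError(f"unknown size_factor {size_factor!r}")

    denom = (s + s0)[:, None] * m_k[None, :]
    d = np.zeros((p, G))
    np.divide(centroids - overall[:, None], denom, out=d, where=denom > 0)
    shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)

    if priors == "empirical":
        pri = n_k / n
    elif priors == "uniform":
        pri = np.full(G, 1.0 / G)
    else:
        raise ValueError(f"unknown priors {priors!r}")

    return NSCModel(
        feature_ids=feature_ids, classes=classes, overall_centroid=overall,
        class_centroids=centroids, pooled_sd=s, sd_offset=s0,
        class_size_factor=m_k, priors=pri, delta=float(delta),
        d=d, shrunken_d=shrunk,
    )


def predict_nsc(model: NSCModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify one sample or a batch against the shrunken centroids.

    The discriminant is delta_k(x) = sum_i (x_i - xbar'_ik)^2/(s_i+s0)^2
    - 2 log pi_k; class probabilities are softmax(-delta_k / 2).
    Returns (predicted labels, probability matrix (n, G)).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(model.feature_ids):
        raise ValueError("feature dimension mismatch")
    sc = model.shrunken_centroids            # (p, G)
    denom = model.pooled_sd + model.sd_offset
    safe = np.where(denom > 0, denom, 1.0)   # zero-sd features carry no signal
    z = (x[:, :, None] - sc[None, :, :]) / safe[None, :, None]
    disc = (z ** 2).sum(axis=1) - 2.0 * np.log(model.priors)[None, :]
    half = -0.5 * disc
    half -= half.max(axis=1, keepdims=True)
    prob = np.exp(half)
    prob /= prob.sum(axis=1, keepdims=True)
    idx = np.argmin(disc, axis=1)
    labels = np.array([model.classes[i] for i in idx])
    return labels, prob


def rank_features_nsc(model: NSCModel) -> RankedFeatureList:
    """Rank features by descending max_k |d_ik| (threshold-independent).

    A feature counts as selected at the model's Delta iff its shrunken
    deviation is nonzero in some class, so N equals the number of features
    the shrunken classifier actually uses.
    """
    score = np.abs(model.d).max(axis=1)
    active = np.abs(model.shrunken_d).max(axis=1) > 0
    order = sorted(range(len(score)), key=lambda i: (-score[i], model.feature_ids[i]))
    return RankedFeatureList(
        method_name="nsc",
        protein_ids=tuple(model.feature_ids[i] for i in order),
        scores=tuple(float(score[i]) for i in order),
        n_selected=int(active.sum()),
    )


def delta_grid(model_or_d: NSCModel | np.ndarray, n_points: int = 30) -> np.ndarray:
    """Evenly spaced shrinkage thresholds from 0 to max |d_ik|."""
    d = model_or_d.d if isinstance(model_or_d, NSCModel) else np.asarray(model_or_d)
    top = float(np.abs(d).max()) if d.size else 0.0
    return np.linspace(0.0, top, n_points)
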