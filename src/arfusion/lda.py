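"""Fisher linear discriminant analysis yielding the f1/f2 discriminant plane.

The discriminant axes solve the generalized eigenproblem
``S_b w = lambda S_w w`` (between-class versus within-class scatter); with
three training classes two informative axes exist, and their projections
(f1, f2) form the third learning graph of the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["DiscriminantModel", "fit_lda", "project"]


@dataclass
class DiscriminantModel:
    """Fitted two-axis Fisher discriminant with its feature scaling.

    Inputs are standardized (mean/std stored), so projecting the pooled grand
    mean yields (0, 0).  Axes are oriented so the positive class mean has
    non-negative coordinates.
    """

    feature_names: tuple[str, ...]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    weights: np.ndarray  # shape (2, n_features), rows w1 and w2
    eigenvalues: np.ndarray  # shape (2,)
    classes: tuple[str, ...]
    class_means: np.ndarray  # shape (n_classes, 2), discriminant space
    positive_label: str

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "weights": self.weights.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "classes": list(self.classes),
            "class_means": self.class_means.tolist(),
            "positive_label": self.positive_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            scale_mean=np.asarray(d["scale_mean"], dtype=float),
            scale_std=np.asarray(d["scale_std"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            classes=tuple(d["classes"]),
            class_means=np.asarray(d["class_means"], dtype=float),
            positive_label=d["positive_label"],
        )


def _scatter_matrices(X: np.ndarray, y: np.ndarray, classes: np.ndarray):
    grand = X.mean(axis=0)
    d = X.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        dev = Xc - mu
        Sw += dev.T @ dev
        diff = (mu - grand)[:, None]
        Sb += len(Xc) * (diff @ diff.T)
    return Sw, Sb


def fit_lda(
    X,
    labels,
    feature_names: tuple[str, ...] | None = None,
    positive_label: str | None = None,
) -> DiscriminantModel:
    """Fit the two-axis discriminant.

    Requires at least three distinct classes (two discriminant axes), at least
    two samples per class, and no constant feature.  The within-class scatter
    is ridge-regularized by ``1e-6 * trace(Sw)/d * I`` when singular.
    ``positive_label`` (default: first class in sorted order) fixes the sign
    convention: that class's discriminant-space mean is non-negative on both
    axes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in labels])
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    if len(y) != X.shape[0]:
        raise ValueError("label count does not match row count")
    classes = np.unique(y)
    if len(classes) < 3:
        raise ValueError(f"need >= 3 classes for two discriminant axes, got {len(classes)}")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    if X.shape[0] <= len(classes):
        raise ValueError("fewer samples than classes")

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    if np.any(std == 0):
        dead = [i for i, s in enumerate(std) if s == 0]
        raise ValueError(f"constant feature(s) at column(s) {dead}")
    Xs = (X - mean) / std

    Sw, Sb = _scatter_matrices(Xs, y, classes)
    d = X.shape[1]
    # regularize only when Sw is (numerically) singular
    if np.linalg.matrix_rank(Sw) < d or np.linalg.cond(Sw) > 1e12:
        Sw = Sw + (1e-6 * np.trace(Sw) / d) * np.eye(d)

    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    evals = evals[order][:2]
    W = evecs[:, order][:, :2].T  # rows are w1, w2

    if positive_label is None:
        positive_label = str(classes[0])
    if positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among classes")
    pos_mean = Xs[y == positive_label].mean(axis=0)
    for k in range(2):
        if float(W[k] @ pos_mean) < 0:
            W[k] = -W[k]

    class_means = np.vstack([(W @ Xs[y == c].mean(axis=0)) for c in classes])
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(d))
    return DiscriminantModel(
        feature_names=tuple(feature_names),
        scale_mean=mean,
        scale_std=std,
        weights=W,
        eigenvalues=np.asarray(evals, dtype=float),
        classes=tuple(str(c) for c in classes),
        class_means=class_means,
        positive_label=positive_label,
    )


def project(model: DiscriminantModel, features) -> np.ndarray:
    """Project feature row(s) onto (f1, f2).

    Accepts a single vector (returns shape ``(2,)``) or a matrix
    (returns ``(n, 2)``).  Linearity makes batch and per-row projection agree.
    """
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    Xs = (X - model.scale_mean) / model.scale_std
    F = Xs @ model.weights.T
    return F[0] if single else F
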