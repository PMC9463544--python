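"""Sparse multinomial logistic regression (SMLR) for spectral classification.

A Bayesian multinomial logistic classifier with a Laplacian (L1) prior on
the weights: training maximizes the multinomial log-likelihood minus
``lambda * sum(|w|)`` with the intercept unpenalized and the last class
pinned at zero weights.  Sparsity makes the classifier well suited to
feasibility studies on small spectral datasets - only the wavelengths
that carry class information keep nonzero weights, and the model yields
posterior class probabilities rather than hard labels.

The optimizer is a cyclic coordinate-wise bound (majorize-minimize)
scheme: the multinomial Hessian is bounded by ``(1/2)(1 - 1/M) X^T X``
on its diagonal, giving closed-form soft-threshold updates per feature
row.  Each surrogate step increases the penalized likelihood, so the
iteration is monotone and needs no step-size tuning.

Evaluation uses leave-one-out cross-validation with standardization
refit inside every fold, and confusion/accuracy summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "LabeledSpectra",
    "SmlrModel",
    "ConfusionSummary",
    "band_normalize",
    "train_smlr",
    "predict_posterior",
    "loocv",
    "confusion_and_accuracy",
]


def band_normalize(X, wavelengths_nm, junction_nm: float = 1000.0) -> np.ndarray:
    """Normalize each spectrometer band of every row to unit mean.

    Dual-band spectra carry an independent multiplicative gain per
    spectrometer on every acquisition; row-wise scaling of the VIS/NIR
    (<= junction) and SWIR (> junction) segments separately removes that
    common-mode factor so classifier weights respond to line shape, not
    acquisition gain.  Feature preparation for :func:`train_smlr`.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(wavelengths_nm, dtype=float)
    if X.shape[1] != w.size:
        raise ValueError("wavelength grid does not match feature count")
    out = X.copy()
    for sel in (w <= junction_nm, w > junction_nm):
        if np.any(sel):
            seg_mean = out[:, sel].mean(axis=1, keepdims=True)
            if np.any(seg_mean == 0):
                raise ValueError("cannot band-normalize a zero-mean segment")
            out[:, sel] /= seg_mean
    return out


@dataclass(frozen=True)
class LabeledSpectra:
    """Feature matrix (rows = spectra on a common grid) with class labels."""

    X: np.ndarray
    labels: np.ndarray
    wavelengths_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        labels = np.asarray(self.labels)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (spectra x features)")
        if labels.shape[0] != X.shape[0]:
            raise ValueError("one label per row required")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size < 2:
            raise ValueError("need at least two classes")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)

    @property
    def class_names(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx) -> "LabeledSpectra":
        return LabeledSpectra(self.X[idx], self.labels[idx], self.wavelengths_nm)


@dataclass(frozen=True)
class SmlrModel:
    """Fitted SMLR weights: (features + intercept) x classes, last class zero."""

    weights: np.ndarray  # (F+1, M) with column M-1 all zeros
    class_names: np.ndarray
    prior_scale: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    converged: bool = True
    n_sweeps: int = 0

    @property
    def selected_features(self) -> np.ndarray:
        """Indices of features with any nonzero weight (intercept excluded)."""
        return np.flatnonzero(np.any(self.weights[1:] != 0.0, axis=1))


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-class confusion counts and overall accuracy."""

    labels: np.ndarray
    matrix: np.ndarray  # rows = true class, columns = predicted

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.matrix))

    @property
    def misclassified(self) -> int:
        return self.total - self.correct

    @property
    def accuracy(self) -> float:
        return self.correct / self.total

    @property
    def per_class_correct(self) -> np.ndarray:
        return np.diagonal(self.matrix)

    @property
    def per_class_total(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def _one_hot(labels: np.ndarray, class_names: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(class_names, labels)
    out = np.zeros((labels.shape[0], class_names.size))
    out[np.arange(labels.shape[0]), idx] = 1.0
    return out


def _softmax_scores(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


@njit(cache=True)
def _cd_sweeps(X, Y, B, lam, max_sweeps, tol):
    """Cyclic coordinate-wise bound-optimization sweeps (compiled core).

    Row 0 of ``X`` is the intercept column (unpenalized); the last class
    column of the weight matrix stays pinned at zero.
    """
    n, F1 = X.shape
    M = Y.shape[1]
    W = np.zeros((F1, M))
    scores = np.zeros((n, M))
    P = np.full((n, M), 1.0 / M)
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(F1):
            changed = False
            for c in range(M - 1):
                g = 0.0
                for i in range(n):
                    g += X[i, j] * (Y[i, c] - P[i, c])
                prop = W[j, c] + g / B[j]
                if j == 0 or lam == 0.0:
                    new = prop
                else:
                    if prop > lam / B[j]:
                        new = prop - lam / B[j]
                    elif prop < -lam / B[j]:
                        new = prop + lam / B[j]
                    else:
                        new = 0.0
                delta = new - W[j, c]
                if delta != 0.0:
                    W[j, c] = new
                    for i in range(n):
                        scores[i, c] += X[i, j] * delta
                    changed = True
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            if changed:
                # refresh the softmax probabilities
                for i in range(n):
                    m = scores[i, 0]
                    for c in range(1, M):
                        if scores[i, c] > m:
                            m = scores[i, c]
                    tot = 0.0
                    for c in range(M):
                        e = np.exp(scores[i, c] - m)
                        P[i, c] = e
                        tot += e
                    for c in range(M):
                        P[i, c] /= tot
        if max_delta < tol:
            converged = True
            break
    return W, sweep, converged


def train_smlr(
    data: LabeledSpectra,
    prior_scale: float = 0.1,
    standardize: bool = True,
    max_sweeps: int = 10_000,
    tol: float = 1e-6,
) -> SmlrModel:
    """Fit SMLR by cyclic coordinate-wise bound optimization.

    ``prior_scale`` is the Laplacian prior scale (L1 penalty weight) on
    standardized features; 0 gives plain multinomial regression.
    Convergence is declared when the largest weight change in a sweep
    drops below ``tol``; otherwise the model carries ``converged=False``
    and a warning is emitted rather than raising.
    """
    if prior_scale < 0:
        raise ValueError("prior scale must be non-negative")
    classes = data.class_names
    M = classes.size
    n, F = data.X.shape
    if standardize:
        mean = data.X.mean(axis=0)
        scale = data.X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(F)
        scale = np.ones(F)
    X = np.hstack([np.ones((n, 1)), (data.X - mean) / scale])
    Y = _one_hot(data.labels, classes)

    # diagonal bound of the multinomial Hessian per feature row
    B = 0.5 * (1.0 - 1.0 / M) * np.sum(X * X, axis=0)
    B[B == 0] = 1.0

    W, sweep, converged = _cd_sweeps(
        np.ascontiguousarray(X), np.ascontiguousarray(Y), B,
        float(prior_scale), int(max_sweeps), float(tol),
    )
    if not converged:
        warnings.warn(
            f"SMLR did not converge within {max_sweeps} sweeps",
            stacklevel=2,
        )
    return SmlrModel(
        weights=W,
        class_names=classes,
        prior_scale=prior_scale,
        feature_mean=mean,
        feature_scale=scale,
        converged=converged,
        n_sweeps=sweep,
    )


def predict_posterior(model: SmlrModel, spectrum) -> np.ndarray:
    """Per-class posterior probabilities for one spectrum or a matrix."""
    x = np.asarray(spectrum, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.feature_mean.size:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model "
            f"({model.feature_mean.size})"
        )
    Xs = np.hstack([
        np.ones((X.shape[0], 1)),
        (X - model.feature_mean) / model.feature_scale,
    ])
    P = _softmax_scores(Xs @ model.weights)
    return P[0] if single else P


def predict_label(model: SmlrModel, spectrum):
    """Argmax class (ties broken toward the lowest class index)."""
    post = predict_posterior(model, spectrum)
    post2 = np.atleast_2d(post)
    idx = np.argmax(post2, axis=1)  # argmax returns the first maximal index
    labels = model.class_names[idx]
    return labels[0] if post2.shape[0] == 1 and np.ndim(spectrum) == 1 else labels


def loocv(data: LabeledSpectra, prior_scale: float = 0.1, **fit_kwargs) -> np.ndarray:
    """Leave-one-out predicted label per row.

    Standardization is refit inside every fold.  A fold that loses an
    entire class (singleton class) emits a warning but still predicts.
    """
    n = data.X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least three rows")
    _, counts = np.unique(data.labels, return_counts=True)
    if np.any(counts < 2):
        warnings.warn(
            "singleton class present: some folds lose an entire class",
            stacklevel=2,
        )
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_labels = data.labels[mask]
        if np.unique(fold_labels).size < 2:
            # degenerate fold: only one class left to train on
            preds.append(fold_labels[0])
            continue
        fold = LabeledSpectra(data.X[mask], fold_labels, data.wavelengths_nm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_smlr(fold, prior_scale=prior_scale, **fit_kwargs)
        preds.append(predict_label(model, data.X[i]))
    return np.asarray(preds)


def confusion_and_accuracy(true_labels, predicted_labels) -> ConfusionSummary:
    """Confusion counts and overall accuracy (trace / total)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape[0] != p.shape[0]:
        raise ValueError("label vectors differ in length")
    labels = np.unique(np.concatenate([t, p]))
    k = labels.size
    mat = np.zeros((k, k), dtype=int)
    ti = np.searchsorted(labels, t)
    pi = np.searchsorted(labels, p)
    np.add.at(mat, (ti, pi), 1)
    return ConfusionSummary(labels=labels, matrix=mat)
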