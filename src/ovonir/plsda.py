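"""Three-class PLS-DA on numerically coded labels (0 normal, 1 bloody,
2 yolk-destroyed).

A single-response (PLS1) NIPALS decomposition is fitted to the
column-centered spectral matrix X and the centered numeric label vector y:
X = T P' + E, y-side scores/loadings U, Q, and a regression vector beta
mapping centered X to centered y.  Class assignment thresholds the
continuous score at 0.5 and 1.5 (nearest label, boundary to the upper
class).  The weighted regression coefficient used for wavelength ranking is
beta scaled by each column's training standard deviation (autoscaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .spectra import SpectraSet

THRESHOLDS = (0.5, 1.5)


@dataclass
class PLSDAModel:
    """Fitted PLS1 discriminant model with its full decomposition."""

    A: int
    axis: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    W: np.ndarray  # p x A weights
    T: np.ndarray  # n x A X-scores
    P: np.ndarray  # p x A X-loadings
    U: np.ndarray  # n x A Y-scores
    Q: np.ndarray  # A Y-loadings
    E: np.ndarray  # n x p X-residual
    F: np.ndarray  # n y-residual
    beta: np.ndarray  # p regression vector (centered X -> centered y)
    thresholds: tuple[float, float] = THRESHOLDS


@dataclass
class ClassificationReport:
    """3x3 confusion table plus one-vs-rest counts and rates per class."""

    confusion: np.ndarray
    per_class: dict[int, dict[str, float]]
    total_accuracy: float
    n: int


def split_calibration_validation(
    ds: SpectraSet, frac: float = 0.70, seed: int = 0
) -> tuple[SpectraSet, SpectraSet]:
    """Random row split stratified by class; each class keeps
    floor(frac * n_class) rows in the calibration set."""
    if not 0 < frac < 1:
        raise ValueError("frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(ds.y):
        rows = np.flatnonzero(ds.y == cls)
        if rows.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 rows; cannot split")
        rows = rng.permutation(rows)
        k = int(np.floor(frac * rows.size))
        k = min(max(k, 1), rows.size - 1)
        train_idx.extend(rows[:k])
        test_idx.extend(rows[k:])
    return ds.take_rows(np.sort(train_idx)), ds.take_rows(np.sort(test_idx))


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, A: int):
    """PLS1 NIPALS on pre-centered data.  Sign convention: the first
    nonzero element of each weight vector is forced positive."""
    n, p = Xc.shape
    Xd = Xc.copy()
    yd = yc.copy()
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    U = np.zeros((n, A))
    Q = np.zeros(A)
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            raise ValueError(
                f"X-y covariance vanished at component {a + 1}; reduce A"
            )
        w = w / nw
        nz = np.flatnonzero(np.abs(w) > 1e-12)
        if nz.size and w[nz[0]] < 0:
            w = -w
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-14:
            raise ValueError(f"degenerate score at component {a + 1}; reduce A")
        pvec = Xd.T @ t / tt
        q = (yd @ t) / tt
        # in PLS1 the y-side scores coincide with the X-scores (inner
        # relation u = t), which makes y = U Q' + F hold exactly
        u = t
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q * t
        W[:, a], T[:, a], P[:, a], U[:, a], Q[a] = w, t, pvec, u, q
    beta = W @ np.linalg.solve(P.T @ W, Q)
    return W, T, P, U, Q, Xd, yd, beta


def fit(train: SpectraSet, A: int) -> PLSDAModel:
    """Fit PLS-DA with A latent variables on a calibration set."""
    X, y = train.X, train.y.astype(float)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; restrict the range first")
    x_sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("X has no variance; cannot fit")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, T, P, U, Q, E, F, beta = _nipals_pls1(X - x_mean, y - y_mean, A)
    return PLSDAModel(
        A=A, axis=train.axis.copy(), x_mean=x_mean, x_sd=x_sd, y_mean=y_mean,
        W=W, T=T, P=P, U=U, Q=Q, E=E, F=F, beta=beta,
    )


def predict(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores yhat and hard labels (0/1/2).

    Label rule: 0 if yhat < 0.5, 1 if 0.5 <= yhat < 1.5, else 2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} wavelengths, got {X.shape[1]}"
        )
    yhat = (X - model.x_mean) @ model.beta + model.y_mean
    lo, hi = model.thresholds
    labels = np.where(yhat < lo, 0, np.where(yhat < hi, 1, 2))
    return yhat, labels


def scores_to_labels(yhat: np.ndarray) -> np.ndarray:
    lo, hi = THRESHOLDS
    return np.where(yhat < lo, 0, np.where(yhat < hi, 1, 2))


def choose_components(
    train: SpectraSet,
    A_max: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick the latent-variable count by K-fold cross-validation.

    Uses the one-standard-error convention: among A whose CV
    misclassification rate is within one standard error (over folds) of the
    minimum, the smallest A wins — so an uninformative response collapses
    to A=1 rather than chasing noise.
    """
    n, p = train.X.shape
    A_cap = min(A_max, p, n - int(np.ceil(n / folds)) - 1)
    A_cap = max(A_cap, 1)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    err = np.zeros((A_cap, folds))
    for f, (tr, va) in enumerate(skf.split(train.X, train.y)):
        sub = train.take_rows(tr)
        val = train.take_rows(va)
        a_fit = min(A_cap, sub.n - 1, p)
        model = fit(sub, a_fit)
        # truncating the decomposition gives every smaller-A prediction
        for a in range(1, A_cap + 1):
            beta_a = _beta_truncated(model, min(a, a_fit))
            yhat = (val.X - model.x_mean) @ beta_a + model.y_mean
            err[a - 1, f] = np.mean(scores_to_labels(yhat) != val.y)
    mean_err = err.mean(axis=1)
    se = err.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_err))
    tol = mean_err[best] + se[best]
    return int(np.flatnonzero(mean_err <= tol + 1e-12)[0]) + 1


def _beta_truncated(model: PLSDAModel, a: int) -> np.ndarray:
    W, P, Q = model.W[:, :a], model.P[:, :a], model.Q[:a]
    return W @ np.linalg.solve(P.T @ W, Q)


def evaluate(truth: np.ndarray, labels: np.ndarray) -> ClassificationReport:
    """Confusion table, one-vs-rest Tp/Tn/Fp/Fn, accuracy, recall, precision.

    Per-class accuracy is (Tp+Tn)/(Tp+Tn+Fp+Fn)*100 in the one-vs-rest
    sense; total accuracy is the fraction of rows whose label matches the
    truth.  Undefined precision/recall (zero denominator) is reported as
    NaN, never as 0.
    """
    truth = np.asarray(truth, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if truth.size == 0:
        raise ValueError("cannot evaluate an empty label set")
    if truth.shape != labels.shape:
        raise ValueError("truth and labels must have equal length")
    n = truth.size
    confusion = np.zeros((3, 3), dtype=int)
    for t, l in zip(truth, labels):
        confusion[t, l] += 1
    per_class: dict[int, dict[str, float]] = {}
    for cls in (0, 1, 2):
        tp = int(confusion[cls, cls])
        fn = int(confusion[cls].sum() - tp)
        fp = int(confusion[:, cls].sum() - tp)
        tn = int(n - tp - fn - fp)
        per_class[cls] = {
            "Tp": tp, "Tn": tn, "Fp": fp, "Fn": fn,
            "accuracy": 100.0 * (tp + tn) / n,
            "recall": 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan"),
            "precision": 100.0 * tp / (tp + fp) if (tp + fp) > 0 else float("nan"),
        }
    total = 100.0 * np.trace(confusion) / n
    return ClassificationReport(
        confusion=confusion, per_class=per_class, total_accuracy=total, n=n
    )


def weighted_beta(model: PLSDAModel) -> np.ndarray:
    """Autoscaled (weighted) regression coefficient: beta_j * sd_j.

    Equals, up to one positive constant, the coefficient of a model fitted
    on column-autoscaled X.  Zero-variance columns are flagged NaN.
    """
    wb = model.beta * model.x_sd
    wb = np.where(model.x_sd <= 0, np.nan, wb)
    return wb
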