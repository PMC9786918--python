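"""Wavelength band selection: WRC peaks, sequential forward selection,
successive projections, forward stepwise regression, and the pooling +
threshold cascade that reduces the working set to a handful of bands.

The cascade mirrors the reduction workflow: run WRC/SFS/SPA on the
calibration set restricted to the beta-informative window (550-600 nm by
default), pool their picks, prune the pooled set with forward stepwise
regression at descending p-value thresholds, then refit and evaluate a
PLS-DA model per resulting band set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter
from sklearn.model_selection import StratifiedKFold

from . import plsda
from .spectra import SpectraSet

#: stepwise entry thresholds; None is the pass-through row (pooled set kept)
DEFAULT_THRESHOLDS: tuple[float | None, ...] = (None, 0.05, 0.01, 0.001, 0.0001)

SELECTION_WINDOW_NM = (550.0, 600.0)
MODELLING_WINDOW_NM = (500.0, 680.0)


@dataclass
class SelectionResult:
    """Ordered wavelength picks of one selector plus its per-step trace."""

    method: str
    wavelengths_nm: np.ndarray
    indices: np.ndarray
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        if self.wavelengths_nm.size != self.indices.size:
            raise ValueError("wavelengths and indices must align")
        if np.unique(self.indices).size != self.indices.size:
            raise ValueError("selected indices must be unique")
        order = np.argsort(self.wavelengths_nm)
        self.wavelengths_nm = self.wavelengths_nm[order]
        self.indices = self.indices[order]

    @property
    def k(self) -> int:
        return self.indices.size


# ---------------------------------------------------------------------------
# WRC


def _local_maxima(v: np.ndarray) -> list[int]:
    """Interior local maxima of v; plateaus collapse to their center index."""
    peaks: list[int] = []
    n = v.size
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def wrc_select(
    wbeta: np.ndarray,
    axis: np.ndarray,
    intensity_mean: np.ndarray,
    k_max: int = 5,
) -> SelectionResult:
    """Peaks of |weighted beta|, ranked by |wbeta| x mean intensity.

    A high coefficient at a wavelength where the lamp delivers little light
    carries little usable signal, so peaks are ranked by the product of the
    coefficient magnitude and the mean spectral intensity there.
    """
    wbeta = np.asarray(wbeta, dtype=float)
    axis = np.asarray(axis, dtype=float)
    intensity_mean = np.asarray(intensity_mean, dtype=float)
    if not (wbeta.size == axis.size == intensity_mean.size):
        raise ValueError("wbeta, axis and intensity_mean must align")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    mag = np.abs(np.nan_to_num(wbeta, nan=0.0))
    peaks = _local_maxima(mag)
    if not peaks:
        raise ValueError("no interior peaks in |weighted beta|")
    score = mag[peaks] * np.abs(intensity_mean[peaks])
    order = np.argsort(-score, kind="stable")
    chosen = [peaks[i] for i in order[: min(k_max, len(peaks))]]
    trace = pd.DataFrame(
        {
            "step": np.arange(1, len(chosen) + 1),
            "index": chosen,
            "wavelength_nm": axis[chosen],
            "criterion": score[order[: len(chosen)]],
        }
    )
    return SelectionResult("wrc", axis[chosen], np.array(chosen), trace)


# ---------------------------------------------------------------------------
# SFS


def _cv_misclassification(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int
) -> float:
    """CV misclassification rate of a PLS-DA model on the given columns."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, va in skf.split(X, y):
        Xtr, ytr = X[tr], y[tr]
        A = max(1, min(Xtr.shape[1], Xtr.shape[0] - 1, 5))
        axis = np.arange(Xtr.shape[1], dtype=float)
        sub = SpectraSet(Xtr, axis, ytr, np.arange(len(ytr)))
        try:
            model = plsda.fit(sub, A)
        except ValueError:
            errs.append(1.0)
            continue
        _, labels = plsda.predict(model, X[va])
        errs.append(float(np.mean(labels != y[va])))
    return float(np.mean(errs))


def sfs_select(
    train: SpectraSet, k: int = 3, folds: int = 5, seed: int = 0
) -> SelectionResult:
    """Greedy forward selection minimizing CV misclassification.

    At each step every unselected column is tried in union with the current
    set; the column with the lowest cross-validated misclassification rate
    of the PLS-DA model enters.  Ties break toward the lower wavelength.
    """
    if k > train.p:
        raise ValueError("k exceeds the number of available wavelengths")
    selected: list[int] = []
    rows = []
    for step in range(k):
        best_err, best_col = np.inf, None
        for col in range(train.p):
            if col in selected:
                continue
            cols = selected + [col]
            err = _cv_misclassification(
                train.X[:, cols], train.y, folds=folds, seed=seed
            )
            if err < best_err - 1e-12:
                best_err, best_col = err, col
        if best_col is None:
            break
        selected.append(best_col)
        rows.append(
            {
                "step": step + 1,
                "index": best_col,
                "wavelength_nm": train.axis[best_col],
                "criterion": best_err,
            }
        )
    return SelectionResult(
        "sfs", train.axis[selected], np.array(selected), pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# SPA


def spa_chain(Xc: np.ndarray, start: int, k: int) -> tuple[list[int], list[float]]:
    """Successive-projection chain from one start column.

    At each step every unselected column is projected onto the orthogonal
    complement of the span of the selected columns; the column with maximum
    projected norm is added.  Stops early if all projected norms fall below
    1e-12 (rank exhausted).
    """
    n, p = Xc.shape
    chain = [start]
    norms = [float(np.linalg.norm(Xc[:, start]))]
    basis = np.zeros((n, 0))
    v = Xc[:, start]
    nv = np.linalg.norm(v)
    if nv <= 1e-12:
        return chain, norms
    basis = (v / nv)[:, None]
    while len(chain) < k:
        proj = Xc - basis @ (basis.T @ Xc)
        pn = np.linalg.norm(proj, axis=0)
        pn[chain] = -np.inf
        best = int(np.argmax(pn))
        if pn[best] < 1e-12:
            break
        chain.append(best)
        norms.append(float(pn[best]))
        v = proj[:, best]
        basis = np.hstack([basis, (v / np.linalg.norm(v))[:, None]])
    return chain, norms


def spa_select(
    train: SpectraSet, k: int = 3, seed: int = 0, start: int | None = None
) -> SelectionResult:
    """Successive projections over all start columns, scored by an internal
    seeded 70/30 split misclassification of a PLS-DA model per chain.

    Passing ``start`` fixes the chain's first column (no scoring loop).
    """
    if k > min(train.n - 1, train.p):
        raise ValueError("k exceeds min(n-1, p)")
    Xc = train.X - train.X.mean(axis=0)
    if start is not None:
        chain, norms = spa_chain(Xc, start, k)
        trace = pd.DataFrame(
            {
                "step": np.arange(1, len(chain) + 1),
                "index": chain,
                "wavelength_nm": train.axis[chain],
                "criterion": norms,
            }
        )
        if len(chain) < k:
            trace.attrs["warning"] = "rank exhausted before k columns"
        return SelectionResult("spa", train.axis[chain], np.array(chain), trace)

    cal, val = plsda.split_calibration_validation(train, frac=0.70, seed=seed)
    best = None
    for s in range(train.p):
        chain, norms = spa_chain(Xc, s, k)
        if len(chain) < k:
            continue
        cols = np.sort(chain)
        A = max(1, min(len(chain), cal.n - 1, 5))
        model = plsda.fit(cal.take_columns(cols), A)
        _, labels = plsda.predict(model, val.X[:, cols])
        err = float(np.mean(labels != val.y))
        if best is None or err < best[0] - 1e-12:
            best = (err, s, chain, norms)
    if best is None:
        raise ValueError("no start column yields a full-rank chain of length k")
    err, s, chain, norms = best
    trace = pd.DataFrame(
        {
            "step": np.arange(1, len(chain) + 1),
            "index": chain,
            "wavelength_nm": train.axis[chain],
            "criterion": norms,
        }
    )
    trace.attrs["start"] = s
    trace.attrs["misclassification"] = err
    return SelectionResult("spa", train.axis[chain], np.array(chain), trace)


# ---------------------------------------------------------------------------
# Pooling and forward stepwise


def pool_bands(results: list[SelectionResult]) -> SelectionResult:
    """Sorted de-duplicated union of selector outputs."""
    if not results:
        raise ValueError("pool_bands needs at least one selection result")
    pairs = {}
    for r in results:
        for w, i in zip(r.wavelengths_nm, r.indices):
            pairs[int(i)] = float(w)
    idx = np.array(sorted(pairs))
    return SelectionResult(
        "pooled", np.array([pairs[i] for i in idx]), idx,
        pd.DataFrame({"index": idx, "wavelength_nm": [pairs[i] for i in idx]}),
    )


def partial_f_pvalue(rss0: float, rss1: float, n: int, k1: int) -> float:
    """p-value of the partial F test for one added regressor.

    rss0/rss1 are residual sums of squares of the nested and extended OLS
    models; k1 counts regressors in the extended model (without intercept).
    """
    df2 = n - k1 - 1
    if df2 <= 0:
        return float("nan")
    if rss1 <= 0:
        return 0.0
    fstat = (rss0 - rss1) / (rss1 / df2)
    if fstat < 0:
        fstat = 0.0
    return float(stats.f.sf(fstat, 1, df2))


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    Z = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    r = y - Z @ coef
    return float(r @ r)


def stepwise_select(
    train: SpectraSet, p_enter: float | None = 0.05
) -> SelectionResult:
    """Forward stepwise OLS of the numeric label on the pooled bands.

    At each step the partial-F p-value of every unselected candidate added
    to the current model is computed; the candidate with the smallest
    p-value enters if it clears ``p_enter``.  ``p_enter=None`` is the
    pass-through row: the pooled set is returned unchanged.
    """
    if train.p == 0:
        raise ValueError("empty pooled band set")
    if p_enter is None:
        idx = np.arange(train.p)
        return SelectionResult(
            "stepwise", train.axis[idx], idx,
            pd.DataFrame({"index": idx, "wavelength_nm": train.axis[idx],
                          "p_value": np.nan, "note": "pass-through"}),
        )
    if not 0 < p_enter < 1:
        raise ValueError("p_enter must lie strictly between 0 and 1")
    y = train.y.astype(float)
    n = train.n
    selected: list[int] = []
    rows = []
    rss_current = _ols_rss(np.empty((n, 0)), y)
    while len(selected) < train.p:
        k1 = len(selected) + 1
        if n <= k1 + 2:
            rows.append({"step": len(rows) + 1, "index": -1,
                         "wavelength_nm": np.nan, "p_value": np.nan,
                         "note": "stopped: too few rows for further terms"})
            break
        best = None
        for col in range(train.p):
            if col in selected:
                continue
            rss1 = _ols_rss(train.X[:, selected + [col]], y)
            pval = partial_f_pvalue(rss_current, rss1, n, k1)
            if best is None or pval < best[0] - 1e-15 or (
                abs(pval - best[0]) <= 1e-15 and train.axis[col] < train.axis[best[1]]
            ):
                best = (pval, col, rss1)
        pval, col, rss1 = best
        if not pval < p_enter:
            break
        selected.append(col)
        rss_current = rss1
        rows.append({"step": len(selected), "index": col,
                     "wavelength_nm": train.axis[col], "p_value": pval,
                     "note": ""})
    return SelectionResult(
        "stepwise", train.axis[selected], np.array(selected, dtype=int),
        pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class CascadeRow:
    """One evaluated reduced-band model (one report row)."""

    stage: str
    threshold: float | None
    bands_nm: np.ndarray
    n_bands: int
    report: plsda.ClassificationReport


def cascade(
    train: SpectraSet,
    test: SpectraSet,
    selection_window_nm: tuple[float, float] = SELECTION_WINDOW_NM,
    wrc_k_max: int = 5,
    sfs_k: int = 3,
    spa_k: int = 3,
    thresholds: tuple[float | None, ...] = DEFAULT_THRESHOLDS,
    seed: int = 0,
    folds: int = 5,
) -> tuple[dict[str, SelectionResult], list[CascadeRow]]:
    """Full reduction workflow on a calibrated, preprocessed split.

    Returns the per-selector results (wrc/sfs/spa/pooled plus one stepwise
    entry per threshold) and the evaluated reduced-band models.
    """
    lo, hi = selection_window_nm
    win_cols = np.flatnonzero((train.axis >= lo) & (train.axis <= hi))
    if win_cols.size == 0:
        raise ValueError("selection window contains no wavelengths")
    twin = train.take_columns(win_cols)

    # few latent variables and a short smoothing pass keep the coefficient
    # curve stable enough that each physical absorption feature appears as
    # one ranked peak instead of a cluster of sampling-noise wiggles
    A_win = plsda.choose_components(twin, A_max=5, folds=folds, seed=seed)
    wrc_model = plsda.fit(twin, A_win)
    wb = plsda.weighted_beta(wrc_model)
    if twin.p >= 11:
        wb = savgol_filter(wb, window_length=17, polyorder=2, mode="interp")
    wrc = wrc_select(wb, twin.axis, twin.X.mean(axis=0), k_max=wrc_k_max)
    sfs = sfs_select(twin, k=sfs_k, folds=folds, seed=seed)
    spa = spa_select(twin, k=spa_k, seed=seed)

    def to_parent(r: SelectionResult) -> SelectionResult:
        return SelectionResult(r.method, r.wavelengths_nm,
                               win_cols[r.indices], r.trace)

    results = {"wrc": to_parent(wrc), "sfs": to_parent(sfs), "spa": to_parent(spa)}
    pooled = pool_bands(list(results.values()))
    results["pooled"] = pooled

    rows: list[CascadeRow] = []
    for thr in thresholds:
        sub = train.take_columns(pooled.indices)
        step = stepwise_select(sub, p_enter=thr)
        band_idx = pooled.indices[step.indices]
        if band_idx.size == 0:
            continue
        results[f"stepwise_{'pass' if thr is None else thr}"] = SelectionResult(
            "stepwise", step.wavelengths_nm, band_idx, step.trace
        )
        tr_sub = train.take_columns(band_idx)
        te_sub = test.take_columns(band_idx)
        A = plsda.choose_components(
            tr_sub, A_max=min(band_idx.size, 10), folds=folds, seed=seed
        )
        model = plsda.fit(tr_sub, A)
        _, labels = plsda.predict(model, te_sub.X)
        report = plsda.evaluate(te_sub.y, labels)
        rows.append(
            CascadeRow(
                stage="pooled" if thr is None else "stepwise",
                threshold=thr,
                bands_nm=step.wavelengths_nm,
                n_bands=band_idx.size,
                report=report,
            )
        )
    return results, rows


def cascade_table(rows: list[CascadeRow]) -> pd.DataFrame:
    """Reduced-band report table: bands, per-class recall, total accuracy."""
    recs = []
    for r in rows:
        rec = {
            "stage": r.stage,
            "threshold": 0.0 if r.threshold is None else r.threshold,
            "n_bands": r.n_bands,
            "bands_nm": " ".join(f"{w:.0f}" for w in r.bands_nm),
            "total_accuracy": r.report.total_accuracy,
        }
        for cls, name in ((0, "normal"), (1, "bloody"), (2, "yolk_destroyed")):
            rec[f"{name}_recall"] = r.report.per_class[cls]["recall"]
            rec[f"{name}_accuracy"] = r.report.per_class[cls]["accuracy"]
        recs.append(rec)
    return pd.DataFrame(recs)
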