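"""Spectral pretreatments applied after calibration and range restriction.

All transforms are pure per-spectrum functions except MSC, whose reference
spectrum is learned from the training set only and replayed on validation
rows (no leakage).  Savitzky-Golay derivatives are scaled by the grid
spacing so they are per-nm and axis-resolution independent; edges are
handled by fitting the polynomial on the truncated window rather than by
padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

METHODS = ("none", "mean_norm", "max_norm", "range_norm", "snv", "msc", "sg1", "sg2")

#: table-style display names used in reports
METHOD_LABELS = {
    "none": "Raw",
    "mean_norm": "Mean norm",
    "max_norm": "Max norm",
    "range_norm": "Range norm",
    "snv": "SNV",
    "msc": "MSC",
    "sg1": "SG 1st",
    "sg2": "SG 2nd",
}


def mean_norm(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m == 0:
        raise ValueError("mean normalization undefined: spectrum mean is 0")
    return x / m


def max_norm(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = x.max()
    if m == 0:
        raise ValueError("max normalization undefined: spectrum maximum is 0")
    return x / m


def range_norm(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("range normalization undefined: constant spectrum")
    return (x - lo) / (hi - lo)


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and scaling to unit
    sample standard deviation (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined: constant spectrum")
    return (x - x.mean()) / sd


def msc_fit(X_train: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the column mean of the training matrix."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 1:
        raise ValueError("msc_fit needs an n x p training matrix")
    return X_train.mean(axis=0)


def msc_apply(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Regress x on the reference (x ~ a + b*ref, OLS) and return (x-a)/b."""
    x = np.asarray(x, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if x.shape != reference.shape:
        raise ValueError("spectrum and MSC reference lengths differ")
    rc = reference - reference.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("MSC reference is constant")
    b = (rc @ (x - x.mean())) / denom
    if b <= 1e-12:
        raise ValueError("MSC slope <= 0: spectrum uncorrelated with reference")
    a = x.mean() - b * reference.mean()
    return (x - a) / b


def savitzky_golay(
    x: np.ndarray,
    axis: np.ndarray,
    deriv: int,
    window: int = 11,
    polyorder: int = 2,
) -> np.ndarray:
    """Savitzky-Golay derivative (per nm) on a uniform wavelength grid."""
    x = np.asarray(x, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if deriv not in (1, 2):
        raise ValueError("deriv must be 1 or 2")
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be an odd integer >= 5")
    if window > x.size:
        raise ValueError("window longer than the spectrum")
    if polyorder < deriv:
        raise ValueError("polyorder must be >= deriv")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    delta = float(np.mean(np.diff(axis)))
    return savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=delta, mode="interp",
    )


@dataclass
class PreprocessSpec:
    """A named pretreatment plus the state it learns from training data.

    Only MSC has fitted state (its reference spectrum).  ``fit`` must be
    called on the training set before ``apply``; for stateless methods
    ``fit`` is a no-op provided for a uniform interface.
    """

    method: str = "none"
    sg_window: int = 11
    sg_polyorder: int = 2
    fitted_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_window < 5:
            raise ValueError("sg_window must be an odd integer >= 5")
        if self.sg_polyorder < 2 or self.sg_polyorder >= self.sg_window:
            raise ValueError("need 2 <= sg_polyorder < sg_window")

    @property
    def label(self) -> str:
        return METHOD_LABELS[self.method]

    def fit(self, train: SpectraSet) -> "PreprocessSpec":
        if self.method == "msc":
            self.fitted_state = {"reference": msc_fit(train.X)}
        return self

    def _transform_matrix(self, X: np.ndarray, axis: np.ndarray) -> np.ndarray:
        if self.method == "none":
            return X.copy()
        if self.method == "msc":
            ref = self.fitted_state.get("reference")
            if ref is None:
                raise ValueError("MSC must be fitted on the training set first")
            return np.vstack([msc_apply(row, ref) for row in X])
        per_row = {
            "mean_norm": mean_norm,
            "max_norm": max_norm,
            "range_norm": range_norm,
            "snv": snv,
        }
        if self.method in per_row:
            f = per_row[self.method]
            return np.vstack([f(row) for row in X])
        deriv = 1 if self.method == "sg1" else 2
        return np.vstack(
            [
                savitzky_golay(row, axis, deriv, self.sg_window, self.sg_polyorder)
                for row in X
            ]
        )

    def apply(self, ds: SpectraSet) -> SpectraSet:
        out = ds.with_X(self._transform_matrix(ds.X, ds.axis))
        out.meta = out.meta.assign(preprocessing=self.method)
        return out

    def fit_transform(self, train: SpectraSet) -> SpectraSet:
        return self.fit(train).apply(train)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
        }
        if "reference" in self.fitted_state:
            d["msc_reference"] = list(self.fitted_state["reference"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        spec = cls(
            method=d.get("method", "none"),
            sg_window=d.get("sg_window", 11),
            sg_polyorder=d.get("sg_polyorder", 2),
        )
        if "msc_reference" in d:
            spec.fitted_state = {"reference": np.asarray(d["msc_reference"], float)}
        return spec


def default_grid() -> list[PreprocessSpec]:
    """The pretreatment set screened per model cell."""
    return [PreprocessSpec(method=m) for m in METHODS]
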