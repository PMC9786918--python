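"""In-memory containers for transmittance spectra and their CSV dialect.

A :class:`Spectrum` is a single scan (wavelength axis + value vector +
metadata); a :class:`SpectraSet` is a sample x wavelength matrix with an
aligned axis, integer class labels (0 = normal, 1 = bloody, 2 =
yolk-destroyed) and per-row metadata.  Datasets round-trip through a plain
CSV with header ``egg_id,class,lamp,condition,rotation,<wavelengths...>``,
one scan per row, wavelengths printed with two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["egg_id", "class", "lamp", "condition", "rotation"]

CLASS_NAMES = {0: "normal", 1: "bloody", 2: "yolk_destroyed"}


def _check_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size == 0:
        raise ValueError("wavelength axis must be a non-empty 1-D array")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise ValueError("wavelength axis must be strictly increasing")
    return axis


@dataclass
class Spectrum:
    """One scan: wavelengths (nm), values, and a free-form metadata record.

    ``meta['kind']`` distinguishes raw / white / dark / transmittance scans.
    Undefined transmittance points (where the white and dark references
    coincide) are carried as NaN.
    """

    axis: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.axis.shape:
            raise ValueError(
                f"values length {self.values.size} != axis length {self.axis.size}"
            )

    @property
    def kind(self) -> str:
        return self.meta.get("kind", "raw")


@dataclass
class SpectraSet:
    """Sample x wavelength matrix with aligned axis, labels and egg ids."""

    X: np.ndarray
    axis: np.ndarray
    y: np.ndarray
    egg_id: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.egg_id = np.asarray(self.egg_id)
        if self.X.ndim != 2 or self.X.shape[1] != self.axis.size:
            raise ValueError("X must be n x p with p == len(axis)")
        if self.y.shape != (self.X.shape[0],) or self.egg_id.shape != self.y.shape:
            raise ValueError("y and egg_id must have one entry per row of X")
        if not np.isin(self.y, [0, 1, 2]).all():
            raise ValueError("labels must be drawn from {0, 1, 2}")
        if self.meta is None:
            self.meta = pd.DataFrame(index=range(self.X.shape[0]))
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta must have one row per scan")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def take_rows(self, idx: np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            X=self.X[idx],
            axis=self.axis.copy(),
            y=self.y[idx],
            egg_id=self.egg_id[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def take_columns(self, cols: np.ndarray) -> "SpectraSet":
        cols = np.asarray(cols)
        return SpectraSet(
            X=self.X[:, cols],
            axis=self.axis[cols],
            y=self.y.copy(),
            egg_id=self.egg_id.copy(),
            meta=self.meta.reset_index(drop=True),
        )

    def with_X(self, X: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            X=np.asarray(X, dtype=float),
            axis=self.axis.copy(),
            y=self.y.copy(),
            egg_id=self.egg_id.copy(),
            meta=self.meta.reset_index(drop=True),
        )


@dataclass
class CalibrationReferences:
    """Averaged white (W) and dark (D) reference scans on a shared axis."""

    white: Spectrum
    dark: Spectrum
    n_scans_averaged: int = 1

    def __post_init__(self) -> None:
        if not np.array_equal(self.white.axis, self.dark.axis):
            raise ValueError("white and dark references must share the axis")
        if self.n_scans_averaged < 1:
            raise ValueError("n_scans_averaged must be >= 1")


# ---------------------------------------------------------------------------
# CSV dialect


def _axis_header(axis: np.ndarray) -> list[str]:
    return [f"{w:.2f}" for w in axis]


def write_dataset_csv(path, ds: SpectraSet) -> None:
    """Write one scan per row: egg_id,class,lamp,condition,rotation,<values>."""
    meta = ds.meta if ds.meta is not None else pd.DataFrame(index=range(ds.n))
    out = pd.DataFrame(
        {
            "egg_id": ds.egg_id,
            "class": ds.y,
            "lamp": meta.get("lamp", pd.Series(["?"] * ds.n)).to_numpy(),
            "condition": meta.get("condition", pd.Series([0] * ds.n)).to_numpy(),
            "rotation": meta.get("rotation", pd.Series([0] * ds.n)).to_numpy(),
        }
    )
    spec = pd.DataFrame(ds.X, columns=_axis_header(ds.axis))
    pd.concat([out, spec], axis=1).to_csv(path, index=False)


def read_dataset_csv(path) -> SpectraSet:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset CSV missing metadata columns: {missing}")
    wave_cols = [c for c in df.columns if c not in META_COLUMNS]
    axis = np.array([float(c) for c in wave_cols])
    return SpectraSet(
        X=df[wave_cols].to_numpy(dtype=float),
        axis=axis,
        y=df["class"].to_numpy(),
        egg_id=df["egg_id"].to_numpy(),
        meta=df[["lamp", "condition", "rotation"]].copy(),
    )


def write_references_csv(path, refs: CalibrationReferences) -> None:
    """Two labelled rows (white, dark) over the shared axis."""
    df = pd.DataFrame(
        [refs.white.values, refs.dark.values],
        columns=_axis_header(refs.white.axis),
    )
    df.insert(0, "kind", ["white", "dark"])
    df.to_csv(path, index=False)


def read_references_csv(path) -> CalibrationReferences:
    df = pd.read_csv(path)
    if "kind" not in df.columns or set(df["kind"]) != {"white", "dark"}:
        raise ValueError("references CSV must have rows labelled 'white' and 'dark'")
    wave_cols = [c for c in df.columns if c != "kind"]
    axis = np.array([float(c) for c in wave_cols])
    rows = {k: df.loc[df["kind"] == k, wave_cols].to_numpy(dtype=float)[0] for k in ("white", "dark")}
    return CalibrationReferences(
        white=Spectrum(axis, rows["white"], {"kind": "white"}),
        dark=Spectrum(axis, rows["dark"], {"kind": "dark"}),
    )
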