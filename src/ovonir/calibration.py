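"""Intensity calibration: raw counts -> relative transmittance.

T(lam) = (B - D) / (W - D) with averaged white (W) and dark (D) reference
scans.  Wavelengths where W - D is at the noise floor (outside the lamp
support) have no defined transmittance; they are flagged NaN and must be
dropped (``restrict_range``) before any modelling stage.
"""

from __future__ import annotations

import numpy as np

from .spectra import CalibrationReferences, SpectraSet, Spectrum


def average_scans(scans: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of repeated scans on a shared axis."""
    if not scans:
        raise ValueError("average_scans requires at least one scan")
    axis = scans[0].axis
    for s in scans[1:]:
        if not np.array_equal(s.axis, axis):
            raise ValueError("all scans must share the same wavelength axis")
    mean = np.mean([s.values for s in scans], axis=0)
    meta = dict(scans[0].meta)
    meta["n_averaged"] = len(scans)
    return Spectrum(axis=axis.copy(), values=mean, meta=meta)


#: relative denominator guard: wavelengths where W-D falls below this
#: fraction of its maximum carry no usable light and are flagged undefined.
#: The floor must sit above the reference-scan noise level, or the noise
#: floor outside the lamp support would calibrate to arbitrary ratios.
REL_EPS = 1e-2


def _denominator(
    refs: CalibrationReferences, rel_eps: float = REL_EPS
) -> tuple[np.ndarray, np.ndarray]:
    wd = refs.white.values - refs.dark.values
    eps = rel_eps * np.max(wd)
    defined = wd > eps
    if not defined.any():
        raise ValueError("white and dark references coincide everywhere")
    return wd, defined


def calibrate(b, refs: CalibrationReferences):
    """Eq.-style transmittance (B-D)/(W-D) for a Spectrum or a SpectraSet.

    Points where W-D <= 1e-9 * max(W-D) are undefined and returned as NaN.
    """
    wd, defined = _denominator(refs)
    if isinstance(b, Spectrum):
        if not np.array_equal(b.axis, refs.white.axis):
            raise ValueError("scan and references must share the wavelength axis")
        t = np.full(b.values.shape, np.nan)
        t[defined] = (b.values[defined] - refs.dark.values[defined]) / wd[defined]
        meta = dict(b.meta)
        meta["kind"] = "transmittance"
        return Spectrum(axis=b.axis.copy(), values=t, meta=meta)
    if isinstance(b, SpectraSet):
        if not np.array_equal(b.axis, refs.white.axis):
            raise ValueError("dataset and references must share the wavelength axis")
        t = np.full(b.X.shape, np.nan)
        t[:, defined] = (b.X[:, defined] - refs.dark.values[defined]) / wd[defined]
        out = b.with_X(t)
        out.meta = out.meta.assign(kind="transmittance")
        return out
    raise TypeError(f"cannot calibrate object of type {type(b).__name__}")


def restrict_range(s, lo_nm: float, hi_nm: float):
    """Keep grid points with lo <= lam <= hi, dropping NaN-flagged points.

    Order is preserved; no interpolation.  For a SpectraSet a column is
    dropped if it is undefined (NaN) in any row.
    """
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    if isinstance(s, Spectrum):
        keep = (s.axis >= lo_nm) & (s.axis <= hi_nm) & ~np.isnan(s.values)
        if not keep.any():
            raise ValueError(f"no defined wavelengths inside [{lo_nm}, {hi_nm}] nm")
        return Spectrum(axis=s.axis[keep], values=s.values[keep], meta=dict(s.meta))
    if isinstance(s, SpectraSet):
        keep = (s.axis >= lo_nm) & (s.axis <= hi_nm) & ~np.isnan(s.X).any(axis=0)
        if not keep.any():
            raise ValueError(f"no defined wavelengths inside [{lo_nm}, {hi_nm}] nm")
        return s.take_columns(np.flatnonzero(keep))
    raise TypeError(f"cannot restrict object of type {type(s).__name__}")
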