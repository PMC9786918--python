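"""Synthetic Vis/NIR egg-transmittance scans with white/dark references.

The generator emulates the phenomenology of transmission candling of brown
eggs on a 2068-point 192-1110 nm axis:

* a silver-coated halogen lamp emitting only in 400-700 nm with its peak in
  the blood-sensitive 565-585 nm window, and a gold-coated lamp emitting in
  500-1100 nm with a broad peak above 600 nm;
* a calcium-carbonate shell that blocks light below ~550 nm (logistic
  transmission factor);
* Beer-Lambert absorption with Gaussian bands for hemoglobin (415, 539,
  577 nm) and the shell pigment protoporphyrin IX (539, 589, 643 nm);
* bloody eggs: elevated hemoglobin plus a global intensity attenuation;
  yolk-destroyed eggs: a stronger global attenuation plus a distinct local
  absorption feature in the 590-600 nm region;
* per-scan multiplicative scatter, baseline drift, lamp-shaped stray light
  (fraction set by the measurement-geometry condition) and additive noise.

A raw scan is

    B(lam) = m * L(lam) * S(lam) * exp(-l*j * sum_i c_i * G_i(lam)) * a
             + baseline(lam) + s * L(lam) * S(lam)**g + d + eps(lam),

clipped at 0, with L the lamp envelope, S the shell sigmoid, G_i
unit-height Gaussian absorber bands, l the condition path-length scale and
j a per-scan path jitter, m a per-scan scatter draw, a <= 1 a class
attenuation, s a per-scan stray-light draw scaled by the condition's stray
fraction with a random shell-grazing exponent g, d the sensor dark offset,
and eps additive (partially spectrally correlated) noise.

All randomness flows from a single integer seed through spawned
``numpy.random.Generator`` streams; identical configs give bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .spectra import CalibrationReferences, SpectraSet, Spectrum

DEFAULT_AXIS_POINTS = 2068
DEFAULT_AXIS_SPAN = (192.0, 1110.0)

#: hemoglobin absorption band centers (nm) and relative strengths
HEMOGLOBIN_BANDS = ((415.0, 3.0), (539.0, 0.6), (577.0, 0.8))
#: protoporphyrin-IX band centers (nm) and relative strengths
PPIX_BANDS = ((539.0, 0.5), (589.0, 0.4), (643.0, 0.8))
#: extra absorption feature of yolk-destroyed eggs (membrane/yolk mixing)
YOLK_BAND = (596.0, 1.0)

#: measurement-geometry condition -> (path-length scale, stray-light fraction)
CONDITION_PARAMS = {1: (1.0, 0.10), 2: (1.2, 0.02), 3: (1.1, 0.05)}

SHELL_SIGMOID_CENTER_NM = 550.0
SHELL_SIGMOID_SCALE_NM = 12.0
TEFLON_FACTOR = 0.9
DARK_OFFSET = 0.02


def default_axis() -> np.ndarray:
    lo, hi = DEFAULT_AXIS_SPAN
    return np.linspace(lo, hi, DEFAULT_AXIS_POINTS)


@dataclass(frozen=True)
class LampProfile:
    """Smooth nonnegative emission envelope, zero outside its support."""

    name: str
    support_nm: tuple[float, float]
    envelope: np.ndarray
    axis: np.ndarray


def lamp_profile(name: str, axis: np.ndarray) -> LampProfile:
    """Emission envelope of a silver- or gold-coated halogen lamp.

    Silver emits in 400-700 nm peaking inside the blood-sensitive
    565-585 nm window; gold emits in 500-1100 nm with a broad peak above
    600 nm.  The envelope is a Gaussian peak multiplied by a cosine taper
    that reaches zero exactly at the support edges.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size == 0:
        raise ValueError("axis must be a non-empty 1-D array")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    if name == "silver":
        support = (400.0, 700.0)
        center, width = 575.0, 70.0
    elif name == "gold":
        support = (500.0, 1100.0)
        center, width = 800.0, 200.0
    else:
        raise ValueError(f"unknown lamp name: {name!r} (expected 'silver' or 'gold')")
    lo, hi = support
    peak = np.exp(-0.5 * ((axis - center) / width) ** 2)
    # cosine taper: 1 at the support center line, 0 at and beyond the edges
    taper = np.sin(np.pi * np.clip((axis - lo) / (hi - lo), 0.0, 1.0))
    env = np.where((axis >= lo) & (axis <= hi), peak * taper, 0.0)
    return LampProfile(name=name, support_nm=support, envelope=env, axis=axis)


@dataclass(frozen=True)
class ClassParams:
    """Latent concentrations and global attenuation for one egg class."""

    hemoglobin: float
    ppix: float
    yolk_feature: float
    attenuation: float


DEFAULT_CLASS_PARAMS = {
    0: ClassParams(hemoglobin=0.3, ppix=0.6, yolk_feature=0.0, attenuation=1.0),
    1: ClassParams(hemoglobin=1.4, ppix=0.6, yolk_feature=0.0, attenuation=0.95),
    2: ClassParams(hemoglobin=0.3, ppix=0.6, yolk_feature=0.45, attenuation=0.75),
}


@dataclass
class SimulationConfig:
    """Study-design knobs: axis, lamp, geometry condition, class structure, noise."""

    axis: np.ndarray = field(default_factory=default_axis)
    lamp: str = "silver"
    condition: int = 2
    n_eggs_per_class: int = 50
    rotations_per_egg: int = 5
    class_params: dict[int, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    band_width_nm: float = 4.5
    yolk_band_width_nm: float = 5.0
    noise_sd: float = 0.008
    scatter_sd: float = 0.12
    baseline_amplitude: float = 0.003
    egg_lognormal_sd: float = 0.25
    noise_correlation_nm: float = 1.5
    stray_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.condition not in CONDITION_PARAMS:
            raise ValueError(f"condition must be one of {sorted(CONDITION_PARAMS)}")
        if self.n_eggs_per_class < 1 or self.rotations_per_egg < 1:
            raise ValueError("counts must be >= 1")
        for name in (
            "noise_sd",
            "scatter_sd",
            "baseline_amplitude",
            "egg_lognormal_sd",
            "stray_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.band_width_nm <= 0 or self.yolk_band_width_nm <= 0:
            raise ValueError("band widths must be > 0")

    @property
    def path_length(self) -> float:
        return CONDITION_PARAMS[self.condition][0]

    @property
    def stray_fraction(self) -> float:
        return CONDITION_PARAMS[self.condition][1]


def _gauss(axis: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((axis - center) / sd) ** 2)


def shell_transmission(axis: np.ndarray) -> np.ndarray:
    """Logistic shell factor rising through ~550 nm (CaCO3 blocks below)."""
    return 1.0 / (1.0 + np.exp(-(axis - SHELL_SIGMOID_CENTER_NM) / SHELL_SIGMOID_SCALE_NM))


def absorbance_profile(
    cfg: SimulationConfig, concentrations: ClassParams
) -> np.ndarray:
    """Total Beer-Lambert exponent sum_i c_i * G_i on the config axis."""
    ax = cfg.axis
    total = np.zeros_like(ax)
    for center, strength in HEMOGLOBIN_BANDS:
        total += concentrations.hemoglobin * strength * _gauss(ax, center, cfg.band_width_nm)
    for center, strength in PPIX_BANDS:
        total += concentrations.ppix * strength * _gauss(ax, center, cfg.band_width_nm)
    center, strength = YOLK_BAND
    total += concentrations.yolk_feature * strength * _gauss(ax, center, cfg.yolk_band_width_nm)
    return total


def noiseless_scan(cfg: SimulationConfig, params: ClassParams) -> np.ndarray:
    """Deterministic part of a scan: m=1, no baseline, no stray, no noise."""
    lamp = lamp_profile(cfg.lamp, cfg.axis)
    signal = lamp.envelope * shell_transmission(cfg.axis)
    signal = signal * np.exp(-cfg.path_length * absorbance_profile(cfg, params))
    return signal * params.attenuation


def simulate_scan(
    cfg: SimulationConfig,
    egg_class: int,
    rng: np.random.Generator,
    params: ClassParams | None = None,
) -> Spectrum:
    """One raw scan for an egg of the given class.

    ``params`` carries the egg's latent concentrations; by default the
    class means from ``cfg.class_params`` are used.  Scatter, baseline,
    stray light and additive noise are drawn fresh from ``rng``.
    """
    if egg_class not in (0, 1, 2):
        raise ValueError("egg_class must be 0, 1 or 2")
    if params is None:
        params = cfg.class_params[egg_class]
    ax = cfg.axis
    lamp = lamp_profile(cfg.lamp, ax)

    m = float(np.exp(rng.normal(0.0, cfg.scatter_sd))) if cfg.scatter_sd > 0 else 1.0
    # geometric instability: the same sloppiness that admits stray light
    # also jitters the optical path through the egg from scan to scan,
    # modulating apparent band depths
    jitter_sd = cfg.stray_scale * cfg.stray_fraction
    path_jitter = float(np.exp(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 1.0
    mid = 0.5 * (ax[0] + ax[-1])
    span = max(ax[-1] - ax[0], 1.0)
    if cfg.baseline_amplitude > 0:
        b0, b1 = rng.normal(0.0, cfg.baseline_amplitude, size=2)
    else:
        b0, b1 = 0.0, 0.0
    baseline = b0 + b1 * (ax - mid) / span
    stray_amp = cfg.stray_scale * cfg.stray_fraction * rng.uniform(0.5, 1.5)
    # stray light grazes the shell to a scan-dependent degree, so its
    # spectral shape is the lamp envelope partially filtered by the shell
    # sigmoid — a structured nuisance that scatter corrections cannot
    # remove as a constant offset
    graze = rng.uniform(0.0, 1.0)
    stray_shape = lamp.envelope * shell_transmission(ax) ** graze
    eps = _additive_noise(cfg, rng)

    base = lamp.envelope * shell_transmission(ax) * np.exp(
        -cfg.path_length * path_jitter * absorbance_profile(cfg, params)
    ) * params.attenuation

    # DARK_OFFSET models the sensor's dark current, present in every
    # measurement (scans and white reference alike); the dark reference is
    # this offset alone, so calibration divides it out exactly.
    values = m * base + baseline + stray_amp * stray_shape + DARK_OFFSET + eps
    values = np.clip(values, 0.0, None)
    return Spectrum(
        axis=ax.copy(),
        values=values,
        meta={
            "kind": "raw",
            "class": egg_class,
            "lamp": cfg.lamp,
            "condition": cfg.condition,
        },
    )


def _additive_noise(cfg: SimulationConfig, rng: np.random.Generator):
    """Detector noise: equal-power white and spectrally smooth components.

    The smooth part (Gaussian-correlated over ~noise_correlation_nm) models
    readout drift and source flicker; it makes neighbouring wavelengths
    share their noise, as real diode-array detectors do.
    """
    if cfg.noise_sd <= 0:
        return 0.0
    ax = cfg.axis
    white = rng.normal(0.0, 1.0, size=ax.size)
    if cfg.noise_correlation_nm <= 0 or ax.size < 3:
        return cfg.noise_sd * white
    spacing = float(np.mean(np.diff(ax)))
    sigma_cols = cfg.noise_correlation_nm / spacing
    smooth = gaussian_filter1d(rng.normal(0.0, 1.0, size=ax.size), sigma_cols)
    sd = np.sqrt(1.0 / (2.0 * sigma_cols * np.sqrt(np.pi)))
    smooth = smooth / sd
    return cfg.noise_sd * (white + smooth) / np.sqrt(2.0)


def simulate_references(
    cfg: SimulationConfig, n_scans: int = 10, rng: np.random.Generator | None = None
) -> CalibrationReferences:
    """White (Teflon disk, no egg) and dark references, each averaged over
    ``n_scans`` draws."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ax = cfg.axis
    lamp = lamp_profile(cfg.lamp, ax)
    white_clean = lamp.envelope * TEFLON_FACTOR + DARK_OFFSET
    dark_clean = np.full(ax.size, DARK_OFFSET)
    if cfg.noise_sd > 0:
        white_draws = white_clean + rng.normal(0.0, cfg.noise_sd, size=(n_scans, ax.size))
        dark_draws = dark_clean + rng.normal(0.0, cfg.noise_sd, size=(n_scans, ax.size))
    else:
        white_draws = np.tile(white_clean, (n_scans, 1))
        dark_draws = np.tile(dark_clean, (n_scans, 1))
    white = Spectrum(ax.copy(), white_draws.mean(axis=0), {"kind": "white"})
    dark = Spectrum(ax.copy(), dark_draws.mean(axis=0), {"kind": "dark"})
    return CalibrationReferences(white=white, dark=dark, n_scans_averaged=n_scans)


def _draw_egg_params(
    cfg: SimulationConfig, egg_class: int, rng: np.random.Generator
) -> ClassParams:
    """Per-egg latent concentrations: log-normal around the class means."""
    mean = cfg.class_params[egg_class]
    sd = cfg.egg_lognormal_sd

    def ln(x: float) -> float:
        if x <= 0 or sd == 0:
            return x
        return float(x * np.exp(rng.normal(0.0, sd)))

    return ClassParams(
        hemoglobin=ln(mean.hemoglobin),
        ppix=ln(mean.ppix),
        yolk_feature=ln(mean.yolk_feature),
        attenuation=mean.attenuation,
    )


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[SpectraSet, CalibrationReferences]:
    """Full factor-cell dataset: n_eggs_per_class x 3 classes x rotations.

    Rotations of the same egg share its latent concentrations but redraw
    scatter, baseline, stray and noise.  Returns the raw scans and the
    averaged white/dark references for the cell.
    """
    root = np.random.SeedSequence(cfg.seed)
    ref_seq, scan_seq = root.spawn(2)
    refs = simulate_references(cfg, rng=np.random.default_rng(ref_seq))

    rows, labels, egg_ids, meta_rows = [], [], [], []
    egg_streams = scan_seq.spawn(3 * cfg.n_eggs_per_class)
    idx = 0
    for egg_class in (0, 1, 2):
        for e in range(cfg.n_eggs_per_class):
            rng = np.random.default_rng(egg_streams[idx])
            idx += 1
            params = _draw_egg_params(cfg, egg_class, rng)
            egg_id = f"{cfg.lamp}-c{cfg.condition}-{egg_class}-{e:03d}"
            for rot in range(cfg.rotations_per_egg):
                scan = simulate_scan(cfg, egg_class, rng, params=params)
                rows.append(scan.values)
                labels.append(egg_class)
                egg_ids.append(egg_id)
                meta_rows.append(
                    {"lamp": cfg.lamp, "condition": cfg.condition, "rotation": rot}
                )
    ds = SpectraSet(
        X=np.vstack(rows),
        axis=cfg.axis.copy(),
        y=np.array(labels),
        egg_id=np.array(egg_ids),
        meta=pd.DataFrame(meta_rows),
    )
    return ds, refs
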