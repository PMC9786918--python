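"""Shared fixtures: tiny synthetic datasets plus one session-scoped
default-size pipeline run (dataset -> calibration -> split -> full-band
model -> selection cascade) reused by the slower analysis-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from ovonir import calibration, plsda, selection, simulate

#: seed of the canonical default dataset exercised by the analysis-level tests
DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def default_dataset():
    """Default-size silver / condition-2 cell: 750 raw scans + references."""
    cfg = simulate.SimulationConfig(lamp="silver", condition=2, seed=DEFAULT_SEED)
    ds, refs = simulate.generate_dataset(cfg)
    return cfg, ds, refs


@pytest.fixture(scope="session")
def default_split(default_dataset):
    """Calibrated, 500-680 nm windowed, 70/30 stratified split."""
    _, ds, refs = default_dataset
    trans = calibration.calibrate(ds, refs)
    windowed = calibration.restrict_range(trans, 500.0, 680.0)
    return plsda.split_calibration_validation(windowed, frac=0.70, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_full_model(default_split):
    """Full-band PLS-DA model on the default split, A chosen by CV."""
    train, test = default_split
    A = plsda.choose_components(train, A_max=15, folds=5, seed=DEFAULT_SEED)
    model = plsda.fit(train, A)
    _, labels = plsda.predict(model, test.X)
    report = plsda.evaluate(test.y, labels)
    return model, report


@pytest.fixture(scope="session")
def default_cascade(default_split):
    """Selection cascade (WRC/SFS/SPA -> pooled -> stepwise) on the default
    split."""
    train, test = default_split
    return selection.cascade(train, test, seed=DEFAULT_SEED)


@pytest.fixture
def tiny_set():
    """Small balanced three-class set with one informative column."""
    rng = np.random.default_rng(7)
    n_per, p = 20, 6
    y = np.repeat([0, 1, 2], n_per)
    X = rng.normal(0.0, 1.0, size=(3 * n_per, p))
    X[:, 2] = y + rng.normal(0.0, 0.05, size=3 * n_per)
    from ovonir.spectra import SpectraSet

    return SpectraSet(
        X=X,
        axis=np.linspace(500.0, 600.0, p),
        y=y,
        egg_id=np.arange(3 * n_per).astype(str),
    )
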