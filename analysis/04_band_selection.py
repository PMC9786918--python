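#!/usr/bin/env python
"""Reduce the silver / condition-2 model from ~400 wavelengths to a
handful of bands: WRC, SFS and SPA inside the 550-600 nm window, pooling,
then forward stepwise pruning at p < 0.05 / 0.01 / 0.001 / 0.0001.

Writes the selector picks (results/04_selected_bands.csv) and the
stepwise pruning table (results/04_stepwise_bands.csv).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ovonir import calibration, plsda, selection, simulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cfg = simulate.SimulationConfig(lamp="silver", condition=2, seed=args.seed)
    ds, refs = simulate.generate_dataset(cfg)
    trans = calibration.restrict_range(calibration.calibrate(ds, refs), 500.0, 680.0)
    train, test = plsda.split_calibration_validation(trans, seed=args.seed)

    results, rows = selection.cascade(train, test, seed=args.seed)

    sel_rows = []
    for method in ("wrc", "sfs", "spa", "pooled"):
        r = results[method]
        print(f"{method.upper():6s} ({r.k} bands): "
              + ", ".join(f"{w:.0f}" for w in r.wavelengths_nm))
        for w, i in zip(r.wavelengths_nm, r.indices):
            sel_rows.append(
                {"selector": method, "wavelength_nm": round(float(w), 2), "index": int(i)}
            )
    out_dir = ROOT / "results"
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sel_rows).to_csv(out_dir / "04_selected_bands.csv", index=False)

    step_rows = []
    for r in rows:
        thr = 0.0 if r.threshold is None else r.threshold
        step_rows.append(
            {
                "threshold": thr,
                "n_bands": r.n_bands,
                "bands_nm": " ".join(f"{w:.0f}" for w in r.bands_nm),
            }
        )
    pd.DataFrame(step_rows).to_csv(out_dir / "04_stepwise_bands.csv", index=False)

    for method in ("wrc", "sfs", "spa"):
        d = float(np.min(np.abs(results[method].wavelengths_nm - 577.0)))
        print(f"{method.upper()} nearest band to the 577 nm hemoglobin line: "
              f"{d:.1f} nm away")
    print(f"\nStepwise pruning: "
          + " -> ".join(f"{r['n_bands']} bands @ p<{r['threshold']}"
                        for r in step_rows)
          + f"\nTables: {out_dir / '04_selected_bands.csv'}, "
          f"{out_dir / '04_stepwise_bands.csv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
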