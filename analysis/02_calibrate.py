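#!/usr/bin/env python
"""Convert raw counts to relative transmittance, (B-D)/(W-D), and restrict
to the 500-680 nm working window.

Writes per-cell class-mean transmittance at the diagnostic wavelengths
(hemoglobin 577 nm, PPIX 589/643 nm, yolk-feature 596 nm) to
results/02_transmittance_summary.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ovonir import calibration, simulate

ROOT = Path(__file__).resolve().parents[1]
DIAGNOSTIC_NM = (539.0, 577.0, 589.0, 596.0, 643.0)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    rows = []
    for lamp in ("silver", "gold"):
        for condition in (1, 2, 3):
            cfg = simulate.SimulationConfig(
                lamp=lamp, condition=condition, seed=args.seed
            )
            ds, refs = simulate.generate_dataset(cfg)
            trans = calibration.restrict_range(
                calibration.calibrate(ds, refs), 500.0, 680.0
            )
            for nm in DIAGNOSTIC_NM:
                j = int(np.argmin(np.abs(trans.axis - nm)))
                row = {"lamp": lamp, "condition": condition, "wavelength_nm": nm}
                for cls, name in ((0, "normal"), (1, "bloody"), (2, "yolk")):
                    row[f"T_{name}"] = trans.X[trans.y == cls, j].mean()
                rows.append(row)
            print(
                f"{lamp} c{condition}: {trans.p} defined wavelengths in "
                f"[{trans.axis[0]:.0f}, {trans.axis[-1]:.0f}] nm"
            )

    table = pd.DataFrame(rows).round(4)
    out = ROOT / "results" / "02_transmittance_summary.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False)
    sub = table[(table.lamp == "silver") & (table.condition == 2)]
    t577 = sub[sub.wavelength_nm == 577.0].iloc[0]
    print(
        f"\nSilver/condition-2 at 577 nm: normal T={t577.T_normal:.3f}, "
        f"bloody T={t577.T_bloody:.3f}, yolk-destroyed T={t577.T_yolk:.3f} "
        f"- the hemoglobin dip separates bloody eggs. Table: {out}"
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
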