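#!/usr/bin/env python
"""Screen the full experimental grid (2 lamps x 3 conditions x 8
pretreatments) with full-band PLS-DA models on the 500-680 nm window.

Writes the per-model calibration/validation accuracy table
(results/03_full_band_models.csv, one row per lamp x condition x
pretreatment) and reports the winning cell.
"""

import argparse
from pathlib import Path

import pandas as pd

from ovonir.pipeline import RunConfig, fit_cell_models, prepare_cell

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    config = RunConfig(seed=args.seed)
    tables = []
    for lamp in config.lamps:
        for condition in config.conditions:
            train, test = prepare_cell(config, lamp, condition)
            table = fit_cell_models(config, train, test, lamp, condition)
            tables.append(table)
            best = table.sort_values("val_total", ascending=False).iloc[0]
            print(
                f"{lamp} c{condition}: best {best.preprocessing} "
                f"(A={best.A}) validation {best.val_total:.1f}%"
            )
    full = pd.concat(tables, ignore_index=True).round(2)
    out = ROOT / "results" / "03_full_band_models.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    full.to_csv(out, index=False)

    winner = full.sort_values("val_total", ascending=False).iloc[0]
    by_cond = full.groupby("condition")["val_total"].max()
    print(
        f"\nBest cell: {winner.lamp} condition {int(winner.condition)} with "
        f"{winner.preprocessing} ({winner.val_total:.1f}% validation). "
        f"Per-condition best accuracy: "
        + ", ".join(f"c{c}={v:.1f}%" for c, v in by_cond.items())
        + f". Table: {out}"
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
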