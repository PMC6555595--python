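#!/usr/bin/env python
"""Asymmetric-index analysis of the simulated cohort.

Computes the ASI of every perimeter profile written by 01_simulate_inputs.py,
classifies cells at the 0.35 threshold, compares each ASI with the
generator's ground truth, and writes per-cell results and a cohort summary
under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from parcortex.asymmetry import PerimeterProfile, asi, asi_cohort_summary
from parcortex.io import read_table, write_json, write_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = read_table(ROOT / "data" / "asi_profiles.csv", "perimeter_profile")
    truths = json.loads((ROOT / "data" / "asi_profiles_truth.json").read_text())

    rows = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("sample_index")
        res = asi(PerimeterProfile(grp["intensity"].to_numpy(),
                                   cell_id=str(cell_id)))
        rows.append({
            "cell_id": cell_id,
            "asi": res.asi,
            "polarized": res.polarized,
            "true_asi": truths[str(cell_id)]["true_asi"],
        })
    out = pd.DataFrame(rows)
    out["abs_error"] = (out["asi"] - out["true_asi"]).abs()
    write_table(out, ROOT / "asi_per_cell.csv")

    summary = asi_cohort_summary(out["asi"])
    write_json(
        {"n": summary.n, "mean": summary.mean, "sd": summary.sd,
         "fraction_polarized": summary.fraction_polarized,
         "max_abs_error_vs_truth": float(out["abs_error"].max())},
        ROOT / "asi_summary.json",
    )
    print(f"ASI over {summary.n} cells: mean {summary.mean:.3f} "
          f"± {summary.sd:.3f} (s.d.), {100*summary.fraction_polarized:.0f}% "
          f"polarized (ASI > 0.35)")
    print(f"max |ASI - truth| = {out['abs_error'].max():.4f} "
          "(noise-limited; the statistic itself is exact)")


if __name__ == "__main__":
    main()
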