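#!/usr/bin/env python
"""Generate the synthetic measurement bundle every later analysis consumes.

Writes, under results/data/: perimeter intensity profiles for an ASI cohort,
circular membrane traces with island spans, 754 comb-distributed contour
lengths, Gaussian cross-section profiles, and a 40-cell fan cohort — each
with its JSON ground-truth sidecar.  Run with an optional seed argument
(default 0).
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from parcortex.io import write_json, write_table
from parcortex.synthetic import (make_comb_lengths, make_cross_profile,
                                 make_fan_cohort, make_perimeter_profile)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    rng = np.random.default_rng(SEED)
    OUT.mkdir(parents=True, exist_ok=True)

    # ASI cohort: 50 cells, crescent fractions 0.15-0.6, 5x contrast range
    rows, truths = [], {}
    for i in range(50):
        prof, truth = make_perimeter_profile(
            400, float(rng.uniform(0.15, 0.6)), float(rng.uniform(2, 8)),
            1.0, 0.1, seed=int(rng.integers(2**31)),
        )
        cid = f"cell{i:03d}"
        rows.append(pd.DataFrame({
            "cell_id": cid,
            "sample_index": np.arange(prof.n_samples),
            "intensity": prof.intensities,
        }))
        truths[cid] = truth.params
    write_table(pd.concat(rows), OUT / "asi_profiles.csv")
    write_json(truths, OUT / "asi_profiles_truth.json")

    lengths, comb_truth = make_comb_lengths(
        754, 0.38, 0.06 * 0.38, k=7, seed=int(rng.integers(2**31))
    )
    write_table(
        pd.DataFrame({"trace_id": [f"t{i:04d}" for i in range(754)],
                      "length_um": lengths}),
        OUT / "contour_lengths.csv",
    )
    write_json(comb_truth.params, OUT / "contour_lengths_truth.json")

    x, y, cross_truth = make_cross_profile(0.23, 1.0, 0.2, 0.02, 0.05,
                                           seed=int(rng.integers(2**31)))
    write_table(
        pd.DataFrame({"segment_id": "seg000", "position_um": x, "intensity": y}),
        OUT / "cross_profiles.csv",
    )
    write_json(cross_truth.params, OUT / "cross_profiles_truth.json")

    cells, fan_truth = make_fan_cohort(40, (60, 120), 0.8,
                                       seed=int(rng.integers(2**31)))
    write_table(
        pd.DataFrame(
            [(f"cell{i:03d}", *c["center"], *c["edge_a"], *c["edge_b"],
              *c["centrosome"]) for i, c in enumerate(cells)],
            columns=["cell_id", "cx_um", "cy_um", "eax_um", "eay_um",
                     "ebx_um", "eby_um", "sx_um", "sy_um"],
        ),
        OUT / "fan_cohort.csv",
    )
    write_json(fan_truth.params, OUT / "fan_cohort_truth.json")

    print(f"synthetic bundle (seed {SEED}) -> {OUT}")
    print("  50-cell ASI cohort, 754 contour lengths (0.38 um comb),")
    print("  noisy 0.23 um cross-section, 40-cell fan cohort (80% inside)")


if __name__ == "__main__":
    main()
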