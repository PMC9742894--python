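#!/usr/bin/env python
"""Fit the association protocol: inclusion filter, Cox models, FDR control.

Applies the cohort inclusion criteria (AHI ≥ 5, predominantly obstructive,
outcome observed, no event before the 2-year landmark), standardizes each
feature to z-scores, fits one covariate-adjusted Cox proportional-hazards
model per feature (age, BMI, race, smoking, sex; sex dropped in stratified
models) in the full sample and in men/women separately, and applies
Benjamini–Hochberg FDR at 0.05 within each analysis family. AHI is fit
through the identical path for comparison but kept out of the FDR families.

Reads results/features.csv + results/cohort/participants.csv; writes
results/associations.csv and prints the forest-style table.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from oxipheno.association import apply_inclusion, encode_covariates, run_association
from oxipheno.features import FEATURE_NAMES, read_feature_matrix, zscore_matrix
from oxipheno.pipeline import format_forest_text, render_forest_table

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "associations.csv"


def main():
    fdf = read_feature_matrix(ROOT / "results" / "features.csv")
    participants = pd.read_csv(ROOT / "scratch" / "cohort" / "participants.csv").set_index("id")

    included, tally = apply_inclusion(participants, landmark_y=2.0)
    included = encode_covariates(included)
    print("inclusion tally:", json.dumps(tally))

    analysed = fdf.loc[fdf.index.intersection(included.index)]
    z, scaling = zscore_matrix(analysed, drop_degenerate=True)
    dropped = sorted(set(FEATURE_NAMES) - set(z.columns))
    if dropped:
        print(f"dropped zero-variance features: {', '.join(dropped)}")

    assoc = run_association(
        z[[c for c in z.columns if c in FEATURE_NAMES or c == "AHI"]],
        included,
    )
    assoc = render_forest_table(assoc)
    assoc.to_csv(OUT, index=False, float_format="%.17g")
    print(f"wrote {len(assoc)} model rows -> {OUT}\n")
    print(format_forest_text(assoc[assoc["stratum"] == "all"]))

    sig = assoc[assoc["significant"]]
    if len(sig):
        print(f"\nBH-significant at FDR 0.05: "
              + ", ".join(f"{r.feature} ({r.stratum}, HR {r.hr:.2f})"
                          for r in sig.itertuples()))
    else:
        print("\nno pattern significant at FDR 0.05")


if __name__ == "__main__":
    sys.exit(main())
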