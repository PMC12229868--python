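#!/usr/bin/env python
"""Differential abundance: one hierarchical linear mixed model over all
retained proteins (protein, group, protein x group, age, sex, BMI fixed;
person random), then per-protein fold changes with nominal Wald 95% CIs —
no multiplicity correction.  Compares estimates against the simulation
truth and writes results/de/differential_expression.tsv."""

import argparse
from pathlib import Path

import pandas as pd

from synovnet.de import (classify_de, extract_group_contrasts,
                         fit_hierarchical_model, format_fold_change)
from synovnet.npx_io import read_samples
from synovnet.simulate import TruthRecord

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--qc", type=Path, default=Path("results/qc"))
parser.add_argument("--out", type=Path, default=Path("results/de"))
args = parser.parse_args()

retained = pd.read_csv(args.qc / "npx_selected.csv")
samples = read_samples(args.data / "samples.csv")
truth = TruthRecord.from_json(args.data / "truth.json")

model = fit_hierarchical_model(
    retained[["person_id", "assay_id", "npx"]], samples)
results = extract_group_contrasts(model)
args.out.mkdir(parents=True, exist_ok=True)
results.to_csv(args.out / "differential_expression.tsv", sep="\t",
               index=False, float_format="%.10g")

up, down, high = classify_de(results)
print(f"proteins analysed: {len(results)}")
print(f"variance components: person {model.person_variance:.3f}, "
      f"residual {model.residual_variance:.3f}")
print(f"up-regulated in OA: {len(up)}; down-regulated: {len(down)}; "
      f"|FC| >= 1.5 among these: {len(high)}")

merged = results.set_index("protein").join(
    pd.Series(truth.true_log2_effects, name="truth"))
err = (merged["delta_log2"] - merged["truth"]).abs()
cover = ((merged["ci_low"] <= merged["truth"])
         & (merged["truth"] <= merged["ci_high"])).mean()
print(f"vs truth: mean |error| {err.mean():.3f} log2 units, "
      f"CI coverage {100 * cover:.1f}%")

print("largest increases in OA:")
for _, row in results.nlargest(3, "fold_change").iterrows():
    print(f"  {row['protein']}: FC {format_fold_change(row)}")
print("largest decreases in OA:")
for _, row in results.nsmallest(3, "fold_change").iterrows():
    print(f"  {row['protein']}: FC {format_fold_change(row)}")
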