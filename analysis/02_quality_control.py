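#!/usr/bin/env python
"""Pre-analysis QC: per-assay dilution selection (closest to the middle of
the dynamic range), dilution-linearity exclusion, and the below-LOD rule
(exclude an assay when more than two samples of a group sit below the LOD;
remaining below-LOD cells become missing).  Writes the QC report and the
retained one-row-per-sample-x-assay table to results/qc/."""

import argparse
from pathlib import Path

from synovnet.npx_io import read_npx_long, read_samples, run_qc

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/qc"))
args = parser.parse_args()

table = read_npx_long(args.data / "npx.csv")
samples = read_samples(args.data / "samples.csv")
retained, report = run_qc(table, samples)

args.out.mkdir(parents=True, exist_ok=True)
report.to_json(args.out / "qc_report.json")
retained.to_csv(args.out / "npx_selected.csv", index=False)

print(f"assays in: {table['assay_id'].nunique()}")
for assay, reason in sorted(report.excluded.items()):
    score = report.linearity_scores.get(assay)
    extra = f" (linearity score {score:.2f})" if reason == "nonlinearity" else ""
    print(f"  excluded {assay}: {reason}{extra}")
print(f"assays retained: {len(report.retained)}")
dils = sorted({report.chosen_dilution[a] for a in report.retained})
print(f"chosen dilutions among retained assays: {dils}")
print(f"below-LOD cells set to missing: {report.n_cells_masked}")
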