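#!/usr/bin/env python
"""Conditional-dependence networks: fused joint graphical lasso over the
planted 20-protein network subset plus 30 filler proteins, tuning
(lambda1, lambda2) on a grid scored by AIC and BIC, with three models of
increasing complexity marked.  Compares the BIC model's group-distinct
edges and clusters against the simulation truth.  Writes the selection
table, precision matrices and clusters to results/network/."""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from synovnet.jgl import (differential_clusters, group_covariances,
                          model_selection)
from synovnet.npx_io import read_samples, standardize, to_matrix
from synovnet.simulate import TruthRecord

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--qc", type=Path, default=Path("results/qc"))
parser.add_argument("--out", type=Path, default=Path("results/network"))
args = parser.parse_args()

retained = pd.read_csv(args.qc / "npx_selected.csv")
samples = read_samples(args.data / "samples.csv")
truth = TruthRecord.from_json(args.data / "truth.json")
zmatrix = standardize(to_matrix(retained))
groups = samples.set_index("person_id")["group"].loc[zmatrix.index].to_numpy()

# the planted network subset plus filler proteins, as a study of what the
# solver can recover at this sample size
filler = [c for c in zmatrix.columns if c not in truth.network_proteins][:30]
subset = sorted(set(truth.network_proteins) | set(filler))
S_list, n_list, names = group_covariances(zmatrix[subset], groups)

table, fits = model_selection(
    S_list, n_list, lambda1_grid=[4.0, 8.0, 12.0, 16.0],
    lambda2_grid=[0.0, 0.5, 1.0])
args.out.mkdir(parents=True, exist_ok=True)
out_table = table.copy()
out_table["edges_per_group"] = out_table["edges_per_group"].astype(str)
out_table.to_csv(args.out / "model_selection.tsv", sep="\t", index=False,
                 float_format="%.10g")

print("model-selection grid (marked rows = the three models kept):")
print(out_table.to_string(index=False))

best = fits["bic"]
for k, label in enumerate(("control", "OA")):
    pd.DataFrame(best.theta[k], index=names, columns=names).to_csv(
        args.out / f"precision_{label}.tsv", sep="\t", float_format="%.6g")
clusters = differential_clusters(best, names)
(args.out / "differential_clusters.json").write_text(
    json.dumps(clusters, indent=2, sort_keys=True))

truth_diff = {frozenset((a, b)) for a, b, _ in truth.differential_edges}
print()
for label in ("bic", "aic", "dense"):
    est = fits[label]
    found_diff = set()
    for k in range(2):
        other = est.adjacency[1 - k]
        ii, jj = np.nonzero(np.triu(est.adjacency[k] & ~other, 1))
        found_diff |= {frozenset((names[i], names[j])) for i, j in zip(ii, jj)}
    hit = len(found_diff & truth_diff)
    print(f"{label} model: {est.edge_count(0)} control / "
          f"{est.edge_count(1)} OA edges, {est.shared_edge_count()} shared; "
          f"group-distinct edges {len(found_diff)}, planted differential "
          f"recovered {hit}/{len(truth_diff)}")
cl = differential_clusters(fits["bic"], names)
print(f"BIC-model clusters: control {len(cl['control'])}, OA {len(cl['OA'])}")
print("note: at this cohort size (13+11) the per-edge likelihood gain of the "
      "planted partial correlations (~0.3) is below the AIC/BIC penalty, so "
      "information criteria prefer very sparse or empty graphs — the "
      "conditional-dependence analysis is hypothesis-generating only.")
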