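#!/usr/bin/env python
"""Differential co-expression: all-pairs interaction regressions on the
pooled-standardized matrix, then (a) the enrichment protein sets (pairs
whose slope difference is >= 1 with CI excluding 0, split by the dominant
group) and (b) the signed network edges (additionally requiring the
group's own slope >= 1 in magnitude with CI excluding 0).  Writes the pair
models, edge lists and GraphML to results/coexpression/."""

import argparse
from pathlib import Path

import pandas as pd

from synovnet.coexpression import (EdgeSelectionRule, all_pairs,
                                   select_enrichment_proteins,
                                   select_network_edges)
from synovnet.npx_io import read_samples, standardize, to_matrix
from synovnet.pipeline import edges_to_graphml

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--qc", type=Path, default=Path("results/qc"))
parser.add_argument("--out", type=Path, default=Path("results/coexpression"))
args = parser.parse_args()

retained = pd.read_csv(args.qc / "npx_selected.csv")
samples = read_samples(args.data / "samples.csv")
zmatrix = standardize(to_matrix(retained))
groups = samples.set_index("person_id")["group"].loc[zmatrix.index].to_numpy()

pairs = all_pairs(zmatrix, groups)
args.out.mkdir(parents=True, exist_ok=True)
pairs.to_csv(args.out / "pair_models.tsv", sep="\t", index=False,
             float_format="%.10g")

ctrl_set, case_set, qual = select_enrichment_proteins(pairs)
pd.Series(sorted(ctrl_set)).to_csv(args.out / "proteins_control_dominant.txt",
                                   index=False, header=False)
pd.Series(sorted(case_set)).to_csv(args.out / "proteins_case_dominant.txt",
                                   index=False, header=False)
edges = select_network_edges(pairs, EdgeSelectionRule())
edges.to_csv(args.out / "network_edges.csv", index=False, float_format="%.10g")
edges_to_graphml(edges, args.out / "networks.graphml")

print(f"ordered pair models: {len(pairs)} "
      f"({int(pairs['estimable'].sum())} estimable)")
print(f"qualifying unordered pairs (|slope diff| >= 1, CI excl. 0): {len(qual)}")
print(f"enrichment sets: {len(ctrl_set)} control-dominant, "
      f"{len(case_set)} OA-dominant proteins")
for grp in ("control", "OA"):
    sub = edges[edges["group"] == grp]
    pos = (sub["sign"] == "positive").sum()
    print(f"{grp} network: {len(sub)} edges ({pos} positive, "
          f"{len(sub) - pos} negative)")
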