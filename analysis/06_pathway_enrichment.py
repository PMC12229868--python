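#!/usr/bin/env python
"""Pathway over-representation with the detected-panel background: three
hypergeometric analyses sharing one background — (A) differentially
expressed proteins, (B) control-dominant co-expression proteins, (C)
OA-dominant co-expression proteins.  Pathways with at least five
background members are reported as q, m, p, ratio rows, sorted by ratio.
Writes results/enrichment/enrichment.tsv."""

import argparse
from pathlib import Path

import pandas as pd

from synovnet.de import classify_de
from synovnet.enrichment import read_gmt, run_three_analyses, write_enrichment_tsv
from synovnet.npx_io import QCReport  # noqa: F401  (schema reference)

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--qc", type=Path, default=Path("results/qc"))
parser.add_argument("--de", type=Path, default=Path("results/de"))
parser.add_argument("--coex", type=Path, default=Path("results/coexpression"))
parser.add_argument("--out", type=Path, default=Path("results/enrichment"))
args = parser.parse_args()

de_results = pd.read_csv(args.de / "differential_expression.tsv", sep="\t")
up, down, _ = classify_de(de_results)
de_set = set(up) | set(down)
background = set(de_results["protein"])


def _read_list(path):
    text = Path(path).read_text().split()
    return set(text)


ctrl_set = _read_list(args.coex / "proteins_control_dominant.txt")
case_set = _read_list(args.coex / "proteins_case_dominant.txt")
pathways = read_gmt(args.data / "pathways.gmt")

tables = run_three_analyses(de_set, ctrl_set, case_set, background, pathways)
args.out.mkdir(parents=True, exist_ok=True)
write_enrichment_tsv(tables, args.out / "enrichment.tsv")

print(f"background: {len(background)} detected proteins; "
      f"{len(pathways)} annotated pathways")
for label, query, name in (("A", de_set, "differentially expressed"),
                           ("B", ctrl_set, "control-dominant co-expression"),
                           ("C", case_set, "OA-dominant co-expression")):
    t = tables[label]
    print(f"analysis {label} ({name}): query {len(query)}, "
          f"{len(t)} pathways with m >= 5")
    for _, row in t.head(3).iterrows():
        print(f"    {row['Pathway_name']} ({row['TopReactomeName']}): "
              f"q={row['q']} m={row['m']} p={row['p']:.2f} "
              f"ratio={row['Ratio']:.2f}")
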