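"""Hypergeometric over-representation analysis with a panel background.

Pathway membership comes from a GMT-style file (one pathway per line:
name, top-level category, tab-separated member symbols).  The background
is the set of proteins actually detected on the panels — not the whole
genome — which is what makes the enrichment well calibrated for targeted
panel data.  For each pathway with at least ``min_m`` background members,
the reported row carries q (query hits), m (background members),
ratio = q/m, the upper-tail hypergeometric p-value P(X >= q), and the hit
symbols.  Raw p-values are reported without multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "PathwayAnnotation",
    "GMTParseError",
    "read_gmt",
    "enrich",
    "run_three_analyses",
    "write_enrichment_tsv",
]

ENRICHMENT_COLUMNS = [
    "Pathway_name", "TopReactomeName", "q", "m", "p", "Ratio", "Proteins",
]


class GMTParseError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayAnnotation:
    name: str
    category: str
    members: frozenset[str]  # uppercased symbols

    def __post_init__(self):
        if not self.members:
            raise GMTParseError(f"pathway {self.name!r} has no members")


def read_gmt(path) -> list[PathwayAnnotation]:
    """Parse a GMT file: name TAB category TAB member [TAB member ...]."""
    annotations = []
    seen = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"line {lineno}: expected at least 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, category, *members = fields
            if name in seen:
                raise GMTParseError(f"line {lineno}: duplicate pathway {name!r}")
            seen.add(name)
            members = frozenset(m.strip().upper() for m in members if m.strip())
            if not members:
                raise GMTParseError(f"line {lineno}: pathway {name!r} has no members")
            annotations.append(PathwayAnnotation(name, category, members))
    return annotations


def enrich(
    query,
    background,
    pathways: list[PathwayAnnotation],
    min_m: int = 5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within ``background``.

    Matching is by uppercased symbol.  Query proteins outside the background
    are dropped (with the intersection used for the test).  Rows are sorted
    by ratio descending, then p ascending — the ratio-dominant presentation
    of the emulated report.
    """
    background = {str(s).upper() for s in background}
    if not background:
        raise ValueError("background set is empty")
    query = {str(s).upper() for s in query} & background
    n_bg, n_q = len(background), len(query)
    rows = []
    for pw in pathways:
        members_bg = pw.members & background
        m = len(members_bg)
        if m < min_m:
            continue
        hits = sorted(members_bg & query)
        q = len(hits)
        p = float(hypergeom.sf(q - 1, n_bg, m, n_q))
        rows.append(
            {
                "Pathway_name": pw.name,
                "TopReactomeName": pw.category,
                "q": q,
                "m": m,
                "p": min(p, 1.0),
                "Ratio": q / m,
                "Proteins": "|".join(hits),
            }
        )
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if not out.empty:
        out = out.sort_values(
            ["Ratio", "p", "Pathway_name"], ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
    return out


def run_three_analyses(
    de_proteins,
    coex_control_set,
    coex_case_set,
    background,
    pathways: list[PathwayAnnotation],
    min_m: int = 5,
) -> dict[str, pd.DataFrame]:
    """The three enrichment analyses sharing one panel background:

    A — differentially expressed proteins;
    B — proteins with stronger co-expression in the control group;
    C — proteins with stronger co-expression in the case (OA) group.
    """
    return {
        "A": enrich(de_proteins, background, pathways, min_m=min_m),
        "B": enrich(coex_control_set, background, pathways, min_m=min_m),
        "C": enrich(coex_case_set, background, pathways, min_m=min_m),
    }


def write_enrichment_tsv(tables: dict[str, pd.DataFrame], path) -> None:
    """Stacked A/B/C table as TSV with decimal points."""
    parts = []
    for label in sorted(tables):
        t = tables[label].copy()
        t.insert(0, "Analysis", label)
        parts.append(t)
    stacked = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    stacked.to_csv(path, sep="\t", index=False, float_format="%.6g")
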