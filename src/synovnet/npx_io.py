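"""Reading, validation and quality control of long-format NPX data.

NPX (Normalized Protein eXpression) values are log2-scale relative
abundances from proximity extension assay panels.  Each assay carries a
limit of detection (LOD) and an upper limit of quantification (ULOQ) that
bound its dynamic range, and may have been run at several sample dilutions.
This module implements the pre-analysis QC applied before any modelling:

* pick, per assay, the dilution whose values sit closest to the middle of
  the dynamic range;
* score dilution linearity (the NPX shift between dilutions of a
  well-behaved assay equals log2 of the dilution ratio) and exclude assays
  that deviate badly;
* exclude assays with more than ``max_below`` below-LOD samples in either
  group, and mark remaining below-LOD cells as missing;
* standardize the sample x protein matrix (pooled over groups) for the
  co-expression analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NPX_COLUMNS",
    "SAMPLE_COLUMNS",
    "NPXValidationError",
    "QCReport",
    "read_npx_long",
    "read_samples",
    "select_dilution",
    "select_dilutions",
    "dilution_linearity_score",
    "filter_lod",
    "standardize",
    "to_matrix",
    "run_qc",
]

NPX_COLUMNS = [
    "sample_id", "person_id", "assay_id", "panel",
    "dilution", "npx", "lod", "uloq", "qc_pass",
]
SAMPLE_COLUMNS = ["person_id", "group", "age", "sex", "bmi"]
GROUPS = ("control", "OA")


class NPXValidationError(ValueError):
    pass


@dataclass
class QCReport:
    """Per-assay QC outcome: every input assay is either retained (with a
    chosen dilution) or excluded with a reason in {nonlinearity, below_lod,
    no_in_range}."""

    chosen_dilution: dict[str, float] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)
    below_lod_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    linearity_scores: dict[str, float | None] = field(default_factory=dict)
    n_cells_masked: int = 0

    @property
    def retained(self) -> list[str]:
        return sorted(set(self.chosen_dilution) - set(self.excluded))

    def assert_partition(self, input_assays) -> None:
        got = set(self.retained) | set(self.excluded)
        if got != set(input_assays):
            raise AssertionError(
                f"QC report does not partition the assay set: "
                f"missing {set(input_assays) - got}, extra {got - set(input_assays)}"
            )

    def to_json(self, path) -> None:
        payload = {
            "chosen_dilution": self.chosen_dilution,
            "excluded": self.excluded,
            "below_lod_counts": self.below_lod_counts,
            "linearity_scores": self.linearity_scores,
            "n_cells_masked": self.n_cells_masked,
            "retained": self.retained,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_npx_long(path) -> pd.DataFrame:
    """Read and validate the long-format NPX CSV (one row per
    sample x assay x dilution)."""
    table = pd.read_csv(path)
    missing = [c for c in NPX_COLUMNS if c not in table.columns]
    if missing:
        raise NPXValidationError(f"NPX table is missing required columns: {missing}")
    return validate_npx(table)


def validate_npx(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    dup = table.duplicated(subset=["sample_id", "assay_id", "dilution"], keep=False)
    if dup.any():
        keys = (
            table.loc[dup, ["sample_id", "assay_id", "dilution"]]
            .drop_duplicates().head(5).to_records(index=False).tolist()
        )
        raise NPXValidationError(
            f"duplicate (sample_id, assay_id, dilution) keys, e.g. {keys}"
        )
    bad = table["lod"] >= table["uloq"]
    if bad.any():
        rows = table.index[bad][:5].tolist()
        raise NPXValidationError(f"lod >= uloq in rows {rows}")
    if (table["dilution"] <= 0).any():
        raise NPXValidationError("dilution factors must be positive")
    return table


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise NPXValidationError(f"sample table is missing columns: {missing}")
    if samples["person_id"].duplicated().any():
        raise NPXValidationError("sample table must have one row per person")
    unknown = set(samples["group"]) - set(GROUPS)
    if unknown:
        raise NPXValidationError(f"unknown group labels: {sorted(unknown)}")
    for g in GROUPS:
        if not (samples["group"] == g).any():
            raise NPXValidationError(f"group '{g}' is empty")
    return samples


def select_dilution(table: pd.DataFrame, assay_id: str) -> float:
    """Dilution whose NPX values sit closest to the middle of the dynamic
    range: minimises the median over samples of |npx - (lod+uloq)/2|, ties
    broken toward the smaller dilution factor."""
    sub = table[table["assay_id"] == assay_id]
    if sub.empty:
        raise KeyError(f"assay {assay_id!r} not present")
    mid = (sub["lod"] + sub["uloq"]) / 2.0
    dist = (sub["npx"] - mid).abs()
    med = dist.groupby(sub["dilution"]).median().sort_index()
    return float(med.index[np.argmin(med.values)])  # argmin keeps first == smallest


def select_dilutions(table: pd.DataFrame) -> dict[str, float]:
    return {a: select_dilution(table, a) for a in sorted(table["assay_id"].unique())}


def dilution_linearity_score(table: pd.DataFrame, assay_id: str) -> float | None:
    """Mean absolute deviation (log2 units) of the observed inter-dilution NPX
    shift from the ideal ``log2(d2/d1)``, over samples and adjacent dilution
    pairs.  ``None`` when the assay was run at a single dilution."""
    sub = table[table["assay_id"] == assay_id]
    if sub.empty:
        raise KeyError(f"assay {assay_id!r} not present")
    wide = sub.pivot(index="sample_id", columns="dilution", values="npx")
    dils = sorted(wide.columns)
    if len(dils) < 2:
        return None
    devs = []
    for d1, d2 in zip(dils[:-1], dils[1:]):
        observed = wide[d1] - wide[d2]
        expected = np.log2(d2 / d1)
        devs.append((observed - expected).abs())
    return float(pd.concat(devs).mean())


def filter_lod(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    max_below: int = 2,
) -> tuple[pd.DataFrame, QCReport]:
    """Exclude assays with more than ``max_below`` below-LOD samples in either
    group; in retained assays, set below-LOD cells to missing.

    ``table`` must already be dilution-selected (one row per sample x assay).
    """
    dup = table.duplicated(subset=["sample_id", "assay_id"]).any()
    if dup:
        raise NPXValidationError(
            "filter_lod expects one row per sample x assay; select a dilution first"
        )
    merged = table.merge(samples[["person_id", "group"]], on="person_id", how="left")
    below = merged["npx"] < merged["lod"]
    counts = (
        merged.assign(below=below)
        .groupby(["assay_id", "group"], sort=True)["below"].sum()
        .unstack(fill_value=0)
    )
    report = QCReport()
    for assay in counts.index:
        report.below_lod_counts[assay] = {
            g: int(counts.loc[assay].get(g, 0)) for g in GROUPS
        }
    excluded = counts.index[(counts > max_below).any(axis=1)]
    for assay in excluded:
        report.excluded[assay] = "below_lod"
    retained = table[~table["assay_id"].isin(excluded)].copy()
    mask = retained["npx"] < retained["lod"]
    retained.loc[mask, "npx"] = np.nan
    report.n_cells_masked = int(mask.sum())
    return retained, report


def to_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a dilution-selected long table to samples x proteins."""
    return table.pivot(index="sample_id", columns="assay_id", values="npx")


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per protein, pooled over groups: subtract the mean and divide by the
    sample standard deviation (ddof=1), ignoring missing cells."""
    mat = matrix.astype(float)
    counts = mat.notna().sum(axis=0)
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise NPXValidationError(f"proteins with <2 non-missing values: {bad}")
    sd = mat.std(axis=0, ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = sd.index[(sd == 0) | sd.isna()].tolist()
        raise NPXValidationError(f"zero-variance proteins: {bad}")
    return (mat - mat.mean(axis=0)) / sd


def run_qc(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    linearity_threshold: float = 1.0,
    max_below: int = 2,
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC chain: dilution selection -> linearity exclusion -> LOD filter.

    Returns the retained one-row-per-sample x assay long table and a QCReport
    covering every input assay.
    """
    assays = sorted(table["assay_id"].unique())
    report = QCReport()
    keep_rows = []
    for assay in assays:
        chosen = select_dilution(table, assay)
        report.chosen_dilution[assay] = chosen
        score = dilution_linearity_score(table, assay)
        report.linearity_scores[assay] = score
        if score is not None and score > linearity_threshold:
            report.excluded[assay] = "nonlinearity"
            continue
        sub = table[(table["assay_id"] == assay) & (table["dilution"] == chosen)]
        if (~((sub["npx"] >= sub["lod"]) & (sub["npx"] <= sub["uloq"]))).all():
            # no sample in range at the chosen dilution: flag, do not drop silently
            report.excluded[assay] = "no_in_range"
            continue
        keep_rows.append(sub)
    selected = (
        pd.concat(keep_rows, ignore_index=True)
        if keep_rows
        else table.iloc[0:0].copy()
    )
    retained, lod_report = filter_lod(selected, samples, max_below=max_below)
    report.excluded.update(lod_report.excluded)
    report.below_lod_counts.update(lod_report.below_lod_counts)
    report.n_cells_masked = lod_report.n_cells_masked
    report.assert_partition(assays)
    return retained, report
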