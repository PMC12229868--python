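"""End-to-end orchestration: QC -> DE -> co-expression -> JGL -> enrichment.

The pipeline is a pure function of (input files, config, seed): identical
configuration yields byte-identical text outputs.  Each stage logs its
row counts into a :class:`RunManifest` so that bookkeeping invariants
(proteins in = retained + excluded at every filter) can be asserted after
the fact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import (EdgeSelectionRule, all_pairs,
                           select_enrichment_proteins, select_network_edges)
from .de import DEModelSpec, classify_de, extract_group_contrasts, fit_hierarchical_model
from .enrichment import read_gmt, run_three_analyses, write_enrichment_tsv
from .jgl import (JGLConfig, differential_clusters, group_covariances,
                  model_selection)
from .npx_io import read_npx_long, read_samples, run_qc, standardize, to_matrix

logger = logging.getLogger("synovnet")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "pca_overview",
           "edges_to_graphml"]


@dataclass
class PipelineConfig:
    npx_path: str = ""
    samples_path: str = ""
    gmt_path: str = ""
    function_annotation_path: str | None = None   # protein -> molecular function
    out_dir: str = "results/pipeline"
    seed: int = 0
    # QC
    linearity_threshold: float = 1.0
    max_below_lod: int = 2
    # differential expression
    pooling_mode: str = "fixed_interaction"
    fc_magnitude: float = 1.5
    # co-expression selection
    min_abs_slope: float = 1.0
    min_abs_diff: float = 1.0
    # joint graphical lasso
    jgl_n_proteins: int = 50
    jgl_protein_list: tuple[str, ...] | None = None  # overrides the ranking
    jgl_lambda1_grid: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    jgl_lambda2_grid: tuple[float, ...] = (0.0, 0.5, 1.0)
    jgl_max_iter: int = 2000
    # enrichment
    enrichment_min_m: int = 5

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("jgl_lambda1_grid", "jgl_lambda2_grid", "jgl_protein_list"):
            if getattr(cfg, key) is not None:
                setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def validate_paths(self) -> None:
        for label, p in (
            ("npx_path", self.npx_path),
            ("samples_path", self.samples_path),
            ("gmt_path", self.gmt_path),
        ):
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p!r} does not exist")
        if self.function_annotation_path and not Path(
            self.function_annotation_path
        ).exists():
            raise FileNotFoundError(
                f"function_annotation_path: {self.function_annotation_path!r}"
            )


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def log_stage(self, name: str, **counts) -> None:
        logger.info("stage %s: %s", name, counts)
        self.stages.append({"stage": name, **counts})

    def to_json(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        tmp.replace(path)  # atomic write at run end


def pca_overview(matrix: pd.DataFrame, groups=None):
    """Sample scores on the first two principal components of the
    column-centered matrix (SVD), plus explained-variance fractions.

    Missing cells are mean-imputed per protein for this overview only.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA overview needs at least 3 samples")
    mat = matrix.to_numpy(float)
    col_mean = np.nanmean(mat, axis=0)
    inds = np.where(np.isnan(mat))
    mat[inds] = np.take(col_mean, inds[1])
    centered = mat - mat.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("matrix has zero variance; PCA undefined")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / (mat.shape[0] - 1)
    explained = var / var.sum()
    k = min(2, s.size)
    scores = pd.DataFrame(
        U[:, :k] * s[:k], index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    if groups is not None:
        scores["group"] = np.asarray(groups)
    return scores, explained[:k], Vt[:k].T


def edges_to_graphml(edges: pd.DataFrame, path, functions: dict[str, str] | None = None):
    """Write the two group networks into one GraphML file; edges carry the
    group, slope and sign, nodes an optional molecular-function attribute."""
    graph = nx.MultiGraph()
    for row in edges.itertuples():
        graph.add_node(row.protein_a)
        graph.add_node(row.protein_b)
        graph.add_edge(
            row.protein_a, row.protein_b,
            group=row.group, slope=float(row.slope), sign=row.sign,
        )
    if functions:
        for node in graph.nodes:
            graph.nodes[node]["molecular_function"] = functions.get(node, "unknown")
    nx.write_graphml(graph, path)


def _rank_by_connectivity(zmatrix: pd.DataFrame, groups) -> pd.Series:
    """Rank proteins by their strongest within-group marginal correlation.

    Standardized columns all have unit pooled variance, so variance cannot
    rank them; the graphical-lasso subset should instead favour proteins
    that show co-variation structure within at least one group."""
    score = None
    for g in pd.unique(np.asarray(groups)):
        sub = zmatrix[np.asarray(groups) == g]
        corr = sub.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        best = corr.max(axis=0)
        score = best if score is None else np.maximum(score, best)
    return score.sort_values(ascending=False, kind="stable")


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and write all outputs under
    ``config.out_dir``.  Any stage error aborts with the stage name; the
    partial manifest is still written."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)
    manifest_path = out / "manifest.json"
    stage = "read"
    try:
        table = read_npx_long(config.npx_path)
        samples = read_samples(config.samples_path)
        pathways = read_gmt(config.gmt_path)
        functions = None
        if config.function_annotation_path:
            fn = pd.read_csv(config.function_annotation_path)
            functions = dict(zip(fn.iloc[:, 0], fn.iloc[:, 1]))
        n_assays_in = table["assay_id"].nunique()
        manifest.log_stage(stage, rows=len(table), assays=n_assays_in,
                           persons=len(samples), pathways=len(pathways))

        stage = "qc"
        retained, qc_report = run_qc(
            table, samples,
            linearity_threshold=config.linearity_threshold,
            max_below=config.max_below_lod,
        )
        qc_report.assert_partition(sorted(table["assay_id"].unique()))
        qc_report.to_json(out / "qc_report.json")
        manifest.outputs["qc_report"] = str(out / "qc_report.json")
        manifest.log_stage(
            stage, assays_in=n_assays_in,
            assays_retained=len(qc_report.retained),
            assays_excluded=len(qc_report.excluded),
            cells_masked=qc_report.n_cells_masked,
        )

        stage = "standardize"
        matrix = to_matrix(retained)
        zmatrix = standardize(matrix)
        person_group = samples.set_index("person_id")["group"]
        groups = person_group.loc[matrix.index].to_numpy()
        manifest.log_stage(stage, samples=matrix.shape[0], proteins=matrix.shape[1])

        stage = "differential_expression"
        long_de = retained.rename(columns={})[["person_id", "assay_id", "npx"]]
        spec = DEModelSpec(pooling_mode=config.pooling_mode)
        model = fit_hierarchical_model(long_de, samples, spec)
        de_results = extract_group_contrasts(model)
        _write_tsv(de_results, out / "differential_expression.tsv")
        manifest.outputs["differential_expression"] = str(
            out / "differential_expression.tsv")
        up, down, high = classify_de(de_results, fc_magnitude=config.fc_magnitude)
        manifest.log_stage(
            stage, proteins=len(de_results), up=len(up), down=len(down),
            high_magnitude=len(high),
            person_variance=model.person_variance,
            residual_variance=model.residual_variance,
        )

        stage = "coexpression"
        pairs = all_pairs(zmatrix, groups)
        _write_tsv(pairs, out / "pair_models.tsv")
        manifest.outputs["pair_models"] = str(out / "pair_models.tsv")
        ctrl_set, case_set, qual = select_enrichment_proteins(
            pairs, min_abs_diff=config.min_abs_diff)
        rule = EdgeSelectionRule(
            min_abs_slope=config.min_abs_slope, min_abs_diff=config.min_abs_diff)
        edges = select_network_edges(pairs, rule)
        edges.to_csv(out / "network_edges.csv", index=False, float_format="%.10g")
        manifest.outputs["network_edges"] = str(out / "network_edges.csv")
        edges_to_graphml(edges, out / "networks.graphml", functions)
        manifest.outputs["networks_graphml"] = str(out / "networks.graphml")
        manifest.log_stage(
            stage, ordered_pairs=len(pairs), qualifying_pairs=len(qual),
            control_set=len(ctrl_set), case_set=len(case_set),
            edges=len(edges),
        )

        stage = "joint_graphical_lasso"
        if config.jgl_protein_list:
            missing = set(config.jgl_protein_list) - set(zmatrix.columns)
            if missing:
                raise ValueError(f"jgl_protein_list not in data: {sorted(missing)}")
            subset = sorted(config.jgl_protein_list)
        else:
            subset = sorted(
                _rank_by_connectivity(zmatrix, groups).index[: config.jgl_n_proteins]
            )
        S_list, n_list, names = group_covariances(zmatrix[subset], groups)
        jgl_cfg = JGLConfig(max_iter=config.jgl_max_iter)
        sel_table, sel_fits = model_selection(
            S_list, n_list, config.jgl_lambda1_grid, config.jgl_lambda2_grid,
            jgl_cfg)
        sel_out = sel_table.copy()
        sel_out["edges_per_group"] = sel_out["edges_per_group"].astype(str)
        _write_tsv(sel_out, out / "jgl_model_selection.tsv")
        manifest.outputs["jgl_model_selection"] = str(out / "jgl_model_selection.tsv")
        best = sel_fits["bic"]
        for k, label in enumerate(("control", "OA")):
            _write_tsv(
                pd.DataFrame(best.theta[k], index=names, columns=names)
                .reset_index(names="protein"),
                out / f"precision_{label}.tsv",
            )
        clusters = differential_clusters(best, names)
        (out / "differential_clusters.json").write_text(
            json.dumps(clusters, indent=2, sort_keys=True))
        manifest.outputs["differential_clusters"] = str(
            out / "differential_clusters.json")
        manifest.log_stage(
            stage, proteins=len(subset),
            grid_points=len(sel_table),
            bic_edges=[best.edge_count(k) for k in range(2)],
            clusters={k: len(v) for k, v in clusters.items()},
        )

        stage = "enrichment"
        background = set(qc_report.retained)
        de_set = set(up) | set(down)
        tables = run_three_analyses(
            de_set, ctrl_set, case_set, background, pathways,
            min_m=config.enrichment_min_m)
        write_enrichment_tsv(tables, out / "enrichment.tsv")
        manifest.outputs["enrichment"] = str(out / "enrichment.tsv")
        manifest.log_stage(
            stage, background=len(background),
            rows={k: len(v) for k, v in tables.items()},
        )

        stage = "pca"
        scores, explained, _ = pca_overview(zmatrix, groups)
        _write_tsv(scores.reset_index(), out / "pca_scores.tsv")
        manifest.outputs["pca_scores"] = str(out / "pca_scores.tsv")
        manifest.log_stage(stage, explained_variance=[float(e) for e in explained])
    except Exception as err:
        manifest.log_stage("error", failed_stage=stage, message=str(err))
        manifest.to_json(manifest_path)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest.to_json(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest
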