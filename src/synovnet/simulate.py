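"""Synthetic NPX cohort generator with known ground truth.

Emulates the structure of a two-group synovial-fluid panel-immunoassay
study: a small control group of donors and a case (end-stage knee OA)
group, ~3 panels x 92 assays of log2-scale NPX values with per-person
random intercepts, age/sex/BMI covariate effects, case-group mean shifts,
group-specific conditional-dependence (precision) structure over a
designated protein subset, multi-dilution series with a hook-effect
("bad") assay, and LOD/ULOQ censoring thresholds.  Every planted feature
is recorded in a :class:`TruthRecord` so downstream stages can be scored
against a recoverable truth.

Randomness is drawn from named substreams of one seed, so e.g. adding
proteins does not perturb the sampled covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .npx_io import NPX_COLUMNS

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "default_config",
    "simulate_npx_dataset",
    "simulate_dilution_series",
    "chain_precision",
    "simulate_planted_pairs",
    "simulate_gmt",
    "write_dataset",
]

# named substreams: stage name -> spawn key (stable; never reorder)
_STREAMS = {
    "covariates": 0,
    "person_intercepts": 1,
    "protein_means": 2,
    "noise": 3,
    "dilution": 4,
    "effects": 5,
    "pathways": 6,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stage],))
    )


@dataclass
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated study: 13 control donors vs 11 OA
    patients, three 92-assay panels, log2-scale effects up to |3.4|
    (a 10.6-fold change), and three dilutions with the middle one sitting
    in the middle of each assay's dynamic range.
    """

    n_control: int = 13
    n_case: int = 11
    panels: tuple[tuple[str, int], ...] = (("CAM", 92), ("CVDIII", 92), ("DEV", 92))
    log2_effects: np.ndarray | None = None          # per protein, case - control
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.1, "bmi": 0.02}
    )
    person_sd: float = 0.3
    residual_sd: float = 0.5
    network_idx: np.ndarray | None = None           # protein subset with planted structure
    control_precision: np.ndarray | None = None
    case_precision: np.ndarray | None = None
    lod_quantile: float = 0.02
    uloq_quantile: float = 0.995
    dilution_factors: tuple[float, ...] = (1.0, 20.0, 200.0)
    ref_dilution: float | None = None               # default: middle factor
    dilution_noise_sd: float = 0.05
    bad_assay_ids: tuple[str, ...] = ()
    low_detect_assay_ids: tuple[str, ...] = ()
    low_detect_lod_quantile: float = 0.35
    seed: int = 0

    @property
    def n_proteins(self) -> int:
        return sum(k for _, k in self.panels)

    @property
    def assay_ids(self) -> list[str]:
        out = []
        for panel, k in self.panels:
            out.extend(f"{panel}_{i + 1:03d}" for i in range(k))
        return out

    @property
    def reference_dilution(self) -> float:
        if self.ref_dilution is not None:
            return self.ref_dilution
        factors = sorted(self.dilution_factors)
        return factors[len(factors) // 2]

    def validate(self) -> None:
        if self.n_control < 3 or self.n_case < 3:
            raise ValueError("need at least 3 persons per group")
        if list(self.dilution_factors) != sorted(set(self.dilution_factors)):
            raise ValueError("dilution_factors must be strictly increasing")
        if any(d <= 0 for d in self.dilution_factors):
            raise ValueError("dilution_factors must be positive")
        for name in ("control_precision", "case_precision"):
            theta = getattr(self, name)
            if theta is None:
                continue
            theta = np.asarray(theta, float)
            if not np.allclose(theta, theta.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
            if np.linalg.eigvalsh(theta).min() <= 0:
                raise ValueError(f"{name} is not positive definite")
        if self.log2_effects is not None:
            eff = np.asarray(self.log2_effects, float)
            if eff.shape != (self.n_proteins,):
                raise ValueError("log2_effects must have one entry per protein")
            if not np.all(np.isfinite(eff)):
                raise ValueError("log2_effects must be finite")


@dataclass
class TruthRecord:
    """Ground truth planted by the generator (the acceptance oracle)."""

    true_log2_effects: dict[str, float]
    control_edges: list[tuple[str, str]]
    case_edges: list[tuple[str, str]]
    differential_edges: list[tuple[str, str, str]]  # (a, b, group-with-edge-difference)
    censored_cells: list[tuple[str, str, float]]    # (sample, assay, dilution) below LOD
    corrupted_assays: list[str]
    low_detect_assays: list[str]
    network_proteins: list[str]

    def to_json(self, path) -> None:
        payload = {
            "true_log2_effects": self.true_log2_effects,
            "control_edges": [list(e) for e in self.control_edges],
            "case_edges": [list(e) for e in self.case_edges],
            "differential_edges": [list(e) for e in self.differential_edges],
            "censored_cells": [list(c) for c in self.censored_cells],
            "corrupted_assays": self.corrupted_assays,
            "low_detect_assays": self.low_detect_assays,
            "network_proteins": self.network_proteins,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            true_log2_effects=d["true_log2_effects"],
            control_edges=[tuple(e) for e in d["control_edges"]],
            case_edges=[tuple(e) for e in d["case_edges"]],
            differential_edges=[tuple(e) for e in d["differential_edges"]],
            censored_cells=[tuple(c) for c in d["censored_cells"]],
            corrupted_assays=d["corrupted_assays"],
            low_detect_assays=d["low_detect_assays"],
            network_proteins=d["network_proteins"],
        )


def chain_precision(p: int, edges: list[tuple[int, int]], weight: float = 0.3) -> np.ndarray:
    """Unit-diagonal precision matrix with ``-weight`` at the given edges.

    With |weight| <= 0.45 and at most two incident edges per node the matrix
    is diagonally dominant, hence positive definite.
    """
    theta = np.eye(p)
    for i, j in edges:
        theta[i, j] = theta[j, i] = -weight
    if np.linalg.eigvalsh(theta).min() <= 1e-8:
        raise ValueError("edge set / weight produce a non-PD precision matrix")
    return theta


def default_config(seed: int = 0, de_fraction: float = 0.5) -> SimulationConfig:
    """A configuration emulating the study's conditions.

    Half the proteins carry a case-group shift drawn from N(0, 1.2^2)
    truncated to |3.4| log2 units, with the two largest planted shifts set to
    +3.4 (a 10.6-fold increase) and -3.4; a 20-protein subset carries
    group-specific conditional-dependence chains; one assay is corrupted with
    a hook-effect dilution response and one has a high LOD so that more than
    two samples of a group fall below it.
    """
    cfg = SimulationConfig(seed=seed)
    p = cfg.n_proteins
    rng = _rng(seed, "effects")
    effects = np.zeros(p)
    n_de = int(round(de_fraction * p))
    de_idx = rng.choice(p, size=n_de, replace=False)
    effects[de_idx] = np.clip(rng.normal(0.0, 1.2, size=n_de), -3.4, 3.4)
    effects[de_idx[0]] = 3.4
    if n_de > 1:
        effects[de_idx[1]] = -3.4
    cfg.log2_effects = effects

    net = np.arange(20)
    ctrl_edges = [(i, i + 1) for i in range(15)]
    case_edges = [(i, i + 1) for i in range(7)] + [(16, 17), (17, 18), (18, 19)]
    cfg.network_idx = net
    cfg.control_precision = chain_precision(20, ctrl_edges)
    cfg.case_precision = chain_precision(20, case_edges)
    assays = cfg.assay_ids
    cfg.bad_assay_ids = (assays[-1],)          # hook-effect dilution response
    cfg.low_detect_assay_ids = (assays[-2],)   # planted below-LOD exclusion
    return cfg


def simulate_dilution_series(
    base_values: np.ndarray,
    factors,
    corrupt: bool = False,
    noise_sd: float = 0.0,
    ref: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-dilution NPX values from base (reference-dilution) values.

    A well-behaved assay at dilution ``d`` shifts NPX by ``-log2(d/ref)``
    plus small noise.  A corrupted assay mimics a hook effect: ideal values
    above a saturation cap are reflected about it, so the observed
    inter-dilution shift deviates from the ideal log2 ratio.
    Rows of the result follow the order of ``factors``.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("factors must be non-empty")
    if any(d <= 0 for d in factors):
        raise ValueError("dilution factors must be positive")
    base = np.asarray(base_values, float)
    if ref is None:
        ref = factors[0]
    ideal = np.stack([base - np.log2(d / ref) for d in factors])
    if corrupt:
        lo, hi = ideal.min(), ideal.max()
        cap = lo + 0.25 * (hi - lo) if hi > lo else float(np.mean(base)) - 0.75
        ideal = np.where(ideal > cap, 2.0 * cap - ideal, ideal)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        ideal = ideal + rng.normal(0.0, noise_sd, size=ideal.shape)
    return ideal


def simulate_npx_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (NPX long table, sample metadata table, truth record).

    One row per sample x assay x dilution; values are protein mean +
    case-group shift + covariate terms + person intercept + noise that is
    multivariate normal (per-group precision) over the designated network
    subset and independent elsewhere.  Deterministic for a fixed seed.
    """
    config.validate()
    seed = config.seed
    assays = config.assay_ids
    p = config.n_proteins
    n = config.n_control + config.n_case

    # --- sample metadata -------------------------------------------------
    rng_cov = _rng(seed, "covariates")
    persons = [f"ctrl{i + 1:02d}" for i in range(config.n_control)] + [
        f"case{i + 1:02d}" for i in range(config.n_case)
    ]
    group = np.array(["control"] * config.n_control + ["OA"] * config.n_case)
    age = rng_cov.uniform(55.0, 80.0, size=n)
    sex = np.where(rng_cov.random(n) < 0.7, "F", "M")
    bmi = np.clip(rng_cov.normal(27.0, 4.0, size=n), 18.0, 45.0)
    samples = pd.DataFrame(
        {"person_id": persons, "group": group, "age": np.round(age, 1),
         "sex": sex, "bmi": np.round(bmi, 1)}
    )

    # --- expression matrix at the reference dilution ---------------------
    rng_mu = _rng(seed, "protein_means")
    mu = rng_mu.uniform(2.0, 10.0, size=p)
    effects = (
        np.zeros(p) if config.log2_effects is None
        else np.asarray(config.log2_effects, float)
    )
    is_case = (group == "OA").astype(float)
    ce = config.covariate_effects
    cov_term = (
        ce.get("age", 0.0) * (age - np.mean(age))
        + ce.get("sex", 0.0) * (sex == "M").astype(float)
        + ce.get("bmi", 0.0) * (bmi - np.mean(bmi))
    )
    rng_person = _rng(seed, "person_intercepts")
    person_int = rng_person.normal(0.0, config.person_sd, size=n)

    rng_noise = _rng(seed, "noise")
    noise = rng_noise.normal(0.0, config.residual_sd, size=(n, p))
    net = (
        np.asarray(config.network_idx, int)
        if config.network_idx is not None
        else np.zeros(0, int)
    )
    if net.size and config.control_precision is not None:
        sigma_c = np.linalg.inv(np.asarray(config.control_precision, float))
        sigma_t = np.linalg.inv(np.asarray(config.case_precision, float))
        ctrl_rows = np.nonzero(group == "control")[0]
        case_rows = np.nonzero(group == "OA")[0]
        noise[np.ix_(ctrl_rows, net)] = rng_noise.multivariate_normal(
            np.zeros(net.size), sigma_c, size=ctrl_rows.size, method="cholesky"
        )
        noise[np.ix_(case_rows, net)] = rng_noise.multivariate_normal(
            np.zeros(net.size), sigma_t, size=case_rows.size, method="cholesky"
        )

    values = (
        mu[None, :]
        + np.outer(is_case, effects)
        + cov_term[:, None]
        + person_int[:, None]
        + noise
    )

    # --- dilution series and censoring thresholds ------------------------
    factors = sorted(config.dilution_factors)
    ref = config.reference_dilution
    rng_dil = _rng(seed, "dilution")
    rows = []
    censored: list[tuple[str, str, float]] = []
    for j, assay in enumerate(assays):
        series = simulate_dilution_series(
            values[:, j], factors,
            corrupt=assay in config.bad_assay_ids,
            noise_sd=config.dilution_noise_sd, ref=ref, rng=rng_dil,
        )
        ref_vals = series[factors.index(ref)]
        q_lod = (
            config.low_detect_lod_quantile
            if assay in config.low_detect_assay_ids
            else config.lod_quantile
        )
        lod = float(np.quantile(ref_vals, q_lod))
        uloq = float(np.quantile(ref_vals, config.uloq_quantile))
        if uloq <= lod:
            uloq = lod + 1e-6
        panel = assay.rsplit("_", 1)[0]
        for di, d in enumerate(factors):
            for si, person in enumerate(persons):
                npx = float(series[di, si])
                rows.append(
                    (person, person, assay, panel, d, npx, lod, uloq, True)
                )
                if npx < lod:
                    censored.append((person, assay, d))
    npx = pd.DataFrame(rows, columns=NPX_COLUMNS)

    # --- truth ------------------------------------------------------------
    def _edge_names(theta):
        out = []
        for a in range(net.size):
            for b in range(a + 1, net.size):
                if abs(theta[a, b]) > 1e-12:
                    out.append((assays[net[a]], assays[net[b]]))
        return out

    ctrl_edges = (
        _edge_names(np.asarray(config.control_precision, float))
        if net.size and config.control_precision is not None else []
    )
    case_edges = (
        _edge_names(np.asarray(config.case_precision, float))
        if net.size and config.case_precision is not None else []
    )
    diff_edges = [(a, b, "control") for a, b in ctrl_edges if (a, b) not in case_edges]
    diff_edges += [(a, b, "OA") for a, b in case_edges if (a, b) not in ctrl_edges]
    truth = TruthRecord(
        true_log2_effects={a: float(effects[j]) for j, a in enumerate(assays)},
        control_edges=ctrl_edges,
        case_edges=case_edges,
        differential_edges=diff_edges,
        censored_cells=censored,
        corrupted_assays=list(config.bad_assay_ids),
        low_detect_assays=list(config.low_detect_assay_ids),
        network_proteins=[assays[j] for j in net],
    )
    return npx, samples, truth


def simulate_planted_pairs(
    rng: np.random.Generator,
    n_pairs: int = 8,
    slope: float = 1.5,
    residual_sd: float = 0.5,
    n_per_group: int = 12,
) -> tuple[pd.DataFrame, np.ndarray, list[frozenset]]:
    """Disjoint protein pairs with control-only co-expression.

    Values are generated directly on the analysis (standardized-comparable)
    scale: in the control group the outcome follows ``+/-slope * predictor``
    plus ``N(0, residual_sd)`` noise; in the case group every protein is
    independent ``N(0, residual_sd)`` (slope 0, same residual scale, so
    within-group scales stay homogeneous).  Returns (matrix, group labels,
    planted unordered pairs) — the ground truth for differential-edge
    recovery studies.
    """
    n = 2 * n_per_group
    groups = np.array(["control"] * n_per_group + ["OA"] * n_per_group)
    cols: dict[str, np.ndarray] = {}
    planted = []
    for j in range(n_pairs):
        s = slope if j % 2 == 0 else -slope
        x = np.concatenate([
            rng.normal(0.0, 1.0, n_per_group),
            rng.normal(0.0, residual_sd, n_per_group),
        ])
        y = np.concatenate([
            s * x[:n_per_group] + rng.normal(0.0, residual_sd, n_per_group),
            rng.normal(0.0, residual_sd, n_per_group),
        ])
        cols[f"X{j}"] = x
        cols[f"Y{j}"] = y
        planted.append(frozenset((f"X{j}", f"Y{j}")))
    return pd.DataFrame(cols), groups, planted


_CATEGORIES = (
    "Signal Transduction", "Immune System", "Hemostasis",
    "Extracellular matrix organization", "Metabolism of proteins",
    "Vesicle-mediated transport", "Developmental Biology", "Metabolism",
)


def simulate_gmt(
    assay_ids,
    path,
    n_pathways: int = 100,
    size_range: tuple[int, int] = (5, 30),
    planted: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> None:
    """Write a synthetic GMT annotation over the panel's assays.

    Each pathway draws a random member set from ``assay_ids`` and a
    top-level category label.  ``planted`` pathways (name -> exact member
    list) are prepended, letting tests plant a pathway fully contained in a
    protein set of interest.
    """
    rng = _rng(seed, "pathways")
    assay_ids = list(assay_ids)
    lines = []
    for name, members in (planted or {}).items():
        lines.append("\t".join([name, _CATEGORIES[0], *sorted(members)]))
    for i in range(n_pathways - len(lines)):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = sorted(
            rng.choice(assay_ids, size=min(size, len(assay_ids)), replace=False)
        )
        category = _CATEGORIES[int(rng.integers(len(_CATEGORIES)))]
        lines.append("\t".join([f"PATH{i + 1:03d}", category, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(npx, samples, truth, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "npx": str(outdir / "npx.csv"),
        "samples": str(outdir / "samples.csv"),
        "truth": str(outdir / "truth.json"),
    }
    npx.to_csv(paths["npx"], index=False)
    samples.to_csv(paths["samples"], index=False)
    truth.to_json(paths["truth"])
    return paths
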