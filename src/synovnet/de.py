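"""Hierarchical differential abundance: one mixed model across all proteins.

All proteins enter a single linear mixed model of log2 NPX with protein,
group, their interaction, and age/sex/BMI as fixed effects, and a random
intercept per person.  The per-protein case-minus-control contrast
(group main effect + that protein's interaction term) is reported as a
log2 difference and, after exponentiation base 2, as a fold change with a
nominal Wald 95% confidence interval.  No multiplicity correction is
applied anywhere in this module, deliberately: the emulated analysis
reports nominal intervals only.

Two pooling modes are offered because the degree of information sharing
between proteins is a genuine modelling choice:

``fixed_interaction`` (default)
    protein x group terms are fixed effects; each protein's contrast is
    estimated without shrinkage.
``shrunken_interaction``
    the protein-specific group deviation is a second random effect, so
    per-protein contrasts are partially pooled toward the common group
    effect (empirical-BLUP shrinkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .lmm import LMMFit, fit_lmm

__all__ = [
    "DEModelSpec",
    "FittedDEModel",
    "fit_hierarchical_model",
    "extract_group_contrasts",
    "classify_de",
    "format_fold_change",
    "SingularDesignError",
]

_Z975 = float(norm.ppf(0.975))


class SingularDesignError(ValueError):
    pass


@dataclass
class DEModelSpec:
    pooling_mode: str = "fixed_interaction"   # or "shrunken_interaction"
    reml: bool = True
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    fix_person_variance_zero: bool = False    # degenerate OLS limit

    def validate(self) -> None:
        if self.pooling_mode not in ("fixed_interaction", "shrunken_interaction"):
            raise ValueError(f"unknown pooling_mode {self.pooling_mode!r}")


@dataclass
class FittedDEModel:
    fit: LMMFit
    spec: DEModelSpec
    proteins: list[str]          # sorted; proteins[0] is the reference level
    idx_group: int
    idx_interaction: dict[str, int]   # protein -> fixed-effect column (fixed mode)
    person_variance: float
    residual_variance: float

    @property
    def converged(self) -> bool:
        return self.fit.converged


def _prepare(long_table: pd.DataFrame, samples: pd.DataFrame, spec: DEModelSpec):
    df = long_table.merge(
        samples[["person_id", "group", "age", "sex", "bmi"]],
        on="person_id", how="left",
    )
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "person_id"].unique().tolist()
        raise SingularDesignError(f"persons missing from sample table: {missing}")
    df = df.dropna(subset=["npx"]).reset_index(drop=True)
    seen = df.groupby("assay_id")["group"].nunique()
    lone = seen.index[seen < 2].tolist()
    if lone:
        raise SingularDesignError(
            f"proteins observed in one group only: {lone}"
        )
    counts = samples.groupby("group")["person_id"].nunique()
    if (counts < 2).any():
        raise SingularDesignError("need at least 2 persons per group")
    return df


def _design(df: pd.DataFrame, spec: DEModelSpec):
    """Build the fixed-effect design (treatment coding, control & first
    protein as references; age/BMI mean-centered so the group contrast is at
    average covariates)."""
    proteins = sorted(df["assay_id"].unique())
    prot_codes = pd.Categorical(df["assay_id"], categories=proteins).codes
    g = (df["group"] == "OA").to_numpy(float)
    n, p = len(df), len(proteins)

    cols, names = [np.ones(n)], ["intercept"]
    for j in range(1, p):
        cols.append((prot_codes == j).astype(float))
        names.append(f"protein[{proteins[j]}]")
    cols.append(g)
    names.append("group[OA]")
    idx_group = len(names) - 1
    idx_inter: dict[str, int] = {}
    if spec.pooling_mode == "fixed_interaction":
        for j in range(1, p):
            cols.append((prot_codes == j).astype(float) * g)
            idx_inter[proteins[j]] = len(names)
            names.append(f"protein[{proteins[j]}]:group[OA]")
    for cov in spec.covariates:
        if cov == "sex":
            cols.append((df["sex"] == "M").to_numpy(float))
            names.append("sex[M]")
        else:
            v = df[cov].to_numpy(float)
            cols.append(v - v.mean())
            names.append(f"{cov}_c")
    X = np.column_stack(cols)
    return X, names, proteins, prot_codes, g, idx_group, idx_inter


def fit_hierarchical_model(
    long_table: pd.DataFrame,
    samples: pd.DataFrame,
    spec: DEModelSpec | None = None,
) -> FittedDEModel:
    """Fit the all-protein mixed model.

    ``long_table`` has one row per person x protein with columns
    ``person_id``, ``assay_id``, ``npx`` (missing/below-LOD cells absent or
    NaN; they are dropped from the likelihood, not imputed).
    """
    spec = spec or DEModelSpec()
    spec.validate()
    df = _prepare(long_table, samples, spec)
    X, names, proteins, prot_codes, g, idx_group, idx_inter = _design(df, spec)

    person_codes = pd.Categorical(df["person_id"]).codes.astype(int)
    blocks = [person_codes]
    block_names = ["person"]
    if spec.pooling_mode == "shrunken_interaction":
        # group-deviation random effect: loads only on case observations
        dev = np.where(g > 0, prot_codes, -1).astype(int)
        blocks.append(dev)
        block_names.append("protein_group_dev")

    try:
        fixed = None
        if spec.fix_person_variance_zero:
            fixed = np.zeros(len(blocks))
        fit = fit_lmm(
            X, df["npx"].to_numpy(float), blocks,
            names=names, block_names=block_names, reml=spec.reml,
            compute_mme=(spec.pooling_mode == "shrunken_interaction"),
            fixed_lambdas=fixed,
        )
    except np.linalg.LinAlgError as err:
        raise SingularDesignError(f"singular design: {err}") from err
    return FittedDEModel(
        fit=fit,
        spec=spec,
        proteins=proteins,
        idx_group=idx_group,
        idx_interaction=idx_inter,
        person_variance=float(fit.tau2[0]),
        residual_variance=float(fit.sigma2),
    )


def extract_group_contrasts(model: FittedDEModel) -> pd.DataFrame:
    """Per-protein case-minus-control contrast with Wald 95% CI and the
    fold-change-scale transform (2^x)."""
    if not model.converged:
        raise RuntimeError("model did not converge; contrasts unavailable")
    fit = model.fit
    rows = []
    if model.spec.pooling_mode == "fixed_interaction":
        for prot in model.proteins:
            c = np.zeros(fit.beta.size)
            c[model.idx_group] = 1.0
            if prot in model.idx_interaction:
                c[model.idx_interaction[prot]] = 1.0
            delta = float(c @ fit.beta)
            se = float(np.sqrt(c @ fit.cov_beta @ c))
            rows.append((prot, delta, se))
    else:
        # delta_p = fixed group effect + BLUP of protein's group deviation;
        # prediction SE from the mixed-model-equation covariance
        mme = fit.mme_cov
        p_fix = fit.n_fixed
        offset = p_fix + fit.n_levels[0]  # person levels come first
        blup = fit.blups[1]
        for j, prot in enumerate(model.proteins):
            c = np.zeros(mme.shape[0])
            c[model.idx_group] = 1.0
            c[offset + j] = 1.0
            delta = float(fit.beta[model.idx_group] + blup[j])
            se = float(np.sqrt(c @ mme @ c))
            rows.append((prot, delta, se))

    out = pd.DataFrame(rows, columns=["protein", "delta_log2", "se"])
    out["ci_low"] = out["delta_log2"] - _Z975 * out["se"]
    out["ci_high"] = out["delta_log2"] + _Z975 * out["se"]
    out["fold_change"] = 2.0 ** out["delta_log2"]
    out["fc_ci_low"] = 2.0 ** out["ci_low"]
    out["fc_ci_high"] = 2.0 ** out["ci_high"]
    excludes0 = (out["ci_low"] > 0) | (out["ci_high"] < 0)
    out["direction"] = np.where(
        ~excludes0, "inconclusive", np.where(out["delta_log2"] > 0, "up", "down")
    )
    return out


def classify_de(
    results: pd.DataFrame, fc_magnitude: float = 1.5
) -> tuple[list[str], list[str], list[str]]:
    """(up, down, high_magnitude) protein lists.

    up/down: Wald 95% CI excludes 0 and the point estimate is positive /
    negative; high_magnitude: up or down with
    max(fold_change, 1/fold_change) >= ``fc_magnitude``.
    """
    up = results.loc[results["direction"] == "up", "protein"].tolist()
    down = results.loc[results["direction"] == "down", "protein"].tolist()
    mag = np.maximum(results["fold_change"], 1.0 / results["fold_change"])
    high = results.loc[
        (results["direction"] != "inconclusive") & (mag >= fc_magnitude), "protein"
    ].tolist()
    return up, down, high


def format_fold_change(row, digits: int = 2) -> str:
    """Human-readable ``FC [low, high]`` string, e.g. ``0.03 [0.02, 0.05]``."""
    return (
        f"{row['fold_change']:.{digits}f} "
        f"[{row['fc_ci_low']:.{digits}f}, {row['fc_ci_high']:.{digits}f}]"
    )
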