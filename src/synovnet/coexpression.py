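"""All-pairs differential co-expression via interaction regressions.

For every ordered protein pair (outcome y, predictor x) on standardized
NPX, fit ``y = b0 + b1 x + b2 g + b3 x g`` (g = 1 for the case group) by
OLS.  ``b1`` is the control-group co-expression slope, ``b1 + b3`` the
case-group slope and ``b3`` the slope difference, each with a t-based 95%
CI on ``n_used - 4`` degrees of freedom.  Missing cells are handled
pairwise-complete, maximising n per pair.  Selection rules then pick the
protein sets fed to pathway enrichment and the signed edges of the
group-specific co-expression networks.

No multiplicity correction is applied over the ~p^2 pair models; slopes and
intervals are exploratory and nominal.

``fit_pair`` is the readable single-pair reference path (statsmodels OLS);
``all_pairs`` is an algebraically equivalent vectorised implementation used
for full panels (both are cross-checked against each other and against a
normal-equations oracle in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist

__all__ = [
    "PairModel",
    "EdgeSelectionRule",
    "fit_pair",
    "all_pairs",
    "select_enrichment_proteins",
    "select_network_edges",
]

PAIR_COLUMNS = [
    "outcome", "predictor",
    "slope_control", "se_control", "ci_low_control", "ci_high_control",
    "slope_case", "se_case", "ci_low_case", "ci_high_case",
    "slope_diff", "se_diff", "ci_low_diff", "ci_high_diff",
    "n_used", "estimable",
]


@dataclass
class PairModel:
    outcome: str
    predictor: str
    slope_control: float
    se_control: float
    ci_control: tuple[float, float]
    slope_case: float
    se_case: float
    ci_case: tuple[float, float]
    slope_diff: float
    se_diff: float
    ci_diff: tuple[float, float]
    n_used: int
    estimable: bool = True


@dataclass
class EdgeSelectionRule:
    """Network edge criteria: the pair's slope difference must be large and
    confidently non-zero, and the qualifying group's own slope must be large
    and confidently non-zero.  Each CI clause can be toggled because the
    emulated analysis is ambiguous about which interval its wording refers
    to; defaults require both."""

    min_abs_slope: float = 1.0
    min_abs_diff: float = 1.0
    require_diff_ci: bool = True
    require_group_ci: bool = True

    def __post_init__(self):
        if self.min_abs_slope <= 0 or self.min_abs_diff <= 0:
            raise ValueError("thresholds must be positive")


def fit_pair(x, y, groups) -> PairModel:
    """OLS interaction fit for one ordered (predictor, outcome) pair.

    Rows with any missing value are dropped pairwise; needs >= 4 complete
    triples per group, and within-group variation in x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    g = np.asarray([1.0 if v in ("OA", 1, True) else 0.0 for v in groups])
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y, g = x[keep], y[keep], g[keep]
    n = x.size

    def _flagged():
        nan2 = (np.nan, np.nan)
        return PairModel("y", "x", *[np.nan, np.nan, nan2] * 3, n_used=n,
                         estimable=False)

    if min((g == 0).sum(), (g == 1).sum()) < 4:
        return _flagged()
    if np.var(x[g == 0]) == 0 or np.var(x[g == 1]) == 0:
        return _flagged()
    X = np.column_stack([np.ones(n), x, g, x * g])
    res = sm.OLS(y, X).fit()
    tcrit = float(t_dist.ppf(0.975, n - 4))
    b = res.params
    V = res.cov_params()
    slope_control = float(b[1])
    se_control = float(np.sqrt(V[1, 1]))
    slope_case = float(b[1] + b[3])
    se_case = float(np.sqrt(V[1, 1] + V[3, 3] + 2 * V[1, 3]))
    slope_diff = float(b[3])
    se_diff = float(np.sqrt(V[3, 3]))
    return PairModel(
        outcome="y", predictor="x",
        slope_control=slope_control, se_control=se_control,
        ci_control=(slope_control - tcrit * se_control,
                    slope_control + tcrit * se_control),
        slope_case=slope_case, se_case=se_case,
        ci_case=(slope_case - tcrit * se_case, slope_case + tcrit * se_case),
        slope_diff=slope_diff, se_diff=se_diff,
        ci_diff=(slope_diff - tcrit * se_diff, slope_diff + tcrit * se_diff),
        n_used=n,
    )


def _group_pair_stats(mat: np.ndarray):
    """Pairwise-complete first/second moments for one group.

    Returns, for each ordered (outcome i, predictor j):
    joint n, Sxx (predictor SS), Syy (outcome SS), Sxy — all centred on the
    pairwise-complete means.
    """
    W = (~np.isnan(mat)).astype(float)
    M = np.nan_to_num(mat)
    n_ij = W.T @ W                       # joint counts, symmetric
    sum_pred = W.T @ M                   # (i,j): sum of x_j over joint support
    P = M.T @ M                          # (i,j): sum x_i x_j over joint support
    Q = W.T @ (M * M)                    # (i,j): sum x_j^2 over joint support
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = P - sum_pred * sum_pred.T / n_ij
        sxx = Q - sum_pred**2 / n_ij     # predictor j, support of (i, j)
        syy = Q.T - sum_pred.T**2 / n_ij  # outcome i, same support
    return n_ij, sxx, syy, sxy


def all_pairs(matrix: pd.DataFrame, groups) -> pd.DataFrame:
    """Interaction regressions for every ordered protein pair.

    ``matrix`` is samples x proteins (standardized NPX); ``groups`` aligns
    with its rows.  Returns one row per ordered pair in lexicographic order
    (outcome, then predictor), with the same estimates fit_pair would give.
    """
    proteins = list(matrix.columns)
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    g = np.asarray([1.0 if v in ("OA", 1, True) else 0.0 for v in groups])
    if len(set(g)) < 2:
        raise ValueError("both groups must be present")
    order = np.argsort(proteins, kind="stable")
    mat = matrix.to_numpy(float)[:, order]
    proteins = [proteins[i] for i in order]
    p = len(proteins)

    nc, sxx_c, syy_c, sxy_c = _group_pair_stats(mat[g == 0])
    nt, sxx_t, syy_t, sxy_t = _group_pair_stats(mat[g == 1])

    with np.errstate(divide="ignore", invalid="ignore"):
        bc = sxy_c / sxx_c                    # control slope, outcome i pred j
        bt = sxy_t / sxx_t
        rss = (syy_c - sxy_c**2 / sxx_c) + (syy_t - sxy_t**2 / sxx_t)
        n_used = nc + nt
        df = n_used - 4
        s2 = rss / df
        se_c = np.sqrt(s2 / sxx_c)
        se_t = np.sqrt(s2 / sxx_t)
        se_d = np.sqrt(s2 * (1.0 / sxx_c + 1.0 / sxx_t))
    diff = bt - bc
    estimable = (nc >= 4) & (nt >= 4) & (sxx_c > 0) & (sxx_t > 0) & (df > 0)

    iu, ju = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
    off = iu != ju
    tcrit = np.full_like(s2, np.nan)
    ok = estimable & off
    tcrit[ok] = t_dist.ppf(0.975, df[ok])

    def flat(a):
        return a[off]

    out = pd.DataFrame(
        {
            "outcome": np.array(proteins)[iu[off]],
            "predictor": np.array(proteins)[ju[off]],
            "slope_control": flat(bc), "se_control": flat(se_c),
            "slope_case": flat(bt), "se_case": flat(se_t),
            "slope_diff": flat(diff), "se_diff": flat(se_d),
            "n_used": flat(n_used).astype(int),
            "estimable": flat(estimable),
        }
    )
    tc = flat(tcrit)
    for stem in ("control", "case", "diff"):
        s = out[f"slope_{stem}"]
        se = out[f"se_{stem}"]
        out[f"ci_low_{stem}"] = s - tc * se
        out[f"ci_high_{stem}"] = s + tc * se
    out.loc[~out["estimable"], out.columns.difference(
        ["outcome", "predictor", "n_used", "estimable"])] = np.nan
    out = out[PAIR_COLUMNS].sort_values(["outcome", "predictor"],
                                        kind="stable").reset_index(drop=True)
    return out


def _qualifying(pairs: pd.DataFrame, min_abs_diff: float, require_ci: bool):
    ok = pairs["estimable"].fillna(False).astype(bool)
    ok &= pairs["slope_diff"].abs() >= min_abs_diff
    if require_ci:
        ok &= (pairs["ci_low_diff"] > 0) | (pairs["ci_high_diff"] < 0)
    return ok


def _dedup_unordered(pairs: pd.DataFrame) -> pd.DataFrame:
    """One row per unordered pair: keep the direction with the larger
    |slope_diff| (ties: lexicographically first outcome)."""
    df = pairs.copy()
    a = np.minimum(df["outcome"], df["predictor"])
    b = np.maximum(df["outcome"], df["predictor"])
    df["_key"] = a + "\x00" + b
    df["_mag"] = df["slope_diff"].abs().fillna(-np.inf)
    df = df.sort_values(["_key", "_mag", "outcome"],
                        ascending=[True, False, True], kind="stable")
    df = df.drop_duplicates("_key", keep="first")
    return df.drop(columns=["_key", "_mag"]).reset_index(drop=True)


def select_enrichment_proteins(
    pairs: pd.DataFrame, min_abs_diff: float = 1.0, require_ci: bool = True
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Protein sets for pathway enrichment.

    A pair qualifies when |slope difference| >= ``min_abs_diff`` and the
    difference CI excludes 0.  Qualifying pairs are split by which group
    shows the larger |slope|; returns (control-dominant protein set,
    case-dominant protein set, qualifying unordered pairs).
    """
    dedup = _dedup_unordered(pairs)
    qual = dedup[_qualifying(dedup, min_abs_diff, require_ci)].copy()
    ctrl_dom = qual["slope_control"].abs() >= qual["slope_case"].abs()
    control_set: set[str] = set()
    case_set: set[str] = set()
    for dom, row in zip(ctrl_dom, qual.itertuples()):
        (control_set if dom else case_set).update((row.outcome, row.predictor))
    qual["dominant_group"] = np.where(ctrl_dom, "control", "OA")
    return control_set, case_set, qual.reset_index(drop=True)


def select_network_edges(
    pairs: pd.DataFrame, rule: EdgeSelectionRule | None = None
) -> pd.DataFrame:
    """Signed edges of the group-specific co-expression networks.

    An unordered pair enters a group's network when the pair's slope
    difference qualifies (|diff| >= threshold, CI excluding 0) *and* that
    group's slope has |slope| >= threshold with its CI excluding 0.  Edge
    sign is the sign of the qualifying slope.  Returns a frame with columns
    protein_a, protein_b, group, slope, sign.
    """
    rule = rule or EdgeSelectionRule()
    dedup = _dedup_unordered(pairs)
    qual = dedup[_qualifying(dedup, rule.min_abs_diff, rule.require_diff_ci)]
    records = []
    for _, row in qual.iterrows():
        a, b = sorted((row["outcome"], row["predictor"]))
        for group, stem in (("control", "control"), ("OA", "case")):
            slope = row[f"slope_{stem}"]
            if not np.isfinite(slope) or abs(slope) < rule.min_abs_slope:
                continue
            if rule.require_group_ci and not (
                row[f"ci_low_{stem}"] > 0 or row[f"ci_high_{stem}"] < 0
            ):
                continue
            records.append(
                (a, b, group, float(slope), "positive" if slope > 0 else "negative")
            )
    return pd.DataFrame(
        records, columns=["protein_a", "protein_b", "group", "slope", "sign"]
    )
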