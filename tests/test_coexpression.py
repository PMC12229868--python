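"""Pairwise interaction regressions and the selection rules.

The oracle here is a hand-rolled normal-equations solve (X'X)^-1 X'y with
textbook standard errors, written independently of the implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from synovnet.coexpression import (EdgeSelectionRule, all_pairs, fit_pair,
                                   select_enrichment_proteins,
                                   select_network_edges)

# ---------------------------------------------------------------------------
# independent oracle


def normal_equations_oracle(x, y, g):
    """Brute-force OLS for y = b0 + b1 x + b2 g + b3 xg with t CIs."""
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n = y.size
    s2 = resid @ resid / (n - 4)
    cov = s2 * XtX_inv
    tc = t_dist.ppf(0.975, n - 4)
    out = {
        "slope_control": beta[1],
        "se_control": np.sqrt(cov[1, 1]),
        "slope_case": beta[1] + beta[3],
        "se_case": np.sqrt(cov[1, 1] + cov[3, 3] + 2 * cov[1, 3]),
        "slope_diff": beta[3],
        "se_diff": np.sqrt(cov[3, 3]),
    }
    for stem in ("control", "case", "diff"):
        out[f"ci_low_{stem}"] = out[f"slope_{stem}"] - tc * out[f"se_{stem}"]
        out[f"ci_high_{stem}"] = out[f"slope_{stem}"] + tc * out[f"se_{stem}"]
    return out


FIELDS = [
    "slope_control", "se_control", "ci_low_control", "ci_high_control",
    "slope_case", "se_case", "ci_low_case", "ci_high_case",
    "slope_diff", "se_diff", "ci_low_diff", "ci_high_diff",
]


def test_fit_pair_matches_normal_equations_on_random_fixtures():
    """100 random 24-sample fixtures: slopes, SEs and CIs to 1e-10."""
    rng = np.random.default_rng(123)
    g = np.array([0.0] * 12 + [1.0] * 12)
    for _ in range(100):
        x = rng.normal(size=24)
        y = 0.5 * x + rng.normal(size=24) + 0.8 * g * x
        want = normal_equations_oracle(x, y, g)
        pm = fit_pair(x, y, g)
        got = {
            "slope_control": pm.slope_control, "se_control": pm.se_control,
            "ci_low_control": pm.ci_control[0], "ci_high_control": pm.ci_control[1],
            "slope_case": pm.slope_case, "se_case": pm.se_case,
            "ci_low_case": pm.ci_case[0], "ci_high_case": pm.ci_case[1],
            "slope_diff": pm.slope_diff, "se_diff": pm.se_diff,
            "ci_low_diff": pm.ci_diff[0], "ci_high_diff": pm.ci_diff[1],
        }
        for key in FIELDS:
            assert got[key] == pytest.approx(want[key], abs=1e-10), key


def test_all_pairs_matches_fit_pair_with_missing_cells():
    rng = np.random.default_rng(5)
    mat = rng.normal(size=(24, 5))
    mat[rng.random(mat.shape) < 0.1] = np.nan
    groups = np.array(["control"] * 12 + ["OA"] * 12)
    df = pd.DataFrame(mat, columns=[f"P{i}" for i in range(5)])
    pairs = all_pairs(df, groups)
    assert len(pairs) == 5 * 4
    for row in pairs.itertuples():
        pm = fit_pair(df[row.predictor], df[row.outcome], groups)
        if not pm.estimable:
            assert not row.estimable
            continue
        assert row.slope_control == pytest.approx(pm.slope_control, abs=1e-10)
        assert row.se_diff == pytest.approx(pm.se_diff, abs=1e-10)
        assert row.ci_low_case == pytest.approx(pm.ci_case[0], abs=1e-10)
        assert row.n_used == pm.n_used


def test_noise_free_opposite_slopes():
    """y = x in controls, y = -x in cases gives slopes (1, -1), diff -2."""
    x = np.concatenate([np.linspace(-1, 1, 6)] * 2)
    g = np.array([0.0] * 6 + [1.0] * 6)
    y = np.where(g == 0, x, -x)
    pm = fit_pair(x, y, g)
    assert pm.slope_control == pytest.approx(1.0, abs=1e-12)
    assert pm.slope_case == pytest.approx(-1.0, abs=1e-12)
    assert pm.slope_diff == pytest.approx(-2.0, abs=1e-12)


def test_single_group_slope_equals_pearson_r_on_standardized_data():
    """On standardized data within one group the OLS slope is symmetric in
    (x, y) and equals the Pearson correlation."""
    rng = np.random.default_rng(8)
    x = rng.normal(size=40)
    y = 0.6 * x + rng.normal(size=40)
    xs = (x - x.mean()) / x.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    r = np.corrcoef(xs, ys)[0, 1]
    bxy = np.linalg.lstsq(np.column_stack([np.ones(40), xs]), ys, rcond=None)[0][1]
    byx = np.linalg.lstsq(np.column_stack([np.ones(40), ys]), xs, rcond=None)[0][1]
    assert bxy == pytest.approx(r, abs=1e-10)
    assert byx == pytest.approx(r, abs=1e-10)


def test_group_relabeling_flips_diff_sign_only():
    rng = np.random.default_rng(3)
    x = rng.normal(size=24)
    y = rng.normal(size=24) + 0.9 * x
    g = np.array([0.0] * 12 + [1.0] * 12)
    pm = fit_pair(x, y, g)
    pm_swapped = fit_pair(x, y, 1.0 - g)
    assert pm_swapped.slope_diff == pytest.approx(-pm.slope_diff, abs=1e-10)
    assert pm_swapped.se_diff == pytest.approx(pm.se_diff, abs=1e-10)
    assert pm_swapped.slope_control == pytest.approx(pm.slope_case, abs=1e-10)


def test_constant_predictor_within_group_flagged():
    x = np.array([1.0] * 12 + list(np.linspace(0, 1, 12)))
    g = np.array([0.0] * 12 + [1.0] * 12)
    y = np.arange(24.0)
    pm = fit_pair(x, y, g)
    assert not pm.estimable


def test_all_pairs_requires_two_groups_and_two_proteins():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(8, 3)),
                      columns=list("abc"))
    with pytest.raises(ValueError, match="both groups"):
        all_pairs(df, ["control"] * 8)
    with pytest.raises(ValueError, match="2 proteins"):
        all_pairs(df[["a"]], ["control"] * 4 + ["OA"] * 4)


def _pair_row(outcome, predictor, sc, st_, diff, se=0.1, n=24, estimable=True):
    tc = t_dist.ppf(0.975, n - 4)
    row = {
        "outcome": outcome, "predictor": predictor,
        "slope_control": sc, "se_control": se,
        "ci_low_control": sc - tc * se, "ci_high_control": sc + tc * se,
        "slope_case": st_, "se_case": se,
        "ci_low_case": st_ - tc * se, "ci_high_case": st_ + tc * se,
        "slope_diff": diff, "se_diff": se,
        "ci_low_diff": diff - tc * se, "ci_high_diff": diff + tc * se,
        "n_used": n, "estimable": estimable,
    }
    return row


class TestSelectionRules:
    def test_lost_control_coexpression_qualifies_for_enrichment(self):
        # strong negative control slope lost in cases
        pairs = pd.DataFrame([_pair_row("ACAN", "SELP", -1.02, 0.0, 1.02)])
        ctrl_set, case_set, qual = select_enrichment_proteins(pairs)
        assert ctrl_set == {"ACAN", "SELP"}
        assert case_set == set()
        assert len(qual) == 1

    def test_magnitude_rule_blocks_small_differences(self):
        pairs = pd.DataFrame([_pair_row("a", "b", 0.8, 0.0, 0.8)])
        ctrl_set, case_set, qual = select_enrichment_proteins(pairs)
        assert not ctrl_set and not case_set and qual.empty

    def test_ci_rule_blocks_noisy_differences(self):
        pairs = pd.DataFrame([_pair_row("a", "b", 1.4, 0.0, 1.4, se=1.0)])
        _, _, qual = select_enrichment_proteins(pairs)
        assert qual.empty

    def test_control_only_edge_signed_negative(self):
        pairs = pd.DataFrame([_pair_row("TMSB10", "SIRPB1", -1.61, 0.0, 1.61)])
        edges = select_network_edges(pairs)
        assert len(edges) == 1
        edge = edges.iloc[0]
        assert edge["group"] == "control"
        assert edge["sign"] == "negative"
        assert {edge["protein_a"], edge["protein_b"]} == {"TMSB10", "SIRPB1"}

    def test_qualifying_diff_without_big_slope_gives_no_edge(self):
        # diff = 1.4 qualifies but neither group's slope reaches |1|
        pairs = pd.DataFrame([_pair_row("a", "b", -0.5, 0.9, 1.4)])
        edges = select_network_edges(pairs)
        assert edges.empty
        # ... while the pair still feeds the enrichment protein sets
        _, case_set, _ = select_enrichment_proteins(pairs)
        assert case_set == {"a", "b"}

    def test_all_zero_slopes_give_empty_networks(self):
        pairs = pd.DataFrame([_pair_row("a", "b", 0.0, 0.0, 0.0)])
        assert select_network_edges(pairs).empty

    def test_direction_conflict_resolved_by_larger_diff(self):
        rows = [
            _pair_row("a", "b", -1.5, 0.0, 1.5),
            _pair_row("b", "a", -1.2, 0.0, 1.2),
        ]
        edges = select_network_edges(pd.DataFrame(rows))
        assert len(edges) == 1
        assert edges.iloc[0]["slope"] == pytest.approx(-1.5)

    def test_every_pair_classified_exactly_once(self):
        rng = np.random.default_rng(11)
        mat = rng.normal(size=(24, 6))
        groups = np.array(["control"] * 12 + ["OA"] * 12)
        df = pd.DataFrame(mat, columns=[f"P{i}" for i in range(6)])
        pairs = all_pairs(df, groups)
        unestimable = ~pairs["estimable"].astype(bool)
        qualifying = pairs["estimable"].astype(bool) & (
            (pairs["slope_diff"].abs() >= 1.0)
            & ((pairs["ci_low_diff"] > 0) | (pairs["ci_high_diff"] < 0)))
        non_qualifying = pairs["estimable"].astype(bool) & ~qualifying
        counts = (unestimable.astype(int) + qualifying.astype(int)
                  + non_qualifying.astype(int))
        assert (counts == 1).all()

    def test_rule_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            EdgeSelectionRule(min_abs_slope=0.0)


def test_scale_274_proteins_under_a_minute():
    import time

    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(24, 274)),
                      columns=[f"P{i:03d}" for i in range(274)])
    groups = np.array(["control"] * 13 + ["OA"] * 11)
    t0 = time.time()
    pairs = all_pairs(df, groups)
    assert time.time() - t0 < 60
    assert len(pairs) == 274 * 273
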