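import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from csfnet.exceptions import ParameterError
from csfnet.matrix import GeneSetCollection
from csfnet.stats import (anova_tukey, cross_network_overlap, dep_analysis,
                          eigenprotein_group_test, enrichment_table,
                          fisher_enrichment, group_label, module_trait_corr)

GROUPS4 = ("CT.Cau", "CT.AA", "AD.Cau", "AD.AA")


def _four_group_data(effects=(0.0, 0.0, 0.0, 0.0), n=12, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    values, groups = [], []
    for g, e in zip(GROUPS4, effects):
        values.append(e + sd * rng.normal(size=n))
        groups += [g] * n
    return np.concatenate(values), np.array(groups)


def _traits_frame(n_per_group=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for dx in ("CT", "AD"):
        for race in ("Cau", "AA"):
            for _ in range(n_per_group):
                rows.append({"sample_id": f"S{i:03d}", "diagnosis": dx,
                             "race": race,
                             "age": float(rng.normal(68, 8))})
                i += 1
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# anova_tukey
# ---------------------------------------------------------------------------

def test_anova_tukey_matches_scipy_tukey_hsd():
    values, groups = _four_group_data(effects=(0, 0.5, 1.0, 0.2), seed=1)
    # unequal group sizes exercise the Tukey-Kramer form
    keep = np.ones(len(values), dtype=bool)
    keep[:3] = False
    values, groups = values[keep], groups[keep]
    res = anova_tukey(values, groups)
    samples = [values[groups == g] for g in GROUPS4]
    ref = sps.tukey_hsd(*samples)
    for (i, a), (j, b) in itertools.combinations(enumerate(GROUPS4), 2):
        assert res.p[(a, b)] == pytest.approx(ref.pvalue[i, j], abs=1e-6)


def test_anova_tukey_k2_equals_pooled_t_test():
    rng = np.random.default_rng(2)
    values = np.concatenate([rng.normal(size=10), 0.8 + rng.normal(size=14)])
    groups = np.array(["CT.Cau"] * 10 + ["AD.Cau"] * 14)
    res = anova_tukey(values, groups)
    t = sps.ttest_ind(values[:10], values[10:], equal_var=True)
    assert res.p[("CT.Cau", "AD.Cau")] == pytest.approx(t.pvalue, abs=1e-10)


def test_anova_tukey_handles_missing_and_empty_group():
    values, groups = _four_group_data(seed=3)
    values[groups == "AD.AA"] = np.nan       # one group entirely missing
    values[0] = np.nan                        # plus a stray NaN
    res = anova_tukey(values, groups)
    assert res.k == 3
    assert np.isnan(res.p[("CT.Cau", "AD.AA")])
    assert np.isfinite(res.p[("CT.Cau", "AD.Cau")])
    assert res.ns["AD.AA"] == 0 and res.ns["CT.Cau"] == 11


def test_anova_tukey_validation():
    with pytest.raises(ParameterError, match="same length"):
        anova_tukey([1.0, 2.0], ["a"])
    with pytest.raises(ParameterError, match=">= 2 groups"):
        anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


def test_anova_tukey_zero_diff_and_zero_se():
    values = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    groups = np.array(["CT.Cau"] * 3 + ["AD.Cau"] * 3)
    res = anova_tukey(values, groups)
    assert res.p[("CT.Cau", "AD.Cau")] == 1.0   # identical means
    values2 = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    res2 = anova_tukey(values2, groups)
    assert res2.p[("CT.Cau", "AD.Cau")] == 0.0  # zero within-group variance


# ---------------------------------------------------------------------------
# dep_analysis
# ---------------------------------------------------------------------------

def _dep_inputs(seed=0):
    """40 proteins: 10 up in AD (both races), 10 down in AD with a stronger
    AA effect, 20 null; returns (frame, traits, masks)."""
    traits = _traits_frame(n_per_group=20, seed=seed)
    rng = np.random.default_rng(seed + 1)
    dx = (traits["diagnosis"] == "AD").to_numpy(float)
    race = (traits["race"] == "AA").to_numpy(float)
    n = len(traits)
    rows = []
    for _ in range(10):                      # shared, up in AD
        rows.append(1.5 * dx + 0.3 * rng.normal(size=n))
    for _ in range(10):                      # down in AD, stronger in AA
        rows.append(-1.2 * dx - 0.8 * dx * race + 0.3 * rng.normal(size=n))
    for _ in range(20):                      # null
        rows.append(0.3 * rng.normal(size=n))
    df = pd.DataFrame(rows, index=[f"G{i}|Q{i}" for i in range(40)],
                      columns=traits.index)
    return df, traits


def test_dep_analysis_recovers_planted_effects():
    df, traits = _dep_inputs()
    res = dep_analysis(df, traits)
    t = res.table
    planted = np.zeros(40, dtype=bool)
    planted[:20] = True
    # every planted protein is a DEP in both races; nulls mostly are not
    assert t["dep_cau"].to_numpy()[planted].all()
    assert t["dep_aa"].to_numpy()[planted].all()
    assert t["dep_cau"].to_numpy()[~planted].sum() <= 2
    # directions match the planted signs
    assert (t["direction_cau"].to_numpy()[:10] == "up").all()
    assert (t["direction_aa"].to_numpy()[10:20] == "down").all()
    # venn bookkeeping is consistent with the flags
    assert res.venn["shared"] + res.venn["unique_cau"] == int(t["dep_cau"].sum())
    assert res.venn["shared"] + res.venn["unique_aa"] == int(t["dep_aa"].sum())
    # fold changes concordant across races over the DEP union
    assert res.concordance > 0.9


def test_dep_analysis_column_order_invariant():
    df, traits = _dep_inputs(seed=5)
    res1 = dep_analysis(df, traits)
    perm = np.random.default_rng(6).permutation(df.shape[1])
    res2 = dep_analysis(df.iloc[:, perm], traits)
    pd.testing.assert_frame_equal(res1.table, res2.table)
    assert res1.venn == res2.venn


def test_dep_analysis_matches_scalar_anova():
    df, traits = _dep_inputs(seed=7)
    res = dep_analysis(df, traits)
    glab = group_label(traits).to_numpy()
    for i in (0, 15, 30):
        scalar = anova_tukey(df.iloc[i].to_numpy(), glab)
        assert res.table["p_cau"].iloc[i] == pytest.approx(
            scalar.p[("CT.Cau", "AD.Cau")], abs=1e-10)
        assert res.table["p_aa"].iloc[i] == pytest.approx(
            scalar.p[("CT.AA", "AD.AA")], abs=1e-10)


def test_dep_analysis_validation():
    df, traits = _dep_inputs()
    with pytest.raises(ParameterError, match="alpha"):
        dep_analysis(df, traits, alpha=1.5)
    with pytest.raises(ParameterError, match="shared"):
        dep_analysis(df.rename(columns=lambda c: c + "_x"), traits)


# ---------------------------------------------------------------------------
# module_trait_corr
# ---------------------------------------------------------------------------

def test_module_trait_corr_planted_signs(tmt, cohort):
    _, truth = tmt
    eig = truth.eigenprotein_latents.T     # samples x modules
    res = module_trait_corr(eig, cohort)
    # M1 was planted with negative diagnosis and race coefficients
    assert res.r.loc["M1", "diagnosis"] < 0
    assert res.r.loc["M1", "race"] < 0
    assert res.p.loc["M1", "diagnosis"] < 1e-6
    # M3 carries a positive diagnosis effect and no race effect
    assert res.r.loc["M3", "diagnosis"] > 0
    assert abs(res.r.loc["M3", "race"]) < abs(res.r.loc["M3", "diagnosis"])
    assert res.coding    # the 0/1 coding is reported


def test_module_trait_corr_null_is_small(cohort):
    rng = np.random.default_rng(8)
    eig = pd.DataFrame(rng.normal(size=(len(cohort), 4)), index=cohort.index,
                       columns=[f"M{i}" for i in range(1, 5)])
    res = module_trait_corr(eig, cohort)
    assert res.r.abs().to_numpy(dtype=float).max() < 0.2


def test_module_trait_corr_constant_trait_warns(cohort):
    rng = np.random.default_rng(9)
    eig = pd.DataFrame(rng.normal(size=(len(cohort), 2)), index=cohort.index,
                       columns=["M1", "M2"])
    tf = pd.DataFrame({"flat": 1.0, "ok": rng.normal(size=len(cohort))},
                      index=cohort.index)
    with pytest.warns(UserWarning, match="constant"):
        res = module_trait_corr(eig, tf)
    assert res.r["flat"].isna().all()
    assert res.r["ok"].notna().all()


def test_module_trait_corr_too_few_samples(cohort):
    eig = pd.DataFrame(np.zeros((3, 1)), index=cohort.index[:3], columns=["M1"])
    with pytest.raises(ParameterError, match="fewer than 4"):
        module_trait_corr(eig, cohort)


# ---------------------------------------------------------------------------
# eigenprotein_group_test
# ---------------------------------------------------------------------------

def _exact_mwu_two_sided(xa, xb):
    """Two-sided exact Mann-Whitney p by full permutation enumeration."""
    pooled = np.concatenate([xa, xb])
    na = len(xa)
    idx = range(len(pooled))
    u_obs = sum(1.0 for a in xa for b in xb if a > b)
    us = []
    for comb in itertools.combinations(idx, na):
        ga = pooled[list(comb)]
        gb = pooled[[i for i in idx if i not in comb]]
        us.append(sum(1.0 for a in ga for b in gb if a > b))
    us = np.array(us)
    p = 2.0 * min((us >= u_obs).mean(), (us <= u_obs).mean())
    return min(1.0, p)


def test_eigenprotein_group_test_exact_permutation_oracle():
    rng = np.random.default_rng(10)
    traits = _traits_frame(n_per_group=5, seed=10)
    eig = pd.DataFrame({"M1": rng.normal(size=len(traits))}, index=traits.index)
    out = eigenprotein_group_test(eig, traits)
    glab = group_label(traits)
    for a, b in [("CT.Cau", "AD.Cau"), ("CT.AA", "AD.AA")]:
        xa = eig["M1"][glab == a].to_numpy()
        xb = eig["M1"][glab == b].to_numpy()
        expect = min(1.0, 6.0 * _exact_mwu_two_sided(xa, xb))
        assert out.loc["M1", f"{a}_vs_{b}"] == pytest.approx(expect, abs=1e-12)


def test_eigenprotein_group_test_small_group_missing(cohort):
    traits = _traits_frame(n_per_group=6)
    traits = traits[~((traits["diagnosis"] == "AD") & (traits["race"] == "AA"))
                    | (traits.index == traits.index[-1])]
    rng = np.random.default_rng(11)
    eig = pd.DataFrame({"M1": rng.normal(size=len(traits))}, index=traits.index)
    out = eigenprotein_group_test(eig, traits)
    assert np.isnan(out.loc["M1", "CT.Cau_vs_AD.AA"])   # 1 sample in AD.AA
    assert np.isfinite(out.loc["M1", "CT.Cau_vs_AD.Cau"])


def test_eigenprotein_group_test_detects_planted_shift():
    traits = _traits_frame(n_per_group=25, seed=12)
    rng = np.random.default_rng(12)
    x = rng.normal(size=len(traits))
    x[(group_label(traits) == "AD.AA").to_numpy()] += 3.0
    eig = pd.DataFrame({"M1": x}, index=traits.index)
    out = eigenprotein_group_test(eig, traits)
    assert out.loc["M1", "CT.AA_vs_AD.AA"] < 1e-6
    assert out.loc["M1", "CT.Cau_vs_CT.AA"] > 0.05


# ---------------------------------------------------------------------------
# fisher_enrichment / enrichment_table / cross_network_overlap
# ---------------------------------------------------------------------------

def _exact_hypergeom_upper(overlap, N, K, n):
    """P(X >= overlap) by exact rational summation."""
    total = Fraction(0)
    for i in range(overlap, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i),
                          math.comb(N, n))
    return float(total)


@given(st.integers(10, 60), st.integers(1, 9), st.integers(1, 9),
       st.integers(0, 9))
def test_fisher_enrichment_exhaustive_oracle(N, K, n, seed):
    rng = np.random.default_rng(seed)
    background = [f"g{i}" for i in range(N)]
    gene_set = list(rng.choice(background, size=min(K, N), replace=False))
    members = list(rng.choice(background, size=min(n, N), replace=False))
    res = fisher_enrichment(members, gene_set, background)
    expect = _exact_hypergeom_upper(res["overlap"], N, len(gene_set),
                                    len(members))
    assert res["p"] == pytest.approx(expect, abs=1e-12)
    assert 0.0 <= res["p"] <= 1.0


def test_fisher_enrichment_known_table():
    background = [f"g{i}" for i in range(20)]
    members = background[:5]
    gene_set = background[:4] + background[10:12]     # overlap 4 of 6
    res = fisher_enrichment(members, gene_set, background)
    assert res["overlap"] == 4 and res["set_size"] == 6
    assert res["module_size"] == 5 and res["background_size"] == 20
    assert res["p"] == pytest.approx(_exact_hypergeom_upper(4, 20, 6, 5),
                                     abs=1e-12)
    assert res["odds_ratio"] > 1.0


def test_fisher_enrichment_validation():
    with pytest.raises(ParameterError, match="empty background"):
        fisher_enrichment(["a"], ["a"], [])
    with pytest.raises(ParameterError, match="subset"):
        fisher_enrichment(["x"], ["a"], ["a", "b"])


def _bh_oracle(p):
    """Benjamini-Hochberg adjusted p by the textbook step-up formula."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_enrichment_table_bh_and_symbols():
    background = [f"G{i}|Q{i}" for i in range(30)]
    modules = {"M1": background[:8], "M2": background[8:14]}
    coll = GeneSetCollection(sets={
        "setA": {f"G{i}" for i in range(6)},          # overlaps M1
        "setB": {f"G{i}" for i in range(20, 26)},     # overlaps neither much
    })
    table = enrichment_table(modules, coll, background)
    assert len(table) == 4
    top = table.sort_values("p").iloc[0]
    assert (top["module"], top["gene_set"]) == ("M1", "setA")
    assert np.allclose(table["q"].to_numpy(),
                       _bh_oracle(table["p"].to_numpy()), atol=1e-12)
    assert (table["q"] >= table["p"] - 1e-15).all()


def test_enrichment_table_empty_collection():
    coll = GeneSetCollection(sets={})
    table = enrichment_table({"M1": ["G1|Q1"]}, coll, ["G1|Q1", "G2|Q2"])
    assert len(table) == 0


def test_cross_network_overlap_identity_and_shuffle():
    rng = np.random.default_rng(13)
    genes = [f"G{i}" for i in range(200)]
    modules = pd.Series(np.repeat(["A", "B", "C", "D"], 50), index=genes)
    same = cross_network_overlap(modules, modules.rename("brain"))
    for m in "ABCD":
        assert same["q"].loc[m, m] < 1e-10
        off = [b for b in "ABCD" if b != m]
        assert (same["p"].loc[m, off] > 0.5).all()
    shuffled = pd.Series(rng.permutation(modules.to_numpy()), index=genes)
    rand = cross_network_overlap(modules, shuffled)
    assert rand["q"].to_numpy(dtype=float).min() > 0.05


def test_cross_network_overlap_validation():
    a = pd.Series({"G1": "A"})
    b = pd.Series({"G2": "B"})
    with pytest.raises(ParameterError, match="shared"):
        cross_network_overlap(a, b)
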