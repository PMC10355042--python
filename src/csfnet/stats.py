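"""Group statistics, module-trait correlation and enrichment tests.

Differential expression across the four diagnosis x race groups uses
one-way ANOVA with Tukey's studentized-range adjustment; module
eigenproteins are related to traits by biweight midcorrelation and to
groups by pairwise rank-sum tests; gene-set and cross-network overlap use
the one-tailed Fisher exact (hypergeometric) test with Benjamini-Hochberg
adjustment within each collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import robust
from .exceptions import ParameterError
from .matrix import GeneSetCollection, gene_symbol
from .tukey import studentized_range_sf

__all__ = [
    "GROUP_LABELS",
    "TukeyResult",
    "anova_tukey",
    "DEPResult",
    "dep_analysis",
    "ModuleTraitCorr",
    "module_trait_corr",
    "eigenprotein_group_test",
    "fisher_enrichment",
    "enrichment_table",
    "cross_network_overlap",
]

# canonical four-group order: diagnosis x race
GROUP_LABELS = ("CT.Cau", "CT.AA", "AD.Cau", "AD.AA")
_PAIRS = [(a, b) for i, a in enumerate(GROUP_LABELS)
          for b in GROUP_LABELS[i + 1:]]


def group_label(traits: pd.DataFrame) -> pd.Series:
    """``diagnosis.race`` label per sample (e.g. ``AD.AA``)."""
    return traits["diagnosis"].astype(str) + "." + traits["race"].astype(str)


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

@dataclass
class TukeyResult:
    means: dict                  # group -> mean (NaN if group empty)
    ns: dict                     # group -> non-missing count
    mse: float
    df: float
    k: int                       # number of groups with data
    p: dict                      # (group_i, group_j) -> adjusted p (NaN if either empty)


def anova_tukey(values, groups) -> TukeyResult:
    """All six pairwise Tukey-adjusted p-values over a 4-level factor.

    ``values`` are per-sample measurements (NaN = missing), ``groups`` the
    matching labels.  Pooled within-group MSE; the statistic
    ``|mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))`` is referred to
    the studentized-range distribution with k = number of non-empty groups
    and df = N - k.  A group with no data yields missing p for its
    comparisons; the rest are computed.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ParameterError("values and groups must have the same length")
    levels = [g for g in GROUP_LABELS if g in set(groups.tolist())]
    if not levels:
        levels = sorted(set(groups.tolist()))
    stats = {}
    for g in levels:
        x = values[groups == g]
        x = x[~np.isnan(x)]
        stats[g] = (len(x), float(np.mean(x)) if len(x) else np.nan,
                    float(np.sum((x - np.mean(x)) ** 2)) if len(x) else 0.0)
    present = [g for g in levels if stats[g][0] > 0]
    if sum(1 for g in present if stats[g][0] >= 2) < 2:
        raise ParameterError("need >= 2 groups with >= 2 non-missing values")
    k = len(present)
    N = sum(stats[g][0] for g in present)
    df = N - k
    mse = sum(stats[g][2] for g in present) / df if df > 0 else np.nan
    means = {g: stats[g][1] for g in levels}
    ns = {g: stats[g][0] for g in levels}
    pvals = {}
    for a, b in [(x, y) for i, x in enumerate(levels) for y in levels[i + 1:]]:
        na, nb = ns[a], ns[b]
        if na == 0 or nb == 0:
            pvals[(a, b)] = np.nan
            continue
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
        pvals[(a, b)] = _tukey_p_scalar(diff, se, k, df)
    return TukeyResult(means=means, ns=ns, mse=float(mse), df=float(df),
                       k=k, p=pvals)


def _tukey_p_scalar(diff: float, se: float, k: int, df: float) -> float:
    if diff == 0:
        return 1.0
    if se == 0:
        return 0.0
    return float(studentized_range_sf(abs(diff) / se, k, df))


# ---------------------------------------------------------------------------
# Differential expression over the matrix
# ---------------------------------------------------------------------------

@dataclass
class DEPResult:
    table: pd.DataFrame          # per-protein means, FCs, p-values, flags
    venn: dict                   # unique_cau / shared / unique_aa counts
    concordance: float           # bicor of the two races' log2 FCs over DEP union
    alpha: float


def dep_analysis(m, traits: pd.DataFrame, alpha: float = 0.05) -> DEPResult:
    """Per-protein four-group ANOVA/Tukey differential expression.

    A protein is a DEP within a race when the Tukey-adjusted p of that
    race's CT-vs-AD contrast is below ``alpha``.  Proteins failing the
    ANOVA preconditions (fewer than two groups with two values) get
    missing rows.  Volcano coordinates are the per-race log2 fold change
    (AD - CT) against -log10 of the same adjusted p.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0,1)")
    df = m.sample_frame() if hasattr(m, "sample_frame") else m
    common = [s for s in df.columns if s in traits.index]
    if not common:
        raise ParameterError("no samples shared between matrix and traits")
    df = df[common]
    glab = group_label(traits.loc[common]).to_numpy()
    Y = df.to_numpy(dtype=float)
    P = Y.shape[0]

    ns, means, ssds = {}, {}, {}
    for g in GROUP_LABELS:
        sub = Y[:, glab == g]
        obs = ~np.isnan(sub)
        n = obs.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mu = np.nanmean(sub, axis=1)
            ssd = np.nansum((sub - mu[:, None]) ** 2, axis=1)
        mu = np.where(n > 0, mu, np.nan)
        ns[g], means[g], ssds[g] = n, mu, ssd

    n_mat = np.column_stack([ns[g] for g in GROUP_LABELS])
    k_arr = (n_mat > 0).sum(axis=1)
    N_arr = n_mat.sum(axis=1)
    df_arr = N_arr - k_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = sum(ssds[g] for g in GROUP_LABELS) / df_arr
    valid = (n_mat >= 2).sum(axis=1) >= 2
    valid &= df_arr > 0

    contrasts = {"cau": ("CT.Cau", "AD.Cau"), "aa": ("CT.AA", "AD.AA")}
    out = {}
    for g in GROUP_LABELS:
        out[f"mean_{g.replace('.', '_')}"] = means[g]
    pcols = {}
    for race, (ct, ad) in contrasts.items():
        fc = means[ad] - means[ct]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[ct] + 1.0 / ns[ad]))
            q = np.abs(fc) / se
        p = np.full(P, np.nan)
        ok = valid & (ns[ct] > 0) & (ns[ad] > 0)
        p[ok & (fc == 0)] = 1.0
        p[ok & (fc != 0) & (se == 0)] = 0.0
        todo = ok & (fc != 0) & (se > 0) & np.isfinite(q)
        for kk, dd in {(int(a), int(b))
                       for a, b in zip(k_arr[todo], df_arr[todo])}:
            sel = todo & (k_arr == kk) & (df_arr == dd)
            p[sel] = studentized_range_sf(q[sel], kk, float(dd))
        out[f"log2fc_{race}"] = fc
        out[f"p_{race}"] = p
        with np.errstate(divide="ignore"):
            out[f"neglog10p_{race}"] = -np.log10(p)
        out[f"dep_{race}"] = p < alpha
        out[f"direction_{race}"] = np.where(
            np.isnan(fc), "", np.where(fc > 0, "up", "down"))
        pcols[race] = p

    table = pd.DataFrame(out, index=df.index)
    dep_c = table["dep_cau"].to_numpy(bool)
    dep_a = table["dep_aa"].to_numpy(bool)
    venn = {
        "unique_cau": int((dep_c & ~dep_a).sum()),
        "shared": int((dep_c & dep_a).sum()),
        "unique_aa": int((~dep_c & dep_a).sum()),
    }
    union = dep_c | dep_a
    if union.sum() >= 4:
        conc = float(robust.bicor(table["log2fc_cau"].to_numpy()[union],
                                  table["log2fc_aa"].to_numpy()[union]))
    else:
        conc = np.nan
    return DEPResult(table=table, venn=venn, concordance=conc, alpha=alpha)


# ---------------------------------------------------------------------------
# Module-trait statistics
# ---------------------------------------------------------------------------

@dataclass
class ModuleTraitCorr:
    r: pd.DataFrame              # modules x traits bicor
    p: pd.DataFrame              # matching two-sided Student-t p
    coding: dict = field(default_factory=dict)


_TRAIT_CODING = {
    "diagnosis": "CT=0, AD=1",
    "race": "Cau=0, AA=1",
    "apoe4": "noncarrier=0, carrier=1",
}


def trait_frame(traits: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait matrix for module-trait correlation.

    MoCA, CSF analytes, the tTau/Abeta42 ratio (excluding samples whose
    Abeta42 hit assay saturation) and 0/1 codes for diagnosis, APOE e4
    carriage and race.
    """
    t = pd.DataFrame(index=traits.index)
    t["moca"] = pd.to_numeric(traits["moca"])
    t["abeta42"] = pd.to_numeric(traits["abeta42"])
    t["ttau"] = pd.to_numeric(traits["ttau"])
    t["ptau181"] = pd.to_numeric(traits["ptau181"])
    ratio = t["ttau"] / t["abeta42"]
    if "abeta42_saturated" in traits.columns:
        ratio = ratio.where(~traits["abeta42_saturated"].astype(bool))
    t["ttau_abeta42"] = ratio
    t["diagnosis"] = (traits["diagnosis"] == "AD").astype(float)
    t["apoe4"] = traits["apoe4"].astype(float)
    t["race"] = (traits["race"] == "AA").astype(float)
    return t


def module_trait_corr(eigenproteins: pd.DataFrame,
                      traits: pd.DataFrame) -> ModuleTraitCorr:
    """bicor of each module eigenprotein with each clinical trait.

    p is the two-sided Student-t probability of the bicor value with
    n - 2 degrees of freedom over the pairwise non-missing samples.
    A constant trait gives missing correlation with a warning.
    """
    common = eigenproteins.index.intersection(traits.index)
    if len(common) < 4:
        raise ParameterError("fewer than 4 samples shared with traits")
    eig = eigenproteins.loc[common]
    # accept either the clinical traits table or an already-numeric frame
    if "diagnosis" in traits.columns and traits["diagnosis"].dtype == object:
        tf = trait_frame(traits.loc[common])
    else:
        tf = traits.loc[common].astype(float)
    r = pd.DataFrame(index=eig.columns, columns=tf.columns, dtype=float)
    p = pd.DataFrame(index=eig.columns, columns=tf.columns, dtype=float)
    from scipy.stats import t as t_dist
    for trait in tf.columns:
        y = tf[trait].to_numpy(dtype=float)
        obs_y = ~np.isnan(y)
        if np.nanstd(y) == 0:
            warnings.warn(f"trait {trait!r} is constant; correlation undefined",
                          stacklevel=2)
            continue
        for mod in eig.columns:
            x = eig[mod].to_numpy(dtype=float)
            obs = obs_y & ~np.isnan(x)
            n = int(obs.sum())
            if n < 4:
                continue
            rv = robust.bicor(x[obs], y[obs])
            if np.isnan(rv):
                continue
            r.loc[mod, trait] = rv
            if abs(rv) >= 1.0:
                p.loc[mod, trait] = 0.0
            else:
                tstat = rv * np.sqrt((n - 2) / (1.0 - rv * rv))
                p.loc[mod, trait] = 2.0 * t_dist.sf(abs(tstat), n - 2)
    return ModuleTraitCorr(r=r, p=p, coding=dict(_TRAIT_CODING))


def eigenprotein_group_test(eigenproteins: pd.DataFrame,
                            traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of eigenproteins across the 4 groups.

    Returns a module x pair table of two-sided Mann-Whitney p-values
    Bonferroni-multiplied by the six comparisons and capped at 1.  Pairs
    where either group has fewer than two samples are missing.
    """
    common = eigenproteins.index.intersection(traits.index)
    eig = eigenproteins.loc[common]
    glab = group_label(traits.loc[common])
    cols = [f"{a}_vs_{b}" for a, b in _PAIRS]
    out = pd.DataFrame(index=eig.columns, columns=cols, dtype=float)
    for mod in eig.columns:
        x = eig[mod]
        for (a, b), col in zip(_PAIRS, cols):
            xa = x[glab == a].dropna().to_numpy()
            xb = x[glab == b].dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            res = mannwhitneyu(xa, xb, alternative="two-sided")
            out.loc[mod, col] = min(1.0, float(res.pvalue) * len(_PAIRS))
    return out


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(members, gene_set, background) -> dict:
    """One-tailed (greater) Fisher exact test of a module against a gene set.

    ``members`` must be a subset of ``background``; the gene set is
    intersected with the background before testing.  p is the
    hypergeometric upper tail P(X >= overlap); the odds ratio uses the
    Haldane 0.5 correction when any 2x2 cell is zero.
    """
    background = set(background)
    if not background:
        raise ParameterError("empty background")
    members = set(members)
    if not members <= background:
        raise ParameterError("module members must be a subset of the background")
    in_set = set(gene_set) & background
    overlap = len(members & in_set)
    N = len(background)
    K = len(in_set)
    n = len(members)
    p = float(hypergeom.sf(overlap - 1, N, K, n))
    a = overlap
    b = n - overlap
    c = K - overlap
    d = N - K - b
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return {
        "overlap": overlap, "module_size": n, "set_size": K,
        "background_size": N, "odds_ratio": (a * d) / (b * c), "p": p,
    }


def enrichment_table(module_members: dict, collection: GeneSetCollection,
                     background, use_symbols: bool = True) -> pd.DataFrame:
    """Fisher enrichment of every module against every set in a collection.

    Protein identifiers are reduced to gene symbols before matching when
    ``use_symbols`` (the default, matching GMT conventions).  The
    Benjamini-Hochberg q is computed across all (module, set) pairs of the
    collection.
    """
    background = set(background)
    if use_symbols:
        background = {gene_symbol(s) for s in background}
    rows = []
    for mod, members in module_members.items():
        mem = {gene_symbol(s) for s in members} if use_symbols else set(members)
        mem &= background
        for name, gset in collection.sets.items():
            row = fisher_enrichment(mem, gset, background)
            row.update({"module": mod, "gene_set": name})
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table = table[["module", "gene_set", "overlap", "module_size",
                       "set_size", "background_size", "odds_ratio", "p", "q"]]
    return table


def cross_network_overlap(csf_modules: pd.Series,
                          brain_modules: pd.Series) -> dict:
    """Fisher overlap of CSF modules with a second network's modules.

    Both inputs map gene symbols to module names; the background is the
    set of symbols present in both networks.  Returns ``{"p": DataFrame,
    "q": DataFrame}`` of CSF module x brain module matrices, with
    Benjamini-Hochberg adjustment across the whole matrix.
    """
    csf = pd.Series(csf_modules)
    brain = pd.Series(brain_modules)
    background = set(csf.index) & set(brain.index)
    if not background:
        raise ParameterError("no shared gene symbols between the networks")
    csf = csf[csf.index.isin(background)]
    brain = brain[brain.index.isin(background)]
    cmods = sorted(csf.unique())
    bmods = sorted(brain.unique())
    p = pd.DataFrame(index=cmods, columns=bmods, dtype=float)
    for cm in cmods:
        mem = set(csf.index[csf == cm])
        for bm in bmods:
            gset = set(brain.index[brain == bm])
            p.loc[cm, bm] = fisher_enrichment(mem, gset, background)["p"]
    flat = p.to_numpy().ravel()
    q = multipletests(flat, method="fdr_bh")[1].reshape(p.shape)
    return {"p": p, "q": pd.DataFrame(q, index=cmods, columns=bmods)}
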