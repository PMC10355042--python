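"""Targeted-proteomics (SRM) validation stage.

Pooled-QC precision culling of peptides, the zero-respecting log2
transform, collapsing multiple peptides per protein by correlation with the
discovery measurement, and ROC classification of CT vs AD within each race
stratum with DeLong confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm

from . import robust
from .exceptions import ParameterError
from .simulate import SRMDataset

__all__ = [
    "qc_filter",
    "transform_ratios",
    "collapse_peptides",
    "roc_analysis",
    "auc_mann_whitney",
    "delong_ci",
]


# ---------------------------------------------------------------------------
# QC culling
# ---------------------------------------------------------------------------

def qc_filter(d: SRMDataset, cv_threshold: float = 0.20
              ) -> tuple[SRMDataset, pd.DataFrame]:
    """Retain peptides precise in at least one pooled QC standard.

    The coefficient of variation is computed on the raw area ratios
    (SD/mean per pool); a peptide is kept when its CV is at or below the
    threshold in the positive pool or the negative pool.  A pool whose
    replicate mean is zero has an undefined CV and the peptide is dropped
    with a warning.  Returns the retained dataset and a per-peptide CV
    report (``cv_pos``, ``cv_neg``, ``kept``).
    """
    if not 0 < cv_threshold:
        raise ParameterError("cv_threshold must be positive")
    pools = {}
    for pool in ("pos", "neg"):
        cols = d.qc_pool_of.index[d.qc_pool_of == pool]
        if len(cols) < 2:
            raise ParameterError(f"need >= 2 QC replicates in the {pool} pool")
        X = d.qc_ratios[cols].to_numpy(dtype=float)
        mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.nan)
        pools[pool] = cv
    report = pd.DataFrame({"cv_pos": pools["pos"], "cv_neg": pools["neg"]},
                          index=d.ratios.index)
    undefined = report.isna().any(axis=1)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} peptide(s) with a zero-mean QC pool "
            "dropped (CV undefined)", stacklevel=2)
    kept = (~undefined) & ((report["cv_pos"] <= cv_threshold)
                           | (report["cv_neg"] <= cv_threshold))
    report["kept"] = kept
    return d.subset(report.index[kept]), report


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def transform_ratios(d) -> pd.DataFrame:
    """log2 of the area ratios with per-peptide zero replacement.

    True zeros are replaced, after transformation, by the minimum log2
    value observed for that peptide minus 1.  A peptide with no positive
    value has no defined replacement and is an error.
    """
    ratios = d.ratios if isinstance(d, SRMDataset) else d
    X = ratios.to_numpy(dtype=float)
    if (X < 0).any() or np.isnan(X).any():
        raise ParameterError("ratios must be complete and non-negative")
    allzero = ~(X > 0).any(axis=1)
    if allzero.any():
        pep = ratios.index[allzero][0]
        raise ParameterError(f"peptide {pep!r} has only zero ratios; "
                             "zero replacement undefined")
    with np.errstate(divide="ignore"):
        L = np.log2(X)
    mins = np.where(X > 0, L, np.inf).min(axis=1)
    L = np.where(X > 0, L, (mins - 1.0)[:, None] * np.ones_like(L))
    return pd.DataFrame(L, index=ratios.index, columns=ratios.columns)


# ---------------------------------------------------------------------------
# Peptide collapsing
# ---------------------------------------------------------------------------

def collapse_peptides(srm_log2: pd.DataFrame, protein_of: pd.Series,
                      discovery, qc_cvs: pd.Series | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per protein: the peptide most correlated with discovery.

    For each protein with several peptides, the peptide whose profile has
    the largest bicor with the discovery (TMT) measurement of the same
    protein over the shared samples is kept; exact ties break to the
    lexicographically smallest peptide id.  A protein absent from the
    discovery matrix falls back to the peptide with the best (lowest)
    median QC CV — supplied via ``qc_cvs`` (e.g. the mean of the
    :func:`qc_filter` report columns) — and is flagged in the report.
    """
    disc = discovery.sample_frame() if hasattr(discovery, "sample_frame") \
        else discovery
    shared = [s for s in srm_log2.columns if s in disc.columns]
    chosen, rows = [], []
    for prot in protein_of.unique():
        peps = sorted(protein_of.index[protein_of == prot])
        flag = ""
        if prot in disc.index and len(shared) >= 4:
            prof = disc.loc[prot, shared].to_numpy(dtype=float)
            cors = {p: robust.bicor(srm_log2.loc[p, shared].to_numpy(dtype=float),
                                    prof)
                    for p in peps}
            best_r = np.nanmax([v for v in cors.values()]) \
                if not all(np.isnan(v) for v in cors.values()) else np.nan
            if np.isnan(best_r):
                flag = "no_usable_correlation"
                best = _best_by_precision(peps, qc_cvs)
            else:
                best = min(p for p, v in cors.items() if v == best_r)
            rows.append({"protein": prot, "peptide": best,
                         "bicor": cors.get(best, np.nan), "flag": flag,
                         "n_peptides": len(peps)})
        else:
            flag = "protein_absent_from_discovery" if prot not in disc.index \
                else "insufficient_shared_samples"
            best = _best_by_precision(peps, qc_cvs)
            rows.append({"protein": prot, "peptide": best, "bicor": np.nan,
                         "flag": flag, "n_peptides": len(peps)})
        chosen.append((prot, best))
    out = pd.DataFrame(
        [srm_log2.loc[pep].to_numpy(dtype=float) for _, pep in chosen],
        index=[prot for prot, _ in chosen], columns=srm_log2.columns)
    return out, pd.DataFrame(rows).set_index("protein")


def _best_by_precision(peps, qc_cvs: pd.Series | None) -> str:
    if len(peps) == 1 or qc_cvs is None:
        return peps[0]                      # lexicographically smallest
    sub = qc_cvs.reindex(peps)
    if sub.isna().all():
        return peps[0]
    best_cv = sub.min()
    return min(p for p in peps if sub[p] == best_cv)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic over n_pos * n_neg."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (len(pos) * len(neg))


def delong_ci(pos: np.ndarray, neg: np.ndarray, level: float = 0.95
              ) -> tuple[float, float, float]:
    """(AUC, lower, upper) with the DeLong structural-components variance."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = len(pos), len(neg)
    # placement values: for each positive, fraction of negatives below (+ half ties)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(0.5 + level / 2.0)
    return auc, float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


@dataclass
class ROCResult:
    table: pd.DataFrame          # protein x stratum rows: auc, p, ci, ns


def roc_analysis(protein_levels: pd.DataFrame, traits: pd.DataFrame,
                 orientation: pd.Series | None = None,
                 stratify_by: str = "race") -> pd.DataFrame:
    """CT-vs-AD ROC per protein within each stratum (default: race).

    AUC is the Mann-Whitney U over n_CT * n_AD with AD as the positive
    class; when ``orientation`` supplies the discovery fold-change sign the
    scores are flipped for decreased markers so that a discriminative
    down-regulated protein also reports AUC > 0.5.  p is the two-sided
    normal-approximation Mann-Whitney test with tie correction; the 95% CI
    uses the DeLong variance.  Strata with fewer than 3 samples in either
    class yield missing rows with a warning.
    """
    common = [s for s in protein_levels.columns if s in traits.index]
    if not common:
        raise ParameterError("no samples shared between levels and traits")
    tr = traits.loc[common]
    strata = sorted(tr[stratify_by].unique())
    rows = []
    for prot in protein_levels.index:
        sign = 1.0
        if orientation is not None and prot in orientation.index:
            val = orientation[prot]
            sign = -1.0 if (np.isfinite(val) and val < 0) else 1.0
        x = protein_levels.loc[prot, common].to_numpy(dtype=float) * sign
        for stratum in strata:
            sel = (tr[stratify_by] == stratum).to_numpy()
            dx = tr["diagnosis"].to_numpy()
            pos = x[sel & (dx == "AD")]
            neg = x[sel & (dx == "CT")]
            pos, neg = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
            if len(pos) < 3 or len(neg) < 3:
                warnings.warn(
                    f"stratum {stratum!r} has < 3 samples in a class for "
                    f"{prot!r}; ROC skipped", stacklevel=2)
                rows.append({"protein": prot, "stratum": stratum,
                             "auc": np.nan, "p": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "n_ct": len(neg),
                             "n_ad": len(pos)})
                continue
            auc, lo, hi = delong_ci(pos, neg)
            p = float(mannwhitneyu(pos, neg, alternative="two-sided",
                                   method="asymptotic").pvalue)
            rows.append({"protein": prot, "stratum": stratum, "auc": auc,
                         "p": p, "ci_low": lo, "ci_high": hi,
                         "n_ct": len(neg), "n_ad": len(pos)})
    return pd.DataFrame(rows)
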