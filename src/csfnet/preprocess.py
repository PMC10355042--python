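"""Data-cleaning chain for multiplexed proteomics.

Order of operations is fixed: quantification filter -> batch correction by
iterative median polish of internal-standard ratios -> robust-PCA outlier
removal -> bootstrap covariate regression, with multidimensional-scaling
and variance-partition diagnostics available at each stage.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .matrix import AbundanceMatrix
from .rpca import grid_rpca

__all__ = [
    "filter_missingness",
    "median_polish",
    "tampor_correct",
    "mds_coordinates",
    "OutlierParams",
    "OutlierResult",
    "detect_outliers",
    "RegressionSpec",
    "regress_covariates",
    "variance_fractions",
    "knn_impute",
    "encode_covariates",
]


# ---------------------------------------------------------------------------
# quantification filter
# ---------------------------------------------------------------------------

def filter_missingness(m: AbundanceMatrix,
                       min_quantified_fraction: float = 0.5) -> AbundanceMatrix:
    """Keep proteins quantified in at least the given fraction of samples.

    The fraction is computed over sample-role columns only (internal
    standards and pools do not count), and the boundary is inclusive.
    """
    if not 0.0 < min_quantified_fraction <= 1.0:
        raise ParameterError(
            f"min_quantified_fraction must be in (0, 1], got {min_quantified_fraction}")
    cols = m.sample_columns
    frac = m.data[cols].notna().mean(axis=1)
    keep = frac >= min_quantified_fraction
    return m.with_data(m.data.loc[keep])


# ---------------------------------------------------------------------------
# batch correction (iterative median polish of internal-standard ratios)
# ---------------------------------------------------------------------------

def median_polish(df: pd.DataFrame, tol: float = 1e-8,
                  max_iter: int = 100) -> pd.DataFrame:
    """Two-way median polish: alternately remove row and column medians.

    Iterates until the largest absolute extracted median drops below
    ``tol`` or ``max_iter`` sweeps.  NaNs are ignored and preserved.
    """
    X = df.to_numpy(dtype=float).copy()
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            r = np.nanmedian(X, axis=1)
        r = np.where(np.isnan(r), 0.0, r)
        X -= r[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            c = np.nanmedian(X, axis=0)
        c = np.where(np.isnan(c), 0.0, c)
        X -= c[None, :]
        if max(np.max(np.abs(r), initial=0.0), np.max(np.abs(c), initial=0.0)) < tol:
            break
    return pd.DataFrame(X, index=df.index, columns=df.columns)


def tampor_correct(m: AbundanceMatrix, tol: float = 1e-8,
                   max_iter: int = 100) -> AbundanceMatrix:
    """Remove batch-level technical variance by median polish of ratios.

    Per protein and batch, abundances are expressed as log2 ratios to the
    median of that protein's internal-standard (GIS) channels in the same
    batch, which cancels any per-batch offset exactly.  The ratio matrix is
    then two-way median polished, and each protein's pre-correction grand
    median (over sample columns) is added back to restore the abundance
    scale.  GIS and pool columns are dropped from the output.
    """
    sample_cols = m.sample_columns
    batches = m.batches
    ratio = m.data[sample_cols].copy()
    for b in sorted({batches[c] for c in sample_cols}):
        gis_cols = [c for c in m.gis_columns if batches[c] == b]
        if not gis_cols:
            raise ParameterError(f"batch {b!r} has no GIS channel")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gis_med = np.nanmedian(m.data[gis_cols].to_numpy(), axis=1)
        frac_missing = float(np.mean(np.isnan(gis_med)))
        if frac_missing > 0.5:
            warnings.warn(
                f"batch {b!r}: GIS unquantified for {frac_missing:.0%} of proteins",
                stacklevel=2)
        b_cols = [c for c in sample_cols if batches[c] == b]
        ratio[b_cols] = ratio[b_cols].to_numpy() - gis_med[:, None]

    polished = median_polish(ratio, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        grand = np.nanmedian(m.data[sample_cols].to_numpy(), axis=1)
    corrected = polished.add(pd.Series(grand, index=polished.index), axis=0)
    return m.with_data(corrected)


# ---------------------------------------------------------------------------
# MDS diagnostic
# ---------------------------------------------------------------------------

def mds_coordinates(m: AbundanceMatrix, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS embedding of samples.

    Distances are Euclidean over pairwise-complete standardised proteins,
    rescaled by the shared-protein count so sparsely overlapping pairs are
    comparable.  Returns a sample x dimension coordinate frame.
    """
    cols = m.sample_columns
    if len(cols) < n_dims + 1:
        raise ParameterError("need at least n_dims + 1 samples")
    X = m.data[cols].to_numpy(dtype=float)
    allnan = np.isnan(X).all(axis=0)
    if allnan.any():
        bad = [c for c, a in zip(cols, allnan) if a]
        raise ParameterError(f"samples with no quantified proteins: {bad}")
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    obs = ~np.isnan(Z)
    Z0 = np.where(obs, Z, 0.0)
    o = obs.astype(float)
    cross = Z0.T @ Z0
    sqo = (Z0 * Z0).T @ o           # (i,j): sum of z_i^2 over proteins seen in j
    counts = o.T @ o
    if (counts == 0).any():
        raise ParameterError("sample pairs with no shared quantified proteins")
    P = X.shape[0]
    D2 = (sqo + sqo.T - 2.0 * cross) * (P / counts)
    D2 = np.maximum(D2, 0.0)
    np.fill_diagonal(D2, 0.0)
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_dims]
    lam = np.maximum(evals[order], 0.0)
    coords = evecs[:, order] * np.sqrt(lam)
    return pd.DataFrame(coords, index=cols,
                        columns=[f"dim{i + 1}" for i in range(n_dims)])


# ---------------------------------------------------------------------------
# robust-PCA outlier detection
# ---------------------------------------------------------------------------

@dataclass
class OutlierParams:
    """Settings for robust-PCA sample outlier detection."""

    n_components: int = 7
    crit: float = 0.99     # quantile for both distance cutoffs

    def validate(self) -> None:
        if self.n_components < 1:
            raise ParameterError("n_components must be >= 1")
        if not 0.5 < self.crit < 1.0:
            raise ParameterError("crit must lie in (0.5, 1)")


@dataclass
class OutlierResult:
    outliers: list                    # flagged sample column ids
    score_distance: pd.Series
    orthogonal_distance: pd.Series
    sd_cutoff: float
    od_cutoff: float


def detect_outliers(m: AbundanceMatrix, params: OutlierParams | None = None
                    ) -> OutlierResult:
    """Flag aberrant samples by robust PCA score and orthogonal distances.

    Missing abundances are imputed with the per-protein median for this
    step only.  A sample is flagged when its robust score distance exceeds
    the chi-square ``crit`` quantile (on ``n_components`` df) or its
    orthogonal distance exceeds a Wilson-Hilferty normal-approximation
    cutoff at the same quantile.
    """
    params = params or OutlierParams()
    params.validate()
    cols = m.sample_columns
    X = m.data[cols].to_numpy(dtype=float)
    med = np.nanmedian(X, axis=1)
    X = np.where(np.isnan(X), med[:, None], X).T      # samples x proteins
    n, p = X.shape
    if params.n_components > min(n, p):
        raise ParameterError("n_components exceeds data dimensions")
    fit = grid_rpca(X, params.n_components)
    scales = np.where(fit.scales == 0, 1.0, fit.scales)
    sd = np.sqrt(np.sum((fit.scores / scales) ** 2, axis=1))
    resid = (X - fit.center) - fit.scores @ fit.loadings.T
    od = np.linalg.norm(resid, axis=1)
    sd_cut = math.sqrt(stats.chi2.ppf(params.crit, df=params.n_components))
    od23 = od ** (2.0 / 3.0)
    loc = np.median(od23)
    scale = 1.4826 * np.median(np.abs(od23 - loc))
    od_cut = (loc + scale * stats.norm.ppf(params.crit)) ** 1.5
    flagged = [c for c, s, o in zip(cols, sd, od) if s > sd_cut or o > od_cut]
    return OutlierResult(
        outliers=flagged,
        score_distance=pd.Series(sd, index=cols),
        orthogonal_distance=pd.Series(od, index=cols),
        sd_cutoff=float(sd_cut),
        od_cutoff=float(od_cut),
    )


# ---------------------------------------------------------------------------
# covariate encoding shared by regression / variance partition / statistics
# ---------------------------------------------------------------------------

def encode_covariates(traits: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric coding of clinical covariates (AD=1, AA=1, female=1)."""
    out = {}
    for name in names:
        if name == "diagnosis":
            out[name] = (traits["diagnosis"] == "AD").astype(float)
        elif name == "race":
            out[name] = (traits["race"] == "AA").astype(float)
        elif name == "sex":
            out[name] = (traits["sex"] == "F").astype(float)
        else:
            out[name] = pd.to_numeric(traits[name])
    return pd.DataFrame(out, index=traits.index)


@dataclass
class RegressionSpec:
    """What to regress out and what to protect."""

    remove_covariates: tuple = ("age", "sex")
    keep_factors: tuple = ("diagnosis", "race")
    n_bootstrap: int = 1000
    seed: int = 0

    def validate(self) -> None:
        overlap = set(self.remove_covariates) & set(self.keep_factors)
        if overlap:
            raise ParameterError(f"covariates both kept and removed: {sorted(overlap)}")
        if self.n_bootstrap < 1:
            raise ParameterError("n_bootstrap must be >= 1")


def _bootstrap_betas(X: np.ndarray, Y: np.ndarray, n_boot: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Median over case-resampled OLS coefficient estimates.

    ``X`` is n x k (full column rank), ``Y`` n x m.  Returns k x m.
    """
    n = X.shape[0]
    betas = np.empty((n_boot, X.shape[1], Y.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb = X[idx]
        # guard against resamples that drop a level entirely
        try:
            coef, *_ = np.linalg.lstsq(Xb, Y[idx], rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - lstsq rarely fails
            coef = np.full((X.shape[1], Y.shape[1]), np.nan)
        betas[b] = coef
    return np.nanmedian(betas, axis=0)


def regress_covariates(m, traits: pd.DataFrame,
                       spec: RegressionSpec | None = None):
    """Remove nuisance covariates while protecting the group structure.

    Per protein, abundance ~ kept factors + removed covariates is fit on
    bootstrap case-resamples; coefficients are the medians across
    resamples, and only the removed covariates' (centred) terms are
    subtracted, so group signal and the intercept survive.  Missing
    abundances stay missing.  Accepts an :class:`AbundanceMatrix` (sample
    columns, mapped to trait rows) or a plain feature x sample DataFrame
    whose columns are trait index entries; returns the same type.
    """
    spec = spec or RegressionSpec()
    spec.validate()
    if isinstance(m, AbundanceMatrix):
        df = m.sample_frame()
    else:
        df = m
    samples = [s for s in df.columns if s in traits.index]
    if len(samples) != df.shape[1]:
        missing = [s for s in df.columns if s not in traits.index]
        raise ParameterError(f"samples without traits: {missing[:5]}")
    cov = encode_covariates(traits.loc[samples],
                            list(spec.keep_factors) + list(spec.remove_covariates))
    dropped = [c for c in cov.columns if cov[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"constant covariates dropped: {dropped}", stacklevel=2)
        cov = cov.drop(columns=dropped)
    remove = [c for c in spec.remove_covariates if c in cov.columns]

    Xfull = np.column_stack([np.ones(len(samples)), cov.to_numpy()])
    terms = ["intercept"] + list(cov.columns)
    Y = df[samples].to_numpy(dtype=float).T     # samples x proteins
    adjusted = Y.copy()
    rng = np.random.default_rng(spec.seed)

    # group proteins by missingness pattern so each group is fit vectorised
    nan_mask = np.isnan(Y)
    patterns = {}
    for j in range(Y.shape[1]):
        patterns.setdefault(nan_mask[:, j].tobytes(), []).append(j)
    centred = {c: cov[c].to_numpy() - cov[c].to_numpy().mean() for c in remove}
    for key, cols_j in patterns.items():
        obs = ~np.frombuffer(key, dtype=bool)
        if obs.sum() <= Xfull.shape[1]:
            continue  # too few observations to fit; leave untouched
        beta = _bootstrap_betas(Xfull[obs], Y[np.ix_(obs, cols_j)],
                                spec.n_bootstrap, rng)
        for name in remove:
            k = terms.index(name)
            adjusted[np.ix_(obs, cols_j)] -= np.outer(centred[name][obs], beta[k])
    out = pd.DataFrame(adjusted.T, index=df.index, columns=samples)
    if isinstance(m, AbundanceMatrix):
        back = {s: c for c, s in m.sample_of_column.items()}
        if back:
            out = out.rename(columns=back)
        return m.with_data(out)
    return out


# ---------------------------------------------------------------------------
# variance partition diagnostic
# ---------------------------------------------------------------------------

def knn_impute(df: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing values from the k most similar rows (features).

    Similarity is mean squared difference over mutually observed columns;
    for each missing cell the mean of the k nearest rows observed at that
    column is used, falling back to the row mean.
    """
    X = df.to_numpy(dtype=float).copy()
    nan_rows = np.where(np.isnan(X).any(axis=1))[0]
    if nan_rows.size == 0:
        return df.copy()
    obs = ~np.isnan(X)
    Z = np.where(obs, X, 0.0)
    row_mean = np.where(obs.any(axis=1),
                        np.nansum(X, axis=1) / np.maximum(obs.sum(axis=1), 1), 0.0)
    for i in nan_rows:
        xi, oi = Z[i], obs[i]
        shared = obs[:, oi].astype(float) @ np.ones(oi.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            diff = Z[:, oi] - xi[oi]
            diff[~obs[:, oi]] = 0.0
            both = obs[:, oi].astype(float)
            d2 = ((diff * diff) * both).sum(axis=1) / both.sum(axis=1)
        d2[i] = np.inf
        d2[both.sum(axis=1) == 0] = np.inf
        order = np.argsort(d2)
        for j in np.where(~oi)[0]:
            donors = [r for r in order if obs[r, j] and np.isfinite(d2[r])][:k]
            X[i, j] = X[donors, j].mean() if donors else row_mean[i]
    return pd.DataFrame(X, index=df.index, columns=df.columns)


def variance_fractions(m, traits: pd.DataFrame,
                       factors=("diagnosis", "race", "age", "sex"),
                       knn_k: int = 10) -> pd.DataFrame:
    """Per-protein fraction of variance attributable to each factor.

    R-squared is decomposed by sequential sums of squares averaged over
    every ordering of the factors (the LMG decomposition), so the result
    does not depend on an arbitrary factor order.  Missing abundances are
    k-nearest-neighbour imputed for this diagnostic only.
    """
    df = m.sample_frame() if isinstance(m, AbundanceMatrix) else m
    samples = [s for s in df.columns if s in traits.index]
    df = knn_impute(df[samples], k=knn_k)
    cov = encode_covariates(traits.loc[samples], factors)
    Y = df.to_numpy(dtype=float).T                     # samples x proteins
    Yc = Y - Y.mean(axis=0)
    denom = (Yc * Yc).sum(axis=0)
    denom[denom == 0] = np.nan

    factors = list(factors)
    K = len(factors)
    subsets = {}
    for r in range(1, K + 1):
        for S in itertools.combinations(range(K), r):
            Xs = cov.iloc[:, list(S)].to_numpy()
            Xs = Xs - Xs.mean(axis=0)
            Q, _ = np.linalg.qr(Xs)
            proj = Q.T @ Yc
            subsets[S] = (proj * proj).sum(axis=0) / denom
    subsets[()] = np.zeros(Y.shape[1])

    fracs = np.zeros((K, Y.shape[1]))
    n_orderings = math.factorial(K)
    for order in itertools.permutations(range(K)):
        prev = ()
        for f in order:
            cur = tuple(sorted(prev + (f,)))
            fracs[f] += (subsets[cur] - subsets[tuple(sorted(prev))]) / n_orderings
            prev = cur
    full = subsets[tuple(range(K))]
    out = pd.DataFrame(fracs.T, index=df.index, columns=factors)
    out["residual"] = 1.0 - full
    return out
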