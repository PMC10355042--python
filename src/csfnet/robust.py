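"""Robust correlation primitives.

The biweight midcorrelation (bicor) is the workhorse correlation of the
pipeline: it replaces means by medians and downweights observations with
Tukey biweights so that a handful of aberrant samples cannot dominate a
protein-protein or protein-trait correlation the way they can with Pearson.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["bicor", "bicor_matrix", "bicor_pairs", "mad"]

#: minimum number of mutually observed samples required for a correlation
MIN_COMPLETE_PAIRS = 4


def mad(x: np.ndarray, axis=None) -> np.ndarray:
    """Median absolute deviation (unscaled)."""
    med = np.nanmedian(x, axis=axis, keepdims=True)
    return np.nanmedian(np.abs(x - med), axis=axis)


def _biweight_transform(x: np.ndarray) -> np.ndarray:
    """Median-centred, biweight-weighted version of ``x`` (NaNs preserved).

    For each vector: u_i = (x_i - median) / (9 * MAD), w_i = (1 - u_i^2)^2
    for |u_i| < 1 else 0, and the transformed value is (x_i - median) * w_i.
    Vectors whose MAD is zero fall back to mean-centring (Pearson behaviour),
    since the biweight is undefined there.
    """
    x = np.asarray(x, dtype=float)
    med = np.nanmedian(x, axis=-1, keepdims=True)
    d = x - med
    m = np.nanmedian(np.abs(d), axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = d / (9.0 * m)
    w = np.square(1.0 - np.square(u))
    w[np.abs(u) >= 1.0] = 0.0
    out = d * w
    # MAD == 0: Pearson fallback (mean-centre, unit weights) for that vector
    zero = (m == 0).squeeze(-1)
    if np.any(zero):
        mean = np.nanmean(x, axis=-1, keepdims=True)
        centred = x - mean
        out = np.where(zero[..., None], centred, out)
    return out


def bicor(x, y) -> float:
    """Biweight midcorrelation between two 1-D vectors.

    Computed on mutually observed (non-NaN) entries.  Returns NaN (with a
    warning) when fewer than four complete pairs are available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < MIN_COMPLETE_PAIRS:
        warnings.warn(
            f"bicor: only {int(ok.sum())} complete pairs (<{MIN_COMPLETE_PAIRS}); "
            "returning NaN",
            stacklevel=2,
        )
        return float("nan")
    xt = _biweight_transform(x[ok])
    yt = _biweight_transform(y[ok])
    nx = np.linalg.norm(xt)
    ny = np.linalg.norm(yt)
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip(xt @ yt / (nx * ny), -1.0, 1.0))


def _bicor_complete(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """bicor between rows of ``X`` (and optionally rows of ``Y``), no NaNs."""
    Xt = _biweight_transform(X)
    Xt /= np.linalg.norm(Xt, axis=1, keepdims=True)
    if Y is None:
        C = Xt @ Xt.T
        np.fill_diagonal(C, 1.0)
    else:
        Yt = _biweight_transform(Y)
        Yt /= np.linalg.norm(Yt, axis=1, keepdims=True)
        C = Xt @ Yt.T
    return np.clip(C, -1.0, 1.0)


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs bicor between the rows of ``X`` (variables x observations).

    Missing values are handled pairwise-complete: each row's biweights are
    computed on its own observed entries, and each pair's cross-product and
    norms are restricted to mutually observed samples.  Pairs with fewer
    than four complete observations get NaN.
    """
    X = np.asarray(X, dtype=float)
    if not np.isnan(X).any():
        return _bicor_complete(X)
    Xt = _biweight_transform(X)  # NaNs preserved
    obs = ~np.isnan(Xt)
    Z = np.where(obs, Xt, 0.0)
    num = Z @ Z.T
    sq = Z * Z
    # per-pair norms over the mutual support
    o = obs.astype(float)
    nxy = sq @ o.T          # sum of x~^2 over samples observed in both
    nyx = o @ sq.T
    counts = o @ o.T
    with np.errstate(divide="ignore", invalid="ignore"):
        C = num / np.sqrt(nxy * nyx)
    C[counts < MIN_COMPLETE_PAIRS] = np.nan
    if np.any(counts < MIN_COMPLETE_PAIRS):
        warnings.warn(
            "bicor_matrix: some pairs have <4 complete observations; NaN returned",
            stacklevel=2,
        )
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def bicor_pairs(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """bicor between every row of ``X`` and every row of ``Y``.

    Same pairwise-complete convention as :func:`bicor_matrix`.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.isnan(X).any() or np.isnan(Y).any()):
        return _bicor_complete(X, Y)
    Xt = _biweight_transform(X)
    Yt = _biweight_transform(Y)
    ox = ~np.isnan(Xt)
    oy = ~np.isnan(Yt)
    Zx = np.where(ox, Xt, 0.0)
    Zy = np.where(oy, Yt, 0.0)
    num = Zx @ Zy.T
    nxy = (Zx * Zx) @ oy.T.astype(float)
    nyx = ox.astype(float) @ (Zy * Zy).T
    counts = ox.astype(float) @ oy.T.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = num / np.sqrt(nxy * nyx)
    C[counts < MIN_COMPLETE_PAIRS] = np.nan
    return np.clip(C, -1.0, 1.0)
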