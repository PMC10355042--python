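"""Robust principal components by projection-pursuit grid search.

Classical PCA chases variance, so a few aberrant samples can seize the
leading components.  Here each component is the direction maximising a
*robust* spread (1.4826 x median absolute deviation) of the projected
samples, found by the grid algorithm: starting from the best coordinate
axis, the candidate direction is repeatedly rotated within the plane it
spans with each coordinate axis over a shrinking grid of angles, keeping
the rotation that increases the robust scale.  Components are extracted
sequentially with deflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = ["grid_rpca", "RobustPCA"]


def _mad_scale(x: np.ndarray, axis=0) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=axis)


@dataclass
class RobustPCA:
    center: np.ndarray        # p-dim coordinatewise median
    loadings: np.ndarray      # p x k, orthonormal columns
    scores: np.ndarray        # n x k
    scales: np.ndarray        # robust scale of each score column


def _grid_direction(Y: np.ndarray, rng_cycles: int = 4, n_angles: int = 10) -> np.ndarray:
    """Direction (unit vector) maximising the MAD scale of ``Y @ a``."""
    n, r = Y.shape
    col_scales = _mad_scale(Y, axis=0)
    a = np.zeros(r)
    a[int(np.argmax(col_scales))] = 1.0
    ya = Y @ a
    best = _mad_scale(ya[:, None], axis=0)[0]
    half = np.pi / 2.0
    for cycle in range(rng_cycles):
        span = half / (2 ** cycle)
        thetas = np.linspace(-span, span, n_angles)
        for i in range(r):
            yi = Y[:, i]
            ai = a[i]
            cos = np.cos(thetas)
            sin = np.sin(thetas)
            norms = np.sqrt(np.maximum(1.0 + 2.0 * cos * sin * ai, 1e-12))
            proj = (cos[None, :] * ya[:, None] + sin[None, :] * yi[:, None]) / norms
            scales = _mad_scale(proj, axis=0)
            j = int(np.argmax(scales))
            if scales[j] > best + 1e-12:
                best = scales[j]
                a = (cos[j] * a + sin[j] * np.eye(r)[:, i]) / norms[j]
                ya = (cos[j] * ya + sin[j] * yi) / norms[j]
    return a / np.linalg.norm(a)


def grid_rpca(X: np.ndarray, n_components: int) -> RobustPCA:
    """Sequential projection-pursuit robust PCA of ``X`` (observations x variables).

    When the variable count exceeds the observation count the search runs
    in the subspace spanned by the (median-centred) data, which contains
    every direction with non-zero projected spread.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components < 1 or n_components > min(n, p):
        raise ParameterError(
            f"n_components={n_components} outside [1, min(n,p)={min(n, p)}]")
    center = np.median(X, axis=0)
    Xc = X - center
    # reduce to the data's own subspace for speed and identifiability
    if p > n:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        B = Vt[:rank].T                  # p x rank basis
        Y = Xc @ B
    else:
        B = np.eye(p)
        Y = Xc.copy()
    r = Y.shape[1]
    if n_components > r:
        raise ParameterError("n_components exceeds the rank of the data")
    A = np.zeros((r, n_components))
    Ydef = Y.copy()
    for l in range(n_components):
        a = _grid_direction(Ydef)
        # keep the loading orthogonal to previous components
        if l:
            a = a - A[:, :l] @ (A[:, :l].T @ a)
            na = np.linalg.norm(a)
            if na < 1e-12:
                raise ParameterError("degenerate direction during robust PCA")
            a = a / na
        A[:, l] = a
        t = Ydef @ a
        Ydef = Ydef - np.outer(t, a)
    loadings = B @ A
    scores = Xc @ loadings
    scales = _mad_scale(scores, axis=0)
    return RobustPCA(center=center, loadings=loadings, scores=scores, scales=scales)
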