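"""Signed weighted co-expression network: adjacency, TOM, modules, kME.

The pipeline is: biweight midcorrelation between all protein pairs →
signed soft-threshold adjacency → topological overlap dissimilarity →
average-linkage clustering with an adaptive tree cut (:mod:`.treecut`) →
per-module eigenproteins (first right singular vector of the z-scored
member matrix) → merging of modules whose eigenproteins are nearly
collinear → module naming by decreasing size with kME (protein-eigenprotein
bicor) for every protein against every module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import robust
from .exceptions import ParameterError
from .matrix import AbundanceMatrix
from .preprocess import knn_impute
from .treecut import cut_tree_dynamic

__all__ = [
    "NetworkParams",
    "NetworkResult",
    "bicor_matrix",
    "adjacency_tom",
    "cut_modules",
    "eigenproteins",
    "merge_modules",
    "build_network",
    "linkage_to_newick",
]

UNASSIGNED = "M0"


@dataclass
class NetworkParams:
    """Parameters of the signed co-expression network."""

    beta: float = 3.0
    deep_split: int = 4
    min_module_size: int = 5
    merge_cut_height: float = 0.07
    signed: bool = True
    pam_stage: bool = True

    def __post_init__(self):
        if self.beta < 1:
            raise ParameterError("beta must be >= 1")
        if not 0 <= self.deep_split <= 4:
            raise ParameterError("deep_split must be in 0..4")
        if self.min_module_size < 2:
            raise ParameterError("min_module_size must be >= 2")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ParameterError("merge_cut_height must be in (0, 1)")


@dataclass
class NetworkResult:
    """Final module assignment with eigenproteins and kME."""

    module_of: pd.Series                 # protein -> "M1".. / "M0"
    eigenproteins: pd.DataFrame          # samples x modules, unit variance
    variance_explained: pd.Series        # module -> fraction of member variance
    kme: pd.DataFrame                    # proteins x modules, bicor
    dendrogram: np.ndarray | None        # scipy linkage of the proteins
    params: NetworkParams = field(default_factory=NetworkParams)

    def module_sizes(self) -> pd.Series:
        sizes = self.module_of.value_counts()
        return sizes[sizes.index != UNASSIGNED].sort_values(ascending=False)


def _sample_frame(m) -> pd.DataFrame:
    if isinstance(m, AbundanceMatrix):
        return m.sample_frame()
    return m


def bicor_matrix(m) -> pd.DataFrame:
    """All-pairs biweight midcorrelation between proteins (rows)."""
    df = _sample_frame(m)
    C = robust.bicor_matrix(df.to_numpy(dtype=float))
    return pd.DataFrame(C, index=df.index, columns=df.index)


def adjacency_tom(cor, params: NetworkParams | None = None):
    """Topological overlap dissimilarity of a soft-thresholded network.

    Signed adjacency ``a_ij = ((1+cor_ij)/2)^beta`` (``|cor_ij|^beta`` when
    unsigned) with zero diagonal; topological overlap
    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)`` with
    connectivity ``k_i = sum_u a_iu``.  Returns ``1 - TOM`` with a zero
    diagonal, in the same container type as the input.
    """
    params = params or NetworkParams()
    index = cor.index if isinstance(cor, pd.DataFrame) else None
    C = np.asarray(cor, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ParameterError("correlation matrix must be square")
    if np.isnan(C).any():
        raise ParameterError(
            "correlation matrix contains missing values; too few complete "
            "pairs for some proteins")
    if not np.allclose(C, C.T, atol=1e-10, equal_nan=True):
        raise ParameterError("correlation matrix must be symmetric")
    if C.min() < -1 - 1e-12 or C.max() > 1 + 1e-12:
        raise ParameterError("correlation entries must lie in [-1, 1]")
    if params.signed:
        A = ((1.0 + C) / 2.0) ** params.beta
    else:
        A = np.abs(C) ** params.beta
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    numer = A @ A + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = numer / denom
    diss = 1.0 - tom
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    if index is not None:
        return pd.DataFrame(diss, index=index, columns=index)
    return diss


def cut_modules(diss, params: NetworkParams | None = None
                ) -> tuple[pd.Series, np.ndarray | None]:
    """Preliminary modules from average-linkage clustering of ``1 - TOM``.

    Returns the assignment (protein → "M1"… by decreasing size, "M0" for
    unassigned) and the scipy linkage matrix.
    """
    params = params or NetworkParams()
    index = diss.index if isinstance(diss, pd.DataFrame) else None
    D = np.asarray(diss, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ParameterError("dissimilarity matrix must be square")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ParameterError("dissimilarity matrix must have a zero diagonal")
    n = D.shape[0]
    if index is None:
        index = pd.RangeIndex(n)
    if n < params.min_module_size:
        warnings.warn("fewer proteins than min_module_size: all M0", stacklevel=2)
        return pd.Series(UNASSIGNED, index=index, name="module"), None
    Z = linkage(squareform(D, checks=False), method="average")
    result = cut_tree_dynamic(
        Z, D, min_size=params.min_module_size, deep_split=params.deep_split,
        pam=params.pam_stage)
    names = pd.Series([f"M{c}" for c in result.labels], index=index, name="module")
    return names, Z


def eigenproteins(m, assignment: pd.Series, knn_k: int = 10
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component summary profile of every module.

    Member proteins are z-scored across samples, residual missing values are
    imputed module-wise from the ``knn_k`` most similar member proteins, and
    the first right singular vector over samples is scaled to unit variance
    and oriented so the mean member correlation is positive.  Also returns
    the fraction of member variance each eigenprotein explains.
    """
    df = _sample_frame(m)
    modules = _module_names(assignment)
    eig = {}
    varexp = {}
    for name in modules:
        members = assignment.index[assignment == name]
        if len(members) < 2:
            raise ParameterError(f"module {name} has fewer than 2 proteins")
        sub = df.loc[members]
        informative = (~sub.isna()).any(axis=0)
        if int(informative.sum()) < 2:
            raise ParameterError(
                f"module {name} has fewer than 2 samples with data")
        Z = _zscore_rows(sub)
        if Z.isna().any().any():
            Z = knn_impute(Z, k=knn_k)
        if Z.isna().any().any():
            raise ParameterError(
                f"module {name}: missing values remain after imputation")
        U, s, Vt = np.linalg.svd(Z.to_numpy(dtype=float), full_matrices=False)
        v = Vt[0]
        sd = v.std(ddof=1)
        if sd == 0:
            raise ParameterError(f"module {name}: degenerate eigenprotein")
        v = v / sd
        mean_cor = float(np.nanmean(robust.bicor_pairs(
            Z.to_numpy(dtype=float), v[None, :])))
        if mean_cor < 0:
            v = -v
        eig[name] = pd.Series(v, index=df.columns)
        varexp[name] = float(s[0] ** 2 / np.sum(s ** 2))
    eigdf = pd.DataFrame(eig, columns=modules)
    return eigdf, pd.Series(varexp, name="variance_explained").reindex(modules)


def merge_modules(m, assignment: pd.Series, eig: pd.DataFrame,
                  params: NetworkParams | None = None,
                  dendrogram: np.ndarray | None = None) -> NetworkResult:
    """Merge modules with nearly collinear eigenproteins; final result.

    Eigenproteins are clustered on ``1 - bicor`` with average linkage and
    branches below ``merge_cut_height`` are combined; merging repeats on the
    recomputed eigenproteins until no further pair falls below the cut
    (idempotent fixed point).  Modules are renamed M1… by decreasing size
    and kME is the bicor of every protein with every final eigenprotein.
    """
    params = params or NetworkParams()
    df = _sample_frame(m)
    assignment = assignment.copy()
    while True:
        modules = list(eig.columns)
        if len(modules) < 2:
            break
        C = robust.bicor_matrix(eig.to_numpy(dtype=float).T)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        D[D < 0] = 0.0
        Ze = linkage(squareform(D, checks=False), method="average")
        groups = fcluster(Ze, t=params.merge_cut_height, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        relabel = {}
        for gid in np.unique(groups):
            combined = [modules[i] for i in np.where(groups == gid)[0]]
            for name in combined:
                relabel[name] = combined[0]
        assignment = assignment.map(lambda x: relabel.get(x, x))
        eig, _ = eigenproteins(df, assignment)
    assignment = _rename_by_size(assignment)
    eig, varexp = eigenproteins(df, assignment)
    kme = pd.DataFrame(
        robust.bicor_pairs(df.to_numpy(dtype=float),
                           eig.to_numpy(dtype=float).T),
        index=df.index, columns=eig.columns)
    return NetworkResult(module_of=assignment, eigenproteins=eig,
                         variance_explained=varexp, kme=kme,
                         dendrogram=dendrogram, params=params)


def build_network(m, params: NetworkParams | None = None) -> NetworkResult:
    """Full network pipeline: bicor → TOM → cut → eigenproteins → merge.

    Module detection is iterated on the residual: the tree-cut criteria are
    normalised by the dendrogram's height range, so a strong module
    compresses the scale on which weaker ones are judged, and topological
    overlap additionally shrinks distances toward high-connectivity hubs.
    After each pass the network (bicor → TOM) is therefore rebuilt from the
    still-unassigned proteins only and cut again, until a pass detects
    nothing.  Structure-free data yields no modules in the first pass, so
    the iteration cannot manufacture modules from noise; fragments of one
    real module found in different passes are rejoined by the eigenprotein
    merge step.
    """
    params = params or NetworkParams()
    df = _sample_frame(m)
    batch_of_col = None
    if isinstance(m, AbundanceMatrix):
        by_col = {m.sample_of_column.get(c, c): m.batches[c]
                  for c in m.sample_columns}
        batch_of_col = np.array([by_col[c] for c in df.columns])
    assignment = pd.Series(UNASSIGNED, index=df.index, dtype=object)
    dendrogram = None
    next_id = 1
    remaining = df.index
    while len(remaining) >= params.min_module_size:
        sub = df.loc[remaining]
        cor = bicor_matrix(sub)
        diss = adjacency_tom(cor, params)
        with warnings.catch_warnings():
            if dendrogram is not None:        # keep only the first pass's warnings
                warnings.simplefilter("ignore")
            part, Z = cut_modules(diss, params)
        if dendrogram is None:
            dendrogram = Z
        found = {c: part.index[part == c] for c in part.unique() if c != UNASSIGNED}
        if found:
            in_candidate = sub.index.isin(set().union(*found.values()))
            floor = _coherence_floor(sub.to_numpy(dtype=float), cor.to_numpy(),
                                     [len(v) for v in found.values()],
                                     params=params, batch_of_col=batch_of_col,
                                     candidate_rows=in_candidate)
            found = {c: v for c, v in found.items()
                     if _mean_within_bicor(cor, v) > floor[len(v)]}
        if not found:
            break
        for c in sorted(found, key=lambda name: int(name[1:])):
            assignment.loc[found[c]] = f"M{next_id}"
            next_id += 1
        remaining = assignment.index[assignment == UNASSIGNED]

    if not (assignment != UNASSIGNED).any():
        empty = pd.DataFrame(index=df.columns)
        return NetworkResult(module_of=assignment, eigenproteins=empty,
                             variance_explained=pd.Series(dtype=float),
                             kme=pd.DataFrame(index=df.index),
                             dendrogram=dendrogram, params=params)
    eig, _ = eigenproteins(m, assignment)
    return merge_modules(m, assignment, eig, params, dendrogram=dendrogram)


_FLOOR_SEEDS = 256


def _coherence_floor(X: np.ndarray, C_obs: np.ndarray, sizes,
                     params: NetworkParams | None = None,
                     seed: int = 0, batch_of_col=None,
                     candidate_rows=None) -> dict:
    """Null coherence level per module size, matched to the module statistic.

    A detected module is judged by its mean within-module bicor, so the
    floor estimates the best such *clique* coherence achievable by chance.
    Two fixed-seed nulls are evaluated and the stricter one used:

    * independent shuffle — each protein's samples permuted on their own,
      destroying all dependence (calibrates i.i.d. noise);
    * a dependence-preserving rearrangement — when batch labels are known,
      each protein's batch blocks are independently permuted as units
      (keeping noise shared within a batch intact, including the block
      geometry that lets unrelated proteins align by chance); otherwise
      each protein's samples are cyclically shifted by a random offset,
      which keeps dependence on the sample ordering.  Either way proteins
      are de-aligned from one another, so the null has the marginal
      dependence of the data but no co-expression.

    A component shared by *all* proteins (e.g. the sample profile a global
    normalisation injects into every row) is not co-expression evidence,
    so it must survive into the null rather than be destroyed by it: a
    robust rank-one shared profile (median standardised sample profile,
    with a per-protein loading) is fitted first, only the residuals are
    rearranged, and the shared part is added back.  The profile is fitted
    on the rows outside every candidate module (``candidate_rows`` mask)
    when any exist, so genuine module signal cannot masquerade as the
    shared component.

    Each null is mined for chance cliques in two matched ways: greedy
    agglomerative growth (seeded at the strongest null pairs, each step
    adding the protein that maximises the clique's mean pairwise
    correlation), and the detection pipeline itself (TOM dissimilarity plus
    tree cut) run on the null matrix — whatever modules it finds there are
    by definition chance findings, and a chance clique of size ``s0``
    bounds every size ``s <= s0`` because its most coherent sub-clique is
    at least as coherent.
    """
    params = params or NetworkParams()
    rng = np.random.default_rng(seed)
    sizes = set(sizes)
    floors = {s: float("-inf") for s in sizes}
    n = X.shape[1]
    fit_rows = None
    if candidate_rows is not None and (~candidate_rows).any():
        fit_rows = ~np.asarray(candidate_rows, dtype=bool)
    shared, resid = _shared_profile_split(X, fit_rows)
    if batch_of_col is not None:
        blocks = [np.where(batch_of_col == b)[0]
                  for b in pd.unique(batch_of_col)]
    null_cliques = []                       # (size, mean within correlation)
    for mode in ("shuffle", "rearrange"):
        P = resid.copy()
        if mode == "shuffle":
            for row in P:
                rng.shuffle(row)
        elif batch_of_col is not None:
            for row in P:
                order = rng.permutation(len(blocks))
                src = np.concatenate([blocks[i] for i in order])
                row[:] = row[src]
        else:
            for row in P:
                row[:] = np.roll(row, int(rng.integers(1, n)))
        P = P + shared
        C0 = robust.bicor_matrix(P)
        C0 = np.nan_to_num(C0, nan=-1.0)
        np.fill_diagonal(C0, -1.0)
        for s, v in _greedy_clique_floors(C0, sizes).items():
            floors[s] = max(floors[s], v)
        cor0 = pd.DataFrame(C0 + np.eye(C0.shape[0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part0, _ = cut_modules(adjacency_tom(cor0, params), params)
        for c in part0.unique():
            if c == UNASSIGNED:
                continue
            members = part0.index[part0 == c]
            null_cliques.append((len(members),
                                 _mean_within_bicor(cor0, members)))
    for s in sizes:
        for s0, mw0 in null_cliques:
            if s0 >= s:
                floors[s] = max(floors[s], mw0)
    return floors


def _shared_profile_split(X: np.ndarray, fit_rows=None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Split rows into a rank-one shared component and residuals.

    The shared sample profile is the per-sample median of the standardised
    rows (restricted to ``fit_rows`` when given); each row's loading on it
    is its least-squares coefficient.  Rows unrelated to the profile get a
    near-zero loading, so for structure-free data the split is a no-op up
    to noise.
    """
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, keepdims=True)
    sd[~(sd > 0)] = 1.0
    Z = (X - mu) / sd
    if fit_rows is not None:
        Z = Z[fit_rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmedian(Z, axis=0)
    m = np.nan_to_num(m - np.nanmean(m))
    denom = float(m @ m)
    if denom <= 0:
        return np.zeros_like(X), X - mu
    Xc = np.where(np.isnan(X), 0.0, X - mu)
    obs = ~np.isnan(X)
    per_row = (obs * (m * m)).sum(axis=1)
    per_row[per_row <= 0] = denom
    load = (Xc @ m) / per_row
    shared_part = np.outer(load, m)
    return shared_part, X - mu - shared_part


def _greedy_clique_floors(C0: np.ndarray, sizes) -> dict:
    """Best greedy-clique mean correlation per size in a null matrix."""
    p = C0.shape[0]
    smax = min(max(sizes), p)
    iu = np.triu_indices(p, k=1)
    flat = C0[iu]
    k = min(_FLOOR_SEEDS, flat.size)
    top = np.argpartition(flat, -k)[-k:]
    seeds = np.stack([iu[0][top], iu[1][top]], axis=1)     # k x 2

    member = np.zeros((k, p), dtype=bool)
    member[np.arange(k)[:, None], seeds] = True
    colsum = C0[seeds[:, 0]] + C0[seeds[:, 1]]             # k x p
    pairsum = 2.0 * flat[top]
    best = {}
    size = 2
    if size in sizes:
        best[size] = float(pairsum.max() / (size * (size - 1)))
    while size < smax:
        cand = np.where(member, -np.inf, colsum)
        j = cand.argmax(axis=1)
        gain = cand[np.arange(k), j]
        pairsum = pairsum + 2.0 * gain
        member[np.arange(k), j] = True
        colsum = colsum + C0[j]
        size += 1
        if size in sizes:
            best[size] = float(pairsum.max() / (size * (size - 1)))
    for s in sizes:
        if s > p:
            best[s] = best.get(smax, float("-inf"))
    return best


def _mean_within_bicor(cor, members) -> float:
    if len(members) < 2:
        return float("-inf")
    sub = cor.loc[members, members].to_numpy(dtype=float)
    off = sub[~np.eye(len(members), dtype=bool)]
    if not np.isfinite(off).any():
        return float("-inf")
    return float(np.nanmean(off))


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    labels = list(labels)
    n = len(labels)
    if Z is None or Z.shape[0] != n - 1:
        raise ParameterError("linkage matrix does not match the label count")
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for i in range(Z.shape[0]):
        a, b, h = int(Z[i, 0]), int(Z[i, 1]), float(Z[i, 2])
        la = h - height[a]
        lb = h - height[b]
        node[n + i] = f"({node.pop(a)}:{la:g},{node.pop(b)}:{lb:g})"
        height[n + i] = h
    return node[n + Z.shape[0] - 1] + ";"


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score over observed samples; constant rows become zero."""
    X = df.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - mu) / sd
    Z[np.broadcast_to(~(sd > 0), Z.shape) & ~np.isnan(X)] = 0.0
    return pd.DataFrame(Z, index=df.index, columns=df.columns)


def _module_names(assignment: pd.Series) -> list:
    """Module names except M0, by decreasing size then first appearance."""
    sizes = assignment[assignment != UNASSIGNED].value_counts()
    first = {name: i for i, name in enumerate(pd.unique(assignment))}
    return sorted(sizes.index, key=lambda nm: (-sizes[nm], first[nm]))


def _rename_by_size(assignment: pd.Series) -> pd.Series:
    order = _module_names(assignment)
    mapping = {name: f"M{i}" for i, name in enumerate(order, start=1)}
    mapping[UNASSIGNED] = UNASSIGNED
    return assignment.map(mapping)
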