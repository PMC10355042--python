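"""Adaptive branch cutting of a hierarchical dendrogram with a PAM stage.

A fixed-height cut cannot separate nested, differently sized co-expression
modules, so branches are identified adaptively.  Branches are grown bottom
up through the merge sequence; whenever a branch reaches a judgement point
(it meets another sizeable branch, joins committed territory, or hits the
cut height) it qualifies as a module when

* it has at least ``min_size`` members,
* its *core scatter* — the average of its lowest internal merge heights,
  i.e. how tight its core is — is small relative to the tree's height range,
* its core sits well below the height at which it joins the rest of the
  tree (*core gap*), and
* there is genuine separation between the branch's own top merge and that
  joining height (*merge gap*), which distinguishes real branches from
  arbitrary stretches of a continuum of noise merges.

A failing branch is not discarded outright: its merge history is descended
recursively and every maximal sub-branch that qualifies at its own
attachment height is committed (a genuine module that has been accreting
stray elements keeps a tight core with a clear gap at the point where the
accretion started, while a structure-free branch fails at every level and
all of its members stay unassigned).  The ``deep_split`` setting (0-4)
follows the published mapping to (max core scatter, min gap) thresholds,
normalised by the range between the 5th-percentile merge height and the
cut height.  A partitioning-around-medoids stage then assigns unlabelled
elements that fall within a module's radius to the nearest module medoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = ["cut_tree_dynamic", "DynamicCutResult"]

# deep_split 0..4 -> maximum normalised core scatter (reference mapping);
# the minimum gap is (1 - max core scatter) * 3/4
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)

# the branch criteria are scale-free (normalised by the truncated height
# range), so they cannot by themselves tell a flat tree from a structured
# one; when the merge heights span less than this fraction of their own
# magnitude the dendrogram is flat and carries no modules
_FLAT_TREE_FLOOR = 0.01


@dataclass
class DynamicCutResult:
    labels: np.ndarray          # 0 = unassigned, 1..c = module index
    cut_height: float
    n_modules: int


class _Branch:
    """A growing branch: members, sorted internal merge heights, history."""

    __slots__ = ("members", "internal", "composite", "parts")

    def __init__(self, members, internal, composite=False, parts=None):
        self.members = members
        self.internal = internal          # sorted ascending
        self.composite = composite       # True once it contains committed clusters
        self.parts = parts               # (child_a, child_b, merge_height) or None


def cut_tree_dynamic(Z: np.ndarray, diss: np.ndarray, min_size: int = 5,
                     deep_split: int = 4, cut_height: float | None = None,
                     pam: bool = True) -> DynamicCutResult:
    """Adaptive module detection on a hierarchical tree of ``diss``.

    ``Z`` is a scipy linkage matrix for the ``n x n`` dissimilarity
    ``diss``.  ``cut_height`` defaults to 99% of the truncated height range
    (between the 5th-percentile and maximum merge heights); merges
    above it never fuse branches, they only finalise them.  Returns integer
    labels with 0 for unassigned elements, modules numbered by decreasing
    size.
    """
    if not 0 <= deep_split <= 4:
        raise ParameterError("deep_split must be in 0..4")
    if min_size < 2:
        raise ParameterError("min_size must be >= 2")
    n = diss.shape[0]
    if n < min_size:
        warnings.warn("fewer elements than min_size: all unassigned", stacklevel=2)
        return DynamicCutResult(labels=np.zeros(n, dtype=int), cut_height=0.0,
                                n_modules=0)

    clusters, top_cut = _single_pass(Z, n, min_size, deep_split, cut_height)

    labels = np.zeros(n, dtype=int)
    clusters.sort(key=lambda mem: (-len(mem), min(mem)))
    for ci, mem in enumerate(clusters, start=1):
        labels[mem] = ci

    if pam and clusters:
        labels = _pam_stage(labels, diss)
        # medoid reassignment may drain a module below the size floor;
        # such remnants are no longer valid modules
        kept = [c for c in range(1, len(clusters) + 1)
                if np.sum(labels == c) >= min_size]
        relabel = np.zeros(len(clusters) + 1, dtype=int)
        for new, old in enumerate(kept, start=1):
            relabel[old] = new
        labels = relabel[labels]
        n_modules = len(kept)
    else:
        n_modules = len(clusters)

    return DynamicCutResult(labels=labels, cut_height=float(top_cut),
                            n_modules=n_modules)


def _single_pass(Z: np.ndarray, n: int, min_size: int, deep_split: int,
                 cut_height: float | None) -> tuple[list[list[int]], float]:
    """One bottom-up pass over the merge sequence; returns (clusters, cut)."""
    heights = Z[:, 2]
    q05 = float(np.percentile(heights, 5))
    max_h = float(heights.max())
    if max_h <= 0 or (max_h - q05) < _FLAT_TREE_FLOOR * max_h:
        warnings.warn("dendrogram is flat (no hierarchical structure); "
                      "all elements unassigned", stacklevel=3)
        return [], float(max_h)
    if cut_height is None:
        # 99% of the truncated height range (published default)
        cut_height = q05 + 0.99 * (max_h - q05)
    ref = max(cut_height - q05, 1e-12)
    max_cs = _MAX_CORE_SCATTER[deep_split]
    min_gap = (1.0 - max_cs) * 3.0 / 4.0

    def qualifies(br: _Branch, attach: float, need_merge_gap: bool = True) -> bool:
        if len(br.members) < min_size:
            return False
        inner = br.internal
        k = min(len(inner), max(min_size - 1, 1))
        cs = float(np.mean(inner[:k])) if inner else q05
        if (cs - q05) / ref > max_cs:
            return False
        if (attach - cs) / ref < min_gap:            # core gap
            return False
        if not need_merge_gap:
            return True
        top = inner[-1] if inner else q05
        return (attach - top) / ref >= min_gap       # merge-separation gap

    clusters: list[list[int]] = []

    def finalize(br: _Branch, attach: float, lenient: bool = False) -> None:
        """Commit ``br`` or, failing that, its maximal qualifying sub-branches.

        When ``lenient``, the merge-separation gap is waived for the branch
        as a whole: a genuine branch that has been accreting stray elements
        keeps a tight low core but loses its gap.  This is only safe at
        joins with already-committed territory — in structure-free data no
        clusters are ever committed, so the lenient judgement is never
        reached there.
        """
        if not br.composite and lenient and qualifies(br, attach,
                                                      need_merge_gap=False):
            clusters.append(br.members)
            return
        stack = [(br, attach)]
        while stack:
            cur, at = stack.pop()
            if cur.composite:
                continue
            if qualifies(cur, at):
                clusters.append(cur.members)
            elif cur.parts is not None:
                a, b, h = cur.parts
                stack.append((a, h))
                stack.append((b, h))

    branch = {i: _Branch([i], []) for i in range(n)}
    for i in range(Z.shape[0]):
        a, b, h = int(Z[i, 0]), int(Z[i, 1]), float(Z[i, 2])
        A, B = branch.pop(a), branch.pop(b)
        node = n + i
        if A.composite or B.composite:
            # a growing branch joining committed territory is judged
            # leniently as a whole, then recursively on its sub-branches
            for br in (A, B):
                finalize(br, h, lenient=True)
            branch[node] = _Branch(A.members + B.members, [], composite=True)
            continue
        if h > cut_height:
            # branches never fuse above the cut
            for br in (A, B):
                finalize(br, h)
            branch[node] = _Branch(A.members + B.members, [], composite=True)
            continue
        qa, qb = qualifies(A, h), qualifies(B, h)
        if qa or qb:
            # every branch that stands out at this merge is committed; its
            # sibling is judged against the newly committed territory
            for br, q in ((A, qa), (B, qb)):
                if q:
                    clusters.append(br.members)
                else:
                    finalize(br, h, lenient=True)
            branch[node] = _Branch(A.members + B.members, [], composite=True)
        else:
            merged = sorted(A.internal + B.internal + [h])
            branch[node] = _Branch(A.members + B.members, merged,
                                   parts=(A, B, h))

    # anything still growing at the top is judged against the cut height
    for br in branch.values():
        finalize(br, cut_height)

    return clusters, float(cut_height)


def _pam_stage(labels: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Medoid-based cleanup of the branch assignment.

    Medoid = member minimising total within-module dissimilarity.  An
    element joins (or moves to) the nearest medoid's module only if it lies
    within that module's radius (its largest member-to-medoid
    dissimilarity): diffuse background elements stay unassigned, and an
    assigned element is treated as misplaced only when it is strictly
    closer to another medoid *and* fits inside that module's radius —
    topological overlap compresses distances toward large modules, so mere
    proximity to a bigger module's medoid is not evidence of misplacement.
    Ties break toward the larger module, then the lower module index.
    """
    labels = labels.copy()
    mods = [int(m) for m in np.unique(labels) if m != 0]
    medoid, radius, sizes = {}, {}, {}
    for mname in mods:
        idx = np.where(labels == mname)[0]
        sub = diss[np.ix_(idx, idx)]
        mi = idx[int(np.argmin(sub.sum(axis=1)))]
        medoid[mname] = mi
        radius[mname] = float(diss[idx, mi].max())
        sizes[mname] = len(idx)
    d_to_medoid = np.column_stack([diss[:, medoid[mname]] for mname in mods])
    # preference order for ties: larger module first, then lower index
    pref = sorted(range(len(mods)), key=lambda j: (-sizes[mods[j]], mods[j]))

    new = labels.copy()
    for i in range(len(labels)):
        dmin = d_to_medoid[i].min()
        best_j = next(j for j in pref if d_to_medoid[i, j] == dmin)
        target = mods[best_j]
        if labels[i] == 0:
            if dmin <= radius[target]:
                new[i] = target
        elif (dmin < d_to_medoid[i, mods.index(labels[i])]
              and dmin <= radius[target] and target != labels[i]):
            new[i] = target
    return new
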