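"""Clone-tree construction from cluster CCF vectors under the Sum and
Crossing Rules.

Under the infinite sites assumption, subclones nest: a child's cells are a
subset of its parent's in every sample.  Three constraints follow for CCF
vectors measured across samples (all checked with a noise tolerance ``tol``):

* ancestor containment: a parent's CCF is at least each child's in every
  sample (the "pigeonhole" implication of nesting);
* sum rule: sibling CCFs cannot add to more than their shared parent's CCF
  in any sample -- if they do, the two clusters must be collinear;
* crossing rule: if cluster B exceeds C in one sample and C exceeds B in
  another, B and C must be on branching (incomparable) lineages.

``enumerate_trees`` returns every rooted tree over the retained clusters that
satisfies all three, rooted at the unique truncal cluster.  Exhaustive
enumeration is used up to ``max_exhaustive`` clusters; a constraint-propagated
depth-first search above that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np


class TreeConstructionError(ValueError):
    def __init__(self, msg: str, certificate: Optional[dict] = None):
        super().__init__(msg)
        self.certificate = certificate or {}


@dataclass
class TreeBuildParams:
    tol: float = 0.05
    max_exhaustive: int = 7

    def validate(self) -> None:
        if not (0 <= self.tol < 0.5):
            raise ValueError("tol must lie in [0, 0.5)")


@dataclass
class CloneTree:
    root: int
    parent: dict[int, Optional[int]]
    admissible: bool = True

    def children(self, k: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == k)

    def ancestors(self, k: int) -> list[int]:
        out = []
        p = self.parent[k]
        while p is not None:
            out.append(p)
            p = self.parent[p]
        return out

    def descendants(self, k: int) -> set[int]:
        out: set[int] = set()
        stack = [k]
        while stack:
            n = stack.pop()
            for c in self.children(n):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        return a in self.ancestors(b)

    def parent_tuple(self, order: list[int]) -> tuple:
        return tuple(self.parent[k] if self.parent[k] is not None else -1 for k in order)


def check_sum_rule(
    parent_ccf: np.ndarray, children_ccfs: list[np.ndarray], tol: float = 0.05
) -> bool:
    """True (consistent) iff in no sample the children's CCFs sum past the parent's."""
    parent_ccf = np.asarray(parent_ccf, dtype=float)
    if not children_ccfs:
        return True
    kids = np.asarray(children_ccfs, dtype=float)
    if kids.shape[1] != parent_ccf.shape[0]:
        raise ValueError("mismatched sample sets between parent and children")
    return bool(np.all(kids.sum(axis=0) <= parent_ccf + tol))


def check_crossing_rule(ccf_b: np.ndarray, ccf_c: np.ndarray, tol: float = 0.05) -> bool:
    """True iff the pair is forced to branch: B > C in one sample, C > B in another."""
    b = np.asarray(ccf_b, dtype=float)
    c = np.asarray(ccf_c, dtype=float)
    if b.shape != c.shape:
        raise ValueError("mismatched sample sets")
    return bool(np.any(b > c + tol) and np.any(c > b + tol))


def _find_root(ccf: np.ndarray, tol: float) -> int:
    """The unique truncal cluster: within tol of the per-sample maximum everywhere."""
    mx = ccf.max(axis=0)
    cand = [k for k in range(ccf.shape[0]) if np.all(ccf[k] >= mx - tol)]
    if not cand:
        raise TreeConstructionError(
            "no truncal cluster: no cluster is maximal in every sample",
            {"per_sample_max": mx.tolist()},
        )
    # among candidates pick the one with highest mean CCF (ties: lowest id)
    return int(max(cand, key=lambda k: (ccf[k].mean(), -k)))


def _admissible(parent: dict[int, Optional[int]], ccf: np.ndarray, tol: float,
                crossing: np.ndarray) -> bool:
    n = ccf.shape[0]
    # ancestor containment + cycle safety along paths
    anc: dict[int, set[int]] = {}

    def ancestors_of(k: int) -> set[int]:
        if k in anc:
            return anc[k]
        p = parent[k]
        anc[k] = set() if p is None else {p} | ancestors_of(p)
        return anc[k]

    for k in range(n):
        p = parent[k]
        if p is not None and not np.all(ccf[p] >= ccf[k] - tol):
            return False
    # sum rule per sibling set
    for p in range(n):
        kids = [c for c in range(n) if parent[c] == p]
        if kids and not check_sum_rule(ccf[p], [ccf[c] for c in kids], tol):
            return False
    # crossing-forced pairs must be incomparable
    for b in range(n):
        for c in range(b + 1, n):
            if crossing[b, c] and (b in ancestors_of(c) or c in ancestors_of(b)):
                return False
    return True


def enumerate_trees(
    ccf_matrix: np.ndarray,
    params: Optional[TreeBuildParams] = None,
    cluster_ids: Optional[list[int]] = None,
) -> list[CloneTree]:
    """All admissible rooted clone trees for a clusters x samples CCF matrix.

    Raises with a violated-constraint certificate when no tree is admissible.
    """
    params = params or TreeBuildParams()
    params.validate()
    ccf = np.asarray(ccf_matrix, dtype=float)
    n = ccf.shape[0]
    ids = cluster_ids if cluster_ids is not None else list(range(n))
    tol = params.tol

    root = _find_root(ccf, tol)
    crossing = np.zeros((n, n), dtype=bool)
    for b in range(n):
        for c in range(b + 1, n):
            crossing[b, c] = crossing[c, b] = check_crossing_rule(ccf[b], ccf[c], tol)

    if n == 1:
        return [CloneTree(root=ids[0], parent={ids[0]: None})]

    others = [k for k in range(n) if k != root]
    # candidate parents per node: ancestor containment + not crossing-forced
    cand = {
        k: [
            p
            for p in range(n)
            if p != k and np.all(ccf[p] >= ccf[k] - tol) and not crossing[p, k]
        ]
        for k in others
    }
    for k, cs in cand.items():
        if not cs:
            raise TreeConstructionError(
                f"cluster {ids[k]} has no admissible parent",
                {"cluster": ids[k], "reason": "containment/crossing leaves no parent"},
            )

    trees: list[CloneTree] = []
    if n <= params.max_exhaustive:
        for combo in product(*(cand[k] for k in others)):
            parent = {root: None}
            parent.update({k: p for k, p in zip(others, combo)})
            if _has_cycle(parent):
                continue
            if _admissible(parent, ccf, tol, crossing):
                trees.append(
                    CloneTree(
                        root=ids[root],
                        parent={ids[k]: (None if p is None else ids[p]) for k, p in parent.items()},
                    )
                )
    else:
        # DFS over nodes ordered by descending mean CCF with incremental checks
        order = sorted(others, key=lambda k: (-ccf[k].mean(), k))
        parent: dict[int, Optional[int]] = {root: None}

        def placed_ok(k: int) -> bool:
            p = parent[k]
            kids = [c for c in parent if parent.get(c) == p and c != p]
            if not check_sum_rule(ccf[p], [ccf[c] for c in kids], tol):
                return False
            a = p
            while a is not None:
                if crossing[a, k]:
                    return False
                a = parent[a]
            return True

        def dfs(i: int) -> None:
            if i == len(order):
                pm = dict(parent)
                if _admissible(pm, ccf, tol, crossing):
                    trees.append(
                        CloneTree(
                            root=ids[root],
                            parent={ids[k]: (None if p is None else ids[p]) for k, p in pm.items()},
                        )
                    )
                return
            k = order[i]
            for p in cand[k]:
                if p not in parent:
                    continue
                parent[k] = p
                if placed_ok(k):
                    dfs(i + 1)
                del parent[k]

        dfs(0)

    if not trees:
        raise TreeConstructionError(
            "no admissible tree under sum/crossing/containment constraints",
            {"n_clusters": n, "tol": tol},
        )
    return trees


def _has_cycle(parent: dict[int, Optional[int]]) -> bool:
    for k in parent:
        seen = set()
        p = parent[k]
        while p is not None:
            if p in seen:
                return True
            seen.add(p)
            p = parent[p]
    return False


def select_tree(
    trees: list[CloneTree],
    reference: Optional[CloneTree] = None,
    mean_ccf: Optional[dict[int, float]] = None,
) -> CloneTree:
    """Pick one tree from the admissible set.

    With a reference tree (e.g. from prior whole-genome analysis), the
    admissible tree minimizing parent-assignment disagreement is chosen.
    Without one, the choice is deterministic: lexicographically smallest
    parent tuple after sorting clusters by descending mean CCF -- and flagged
    as arbitrary via ``admissible`` trees count in the caller.
    """
    if not trees:
        raise TreeConstructionError("empty admissible set")
    if reference is not None:
        def disagreement(t: CloneTree) -> int:
            return sum(
                1
                for k in t.parent
                if k in reference.parent and t.parent[k] != reference.parent[k]
            )
        return min(trees, key=lambda t: (disagreement(t), _lex_key(t, mean_ccf)))
    return min(trees, key=lambda t: _lex_key(t, mean_ccf))


def _lex_key(t: CloneTree, mean_ccf: Optional[dict[int, float]]) -> tuple:
    ids = list(t.parent)
    if mean_ccf:
        ids.sort(key=lambda k: (-mean_ccf.get(k, 0.0), k))
    else:
        ids.sort()
    return t.parent_tuple(ids)


def to_newick(tree: CloneTree, branch_lengths: Optional[dict[int, float]] = None) -> str:
    """Newick serialization: cluster ids as labels, mutation counts as lengths."""

    def render(k: int) -> str:
        kids = tree.children(k)
        label = str(k)
        bl = f":{branch_lengths[k]:g}" if branch_lengths and k in branch_lengths else ""
        if not kids:
            return f"{label}{bl}"
        return f"({','.join(render(c) for c in kids)}){label}{bl}"

    return render(tree.root) + ";"


def tree_to_json(tree: CloneTree) -> dict:
    return {
        "root": tree.root,
        "parent": {str(k): p for k, p in tree.parent.items()},
        "admissible": tree.admissible,
    }
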