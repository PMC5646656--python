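"""UPGMA clustering of a distance matrix into a rooted ultrametric tree.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the two clusters at minimum distance; the distance from the merged cluster
to any other is the size-weighted average of its parts,

    d(C1 u C2, X) = (|C1| d(C1,X) + |C2| d(C2,X)) / (|C1| + |C2|),

which makes every inter-cluster distance the plain arithmetic mean over leaf
pairs.  Each internal node sits at half its merge distance, so all leaves
are equidistant from the root (ultrametric) and every branch length is the
height difference between a node and its parent.

Ties in the minimum distance are broken deterministically: among equal-
minimum pairs the one with the lexicographically smallest (min id, max id)
is merged, where ids number leaves first (input order) and then internal
nodes in creation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np

__all__ = ["Dendrogram", "upgma", "branch_length", "cophenetic", "to_newick"]


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric merge tree.

    Node ids: ``0..n-1`` are leaves in input order; internal node ``n+k`` is
    created by the k-th merge.  ``merges[k] = (a, b, distance)`` records the
    two child node ids and the merge distance; the node's height is half
    that distance (leaves have height 0).
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        object.__setattr__(self, "merges", tuple(self.merges))
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        d_prev = 0.0
        for k, (a, b, d) in enumerate(self.merges):
            if d < d_prev - 1e-12:
                raise ValueError("merge distances must be non-decreasing")
            d_prev = max(d_prev, d)
            for c in (a, b):
                if not (0 <= c < n + k):
                    raise ValueError(f"merge {k} references unknown node {c}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def height(self, node: int) -> float:
        """Node height = half its merge distance; 0 for leaves."""
        n = self.n_leaves
        if 0 <= node < n:
            return 0.0
        return self.merges[node - n][2] / 2.0

    def children(self, node: int) -> tuple[int, int]:
        n = self.n_leaves
        if node < n:
            raise ValueError(f"leaf {node} has no children")
        a, b, _ = self.merges[node - n]
        return a, b

    def parent(self, node: int) -> Optional[int]:
        n = self.n_leaves
        for k, (a, b, _) in enumerate(self.merges):
            if node in (a, b):
                return n + k
        return None

    def leaf_set(self, node: int) -> frozenset[str]:
        """Labels of the leaves under ``node``."""
        n = self.n_leaves
        if node < n:
            return frozenset((self.leaves[node],))
        a, b = self.children(node)
        return self.leaf_set(a) | self.leaf_set(b)

    def find_clade(self, labels: Sequence[str]) -> int:
        """Node whose leaf set equals ``labels`` exactly; raises if absent."""
        want = frozenset(labels)
        for node in range(self.n_leaves + len(self.merges)):
            if self.leaf_set(node) == want:
                return node
        raise KeyError(f"no clade with exactly {sorted(want)}")


def upgma(distance_matrix: np.ndarray, labels: Optional[Sequence[str]] = None) -> Dendrogram:
    """Agglomerate a symmetric zero-diagonal distance matrix by UPGMA."""
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape != (n, n) or n < 2:
        raise ValueError("distance matrix must be square with >= 2 taxa")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    labels = tuple(labels)
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")

    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        # deterministic tie rule: minimize (distance, min id, max id)
        best = min(
            ((dist[frozenset((a, b))], a, b)
             for i, a in enumerate(active) for b in active[i + 1:]),
            key=lambda t: (t[0], min(t[1], t[2]), max(t[1], t[2])),
        )
        d, a, b = best
        a, b = min(a, b), max(a, b)
        new = next_id
        next_id += 1
        for x in active:
            if x in (a, b):
                continue
            da = dist.pop(frozenset((x, a)))
            db = dist.pop(frozenset((x, b)))
            dist[frozenset((x, new))] = (size[a] * da + size[b] * db) / (size[a] + size[b])
        dist.pop(frozenset((a, b)))
        size[new] = size[a] + size[b]
        merges.append((a, b, d))
        active = [x for x in active if x not in (a, b)] + [new]
    return Dendrogram(leaves=labels, merges=tuple(merges))


def branch_length(dendrogram: Dendrogram, node: int) -> float:
    """Length of the branch above ``node``: parent height minus node height.

    The root has no parent; its branch length is defined as 0 (with a
    warning), so totals over a tree are well defined.
    """
    parent = dendrogram.parent(node)
    if parent is None:
        warnings.warn("root has no parent branch; returning 0", stacklevel=2)
        return 0.0
    return dendrogram.height(parent) - dendrogram.height(node)


def cophenetic(dendrogram: Dendrogram) -> np.ndarray:
    """Tree-induced leaf distances: 2 x height of the lowest common ancestor."""
    n = dendrogram.n_leaves
    # leaf sets per internal node, in merge (height) order
    coph = np.zeros((n, n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, d) in enumerate(dendrogram.merges):
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = d  # 2 * height(n + k)
        members[n + k] = members.pop(a) + members.pop(b)
    return coph


def to_newick(dendrogram: Dendrogram, precision: int = 6) -> str:
    """Serialize as rooted Newick with branch lengths.

    Children of every internal node are ordered by their earliest leaf
    index, so output is deterministic regardless of merge bookkeeping.
    Labels containing whitespace or Newick metacharacters are single-quoted.
    """
    n = dendrogram.n_leaves

    def quote(label: str) -> str:
        if any(ch in label for ch in " \t()[]:;,'"):
            return "'" + label.replace("'", "''") + "'"
        return label

    # earliest leaf index per node, bottom-up
    first_leaf_idx: dict[int, int] = {i: i for i in range(n)}
    for k, (a, b, _) in enumerate(dendrogram.merges):
        first_leaf_idx[n + k] = min(first_leaf_idx[a], first_leaf_idx[b])

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def render(node: int, parent_height: float) -> str:
        blen = parent_height - dendrogram.height(node)
        if node < n:
            return f"{quote(dendrogram.leaves[node])}:{fmt(blen)}"
        a, b = dendrogram.children(node)
        if first_leaf_idx[a] > first_leaf_idx[b]:
            a, b = b, a
        h = dendrogram.height(node)
        return f"({render(a, h)},{render(b, h)}):{fmt(blen)}"

    root = dendrogram.root
    a, b = dendrogram.children(root)
    if first_leaf_idx[a] > first_leaf_idx[b]:
        a, b = b, a
    h = dendrogram.height(root)
    return f"({render(a, h)},{render(b, h)});"


def ascii_tree(dendrogram: Dendrogram, width: int = 60) -> str:
    """Plain-text rendering of the dendrogram, leaves left-aligned."""
    lines = []
    root_h = dendrogram.height(dendrogram.root)

    def walk(node: int, prefix: str, is_last: bool) -> None:
        h = dendrogram.height(node)
        connector = "`-- " if is_last else "|-- "
        if node < dendrogram.n_leaves:
            lines.append(f"{prefix}{connector}{dendrogram.leaves[node]}")
        else:
            lines.append(f"{prefix}{connector}* h={h:.4f}")
            a, b = dendrogram.children(node)
            ext = "    " if is_last else "|   "
            walk(a, prefix + ext, False)
            walk(b, prefix + ext, True)

    lines.append(f"root h={root_h:.4f}")
    a, b = dendrogram.children(dendrogram.root)
    walk(a, "", False)
    walk(b, "", True)
    return "\n".join(lines)
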