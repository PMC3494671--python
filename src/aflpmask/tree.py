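"""Unrooted phylogenetic trees and neighbor-joining.

The tree container is deliberately minimal: an adjacency map with branch
lengths and labelled leaves.  It supports exactly what matrix evaluation
needs — internal-edge enumeration, leaf bipartitions for bootstrap support,
total/internal length sums for stemminess, and newick round-tripping.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .matrix import AFLPError


class TreeError(AFLPError):
    pass


@dataclass(eq=False)
class PhyloTree:
    """Unrooted tree: adjacency with non-negative branch lengths, labelled leaves."""

    _adj: dict[int, dict[int, float]] = field(default_factory=dict)
    leaf_labels: dict[int, str] = field(default_factory=dict)

    # -- construction ---------------------------------------------------
    def add_node(self, label: str | None = None) -> int:
        nid = (max(self._adj) + 1) if self._adj else 0
        self._adj[nid] = {}
        if label is not None:
            if label in self.leaf_labels.values():
                raise TreeError(f"duplicate leaf label {label!r}")
            self.leaf_labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        if v in self._adj[u]:
            raise TreeError("edge already present")
        self._adj[u][v] = float(length)
        self._adj[v][u] = float(length)

    def set_length(self, u: int, v: int, length: float) -> None:
        self._adj[u][v] = float(length)
        self._adj[v][u] = float(length)

    # -- queries --------------------------------------------------------
    def is_leaf(self, node: int) -> bool:
        return node in self.leaf_labels

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def nodes(self) -> list[int]:
        return list(self._adj)

    def edges(self) -> list[tuple[int, int, float]]:
        return [(u, v, l) for u in self._adj for v, l in self._adj[u].items() if u < v]

    def internal_edges(self) -> list[tuple[int, int, float]]:
        """Edges not incident to a leaf."""
        return [
            (u, v, l)
            for u, v, l in self.edges()
            if not self.is_leaf(u) and not self.is_leaf(v)
        ]

    def total_length(self) -> float:
        return sum(l for _, _, l in self.edges())

    def internal_length(self) -> float:
        return sum(l for _, _, l in self.internal_edges())

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaf labels on the v-side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        labels: set[str] = set()
        while stack:
            node = stack.pop()
            if self.is_leaf(node):
                labels.add(self.leaf_labels[node])
            for nb in self._adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return labels

    def bipartition(self, u: int, v: int) -> frozenset[str]:
        """Canonical leaf bipartition of an edge: the side not containing the
        alphabetically smallest leaf."""
        ref = min(self.leaf_labels.values())
        side = self._side_leaves(u, v)
        if ref in side:
            side = set(self.leaf_labels.values()) - side
        return frozenset(side)

    def internal_bipartitions(self) -> dict[frozenset[str], tuple[int, int]]:
        return {self.bipartition(u, v): (u, v) for u, v, _ in self.internal_edges()}

    def clamp_negative_lengths(self) -> int:
        """Set negative branch lengths to zero; returns how many were clamped."""
        n = 0
        for u, v, l in self.edges():
            if l < 0:
                self.set_length(u, v, 0.0)
                n += 1
        return n

    # -- newick ---------------------------------------------------------
    def to_newick(self, support: dict[frozenset[str], float] | None = None) -> str:
        """Newick string, deterministically rooted at the internal node next to
        the alphabetically smallest leaf; optional bootstrap percentages become
        internal node labels."""
        if self.n_leaves < 2:
            raise TreeError("need at least two leaves to write newick")
        ref_leaf = min(self.leaf_labels, key=lambda n: self.leaf_labels[n])
        root = next(iter(self._adj[ref_leaf]))

        def min_label(node: int, parent: int) -> str:
            if self.is_leaf(node):
                return self.leaf_labels[node]
            return min(min_label(nb, node) for nb in self._adj[node] if nb != parent)

        def render(node: int, parent: int) -> str:
            length = self._adj[node][parent]
            if self.is_leaf(node):
                return f"{_newick_quote(self.leaf_labels[node])}:{length:.10g}"
            children = sorted(
                (nb for nb in self._adj[node] if nb != parent),
                key=lambda nb: min_label(nb, node),
            )
            inner = ",".join(render(c, node) for c in children)
            label = ""
            if support is not None:
                bip = self.bipartition(parent, node)
                if bip in support:
                    label = f"{support[bip]:.4g}"
            return f"({inner}){label}:{length:.10g}"

        children = sorted(self._adj[root], key=lambda nb: min_label(nb, root))
        inner = ",".join(render(c, root) for c in children)
        return f"({inner});"


def _newick_quote(label: str) -> str:
    if any(ch in label for ch in " '(){}[],;:"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, path: str, support=None) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(support=support) + "\n")


def read_newick(source: str) -> PhyloTree:
    """Parse a newick string (or file path) into a PhyloTree via dendropy.

    A rooted bifurcation at the top is suppressed so the result is unrooted.
    """
    import dendropy

    if "(" not in source:
        with open(source) as fh:
            source = fh.read()
    dtree = dendropy.Tree.get(data=source, schema="newick")
    dtree.suppress_unifurcations()
    tree = PhyloTree()
    index: dict[object, int] = {}
    for node in dtree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else None
        index[node] = tree.add_node(label)
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            length = node.edge.length if node.edge.length is not None else 0.0
            tree.add_edge(index[node.parent_node], index[node], length)
    # suppress a degree-2 root left over from the rooted representation
    root = index[dtree.seed_node]
    if len(tree._adj[root]) == 2 and not tree.is_leaf(root):
        (a, la), (b, lb) = tree._adj[root].items()
        del tree._adj[a][root]
        del tree._adj[b][root]
        del tree._adj[root]
        tree._adj[a][b] = la + lb
        tree._adj[b][a] = la + lb
    return tree


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(labels: list[str], d: np.ndarray, clamp: bool = True) -> PhyloTree:
    """Standard neighbor-joining agglomeration on a distance matrix.

    Join selection uses the Q criterion; ties are broken by the
    lexicographically smallest pair of (minimum contained) labels, making the
    result deterministic.  Negative estimated branch lengths are recorded and
    then clamped to zero unless ``clamp`` is false.
    """
    n = len(labels)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    D = np.asarray(d, dtype=float).copy()
    if D.shape != (n, n):
        raise TreeError("distance matrix shape mismatch")
    if not np.all(np.isfinite(D)):
        raise TreeError("non-finite distances")

    tree = PhyloTree()
    nodes = [tree.add_node(lab) for lab in labels]
    minlab = list(labels)

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        # R_i + R_j first: keeps Q exactly symmetric under float arithmetic
        Q = (m - 2) * D - (R[:, None] + R[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q == qmin)
        best = min(
            ((i, j) for i, j in cand if i < j),
            key=lambda ij: tuple(sorted((minlab[ij[0]], minlab[ij[1]]))),
        )
        i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (m - 2))
        lj = dij - li
        parent = tree.add_node()
        tree.add_edge(parent, nodes[i], li)
        tree.add_edge(parent, nodes[j], lj)
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([np.column_stack([D[np.ix_(keep, keep)], dk[keep]]),
                       np.append(dk[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [parent]
        minlab = [minlab[k] for k in keep] + [min(minlab[i], minlab[j])]

    # final three-point attachment
    (x, y, z) = range(3)
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    center = tree.add_node()
    tree.add_edge(center, nodes[x], lx)
    tree.add_edge(center, nodes[y], ly)
    tree.add_edge(center, nodes[z], lz)
    if clamp:
        tree.clamp_negative_lengths()
    return tree
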