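"""Neighbor-joining trees from distance matrices, and allele-frequency PCA.

The NJ implementation follows Saitou & Nei's agglomeration with the
Studier-Keppler Q-criterion, the O(n^3) formulation used throughout
phylogenetics.  It is deterministic: Q-ties are broken by the lowest
(row, column) index pair, and negative branch lengths (which arise on
non-additive matrices) are clamped to zero with the deficit transferred to
the sister branch, preserving the path length between the joined pair.

PCA operates on the population x locus matrix of insertion-allele
frequencies (the deletion column is perfectly anticollinear and carries no
extra information): columns are centered, not scaled, and components come
from the singular-value decomposition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .genotype_model import FreqTable
from .population_comparison import DistanceMatrix

__all__ = [
    "TreeNode",
    "Tree",
    "PcaResult",
    "neighbor_joining",
    "to_newick",
    "nearest_neighbor",
    "pca",
]


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree represented by an arbitrary internal anchor node."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by sorted label pair."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node):
            # returns {leaf_label: distance to node}
            if node.is_leaf:
                return {node.label: 0.0}
            below: list[dict[str, float]] = []
            for child, bl in node.children:
                sub = walk(child)
                below.append({k: v + bl for k, v in sub.items()})
            merged: dict[str, float] = {}
            for i, di in enumerate(below):
                for j in range(i + 1, len(below)):
                    for la, va in di.items():
                        for lb, vb in below[j].items():
                            key = tuple(sorted((la, lb)))
                            dists[key] = va + vb
                merged.update(di)
            return merged

        walk(self.root)
        return dists

    def neighbor_sets(self) -> set[frozenset[str]]:
        """Leaf bipartitions (splits) induced by internal edges.

        Topology fingerprint: two trees on the same leaves are isomorphic
        iff their split sets agree.
        """
        all_leaves = frozenset(self.leaf_labels())
        splits: set[frozenset[str]] = set()

        def walk(node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            under = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_leaves) - 1:
                    splits.add(min(side, all_leaves - side,
                                   key=lambda s: (len(s), sorted(s))))
                under = under | side
            return under

        walk(self.root)
        return splits


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices."""
    k = len(dm.labels)
    if k < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [TreeNode(label=lab) for lab in dm.labels]
    active = list(range(k))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest flat index = lowest (row, col)
        flat = int(np.argmin(q))
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        bi = 0.5 * dij + (totals[i_loc] - totals[j_loc]) / (2 * (m - 2))
        bj = dij - bi
        # clamp negatives, transferring the deficit to the sister branch so
        # the i--j path length is preserved
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        # distances from the new node
        newrow = np.zeros(d.shape[0] + 1)
        for l_loc, l in enumerate(active):
            if l in (i, j):
                continue
            newrow[l] = 0.5 * (d[i, l] + d[j, l] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = newrow[:-1]
        d[:-1, -1] = newrow[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j = active
    # final join: attach one remaining node to the other with the leftover
    # branch, yielding the customary unrooted representation
    last = max(d[i, j], 0.0)
    if nodes[j].is_leaf and not nodes[i].is_leaf:
        i, j = j, i
    anchor = nodes[j]
    anchor.children.append((nodes[i], last))
    return Tree(root=anchor)


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(t: Tree, precision: int = 10) -> str:
    """Serialize with branch lengths; labels quoted per Newick convention."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.label or "")
        inner = ",".join(
            f"{render(child)}:{bl:.{precision}g}" for child, bl in node.children
        )
        return f"({inner})"

    root = t.root
    if root.is_leaf:
        raise ValueError("cannot serialize a single-leaf tree")
    parts = [f"{render(c)}:{bl:.{precision}g}" for c, bl in root.children]
    if root.label:
        return f"({','.join(parts)}){_quote(root.label)};"
    return f"({','.join(parts)});"


def nearest_neighbor(dm: DistanceMatrix, label: str,
                     rank: int = 1) -> tuple[str, float]:
    """The rank-th closest other population; ties broken by label order."""
    if label not in dm.labels:
        raise KeyError(f"label {label!r} not in matrix")
    if not (1 <= rank < len(dm.labels)):
        raise ValueError(f"rank must be in [1, {len(dm.labels) - 1}]")
    i = dm.labels.index(label)
    others = [(float(dm.d[i, j]), dm.labels[j])
              for j in range(len(dm.labels)) if j != i]
    others.sort(key=lambda t: (t[0], t[1]))
    dist, lab = others[rank - 1]
    return lab, dist


@dataclass
class PcaResult:
    populations: list[str]
    scores: np.ndarray       # (n_populations, n_components)
    loadings: np.ndarray     # (n_loci, n_components)
    explained: np.ndarray    # fraction of total variance per component

    def __post_init__(self) -> None:
        if np.any(self.explained < -1e-12):
            raise ValueError("explained variance fractions must be >= 0")
        if self.explained.sum() > 1 + 1e-9:
            raise ValueError("explained variance fractions exceed 1")


def pca(ft: FreqTable) -> PcaResult:
    """PCA of the centered population x locus DIP+ frequency matrix.

    Columns are centered but not scaled; scores and loadings come from the
    SVD of the centered matrix.  Component signs are fixed so the largest
    |loading| of each component is positive (determinism across BLAS
    libraries).
    """
    if len(ft.populations) < 2:
        raise ValueError("PCA needs at least 2 populations")
    x = ft.p_ins_matrix()
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign convention
    for c in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u * s
    total = (s ** 2).sum()
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)
    return PcaResult(populations=list(ft.populations), scores=scores,
                     loadings=vt.T, explained=explained)
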