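"""Tumor transition-state detection from copy-number phylogenies.

Cells are related by a neighbor-joining tree over Euclidean distances
between their copy-number profiles; the tree is cut into clades and each
clade's mixture of normal- versus cancer-origin cells is scored with the
binary Shannon entropy

    H = -p_n log2 p_n - p_c log2 p_c,   p_n = N_n / (N_n + N_c),

so a pure clade scores 0 and a 50/50 clade scores 1 bit.  Clades whose
entropy reaches the threshold (default 0.8 bits, which a 3:1 mixture just
clears) are called the transition state: the region of the phylogeny where
normal- and cancer-origin cells still coexist.

The critical-transition index supplements the call on expression data: the
ratio of mean absolute gene-gene correlation to mean absolute cell-cell
correlation, which rises as a cell population approaches a tipping point
(coordinated genes, decohering cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "CladeCount",
    "TransitionCall",
    "build_nj_tree",
    "partition_clades",
    "clade_entropy",
    "count_clades",
    "call_transition_state",
    "critical_transition_index",
    "transition_state_from_cnv",
]


@dataclass(frozen=True)
class CladeCount:
    """Origin composition of one clade."""

    clade_id: int
    n_normal: int
    n_cancer: int
    entropy: float
    members: tuple[str, ...] = ()


@dataclass(frozen=True)
class TransitionCall:
    """Clades flagged as the transition state."""

    flagged: tuple[int, ...]
    cells: tuple[str, ...]
    threshold: float
    clades: tuple[CladeCount, ...]


def build_nj_tree(cnv: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree over Euclidean cell-cell CNV distances.

    Leaf names are the matrix index (cell ids).  Negative branch lengths,
    which plain NJ can produce, are clamped to zero.
    """
    if cnv.shape[0] < 4:
        raise ValueError(f"need >= 4 cells for a meaningful tree, got {cnv.shape[0]}")
    if cnv.isna().any().any():
        raise ValueError("CNV matrix contains missing values")
    dist = squareform(pdist(cnv.to_numpy(), metric="euclidean"))
    dm = DistanceMatrix(dist, ids=[str(i) for i in cnv.index])
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def partition_clades(tree: TreeNode, n_clades: int) -> dict[str, int]:
    """Cut the tree into ``n_clades`` leaf groups by longest-edge removal.

    Edges are removed greedily in order of decreasing branch length (ties by
    traversal order); a removal only counts when both sides of the edge
    retain at least one leaf, so each accepted cut splits one clade in two.
    Returns leaf name -> clade id (ids numbered 0.. in leaf order).
    """
    import networkx as nx

    leaves = [n.name for n in tree.tips()]
    if not 1 <= n_clades <= len(leaves):
        raise ValueError(
            f"n_clades must be in [1, {len(leaves)}], got {n_clades}")

    g = nx.Graph()
    counter = [0]
    names: dict = {}

    def node_key(node):
        if node not in names:
            names[node] = node.name if node.is_tip() else f"__int{counter[0]}"
            counter[0] += 1
        return names[node]

    edges = []
    for node in tree.traverse(include_self=True):
        for child in node.children:
            u, v = node_key(node), node_key(child)
            length = child.length or 0.0
            g.add_edge(u, v)
            edges.append((length, u, v))
    leaf_set = set(leaves)

    edges.sort(key=lambda e: -e[0])
    n_groups = 1
    for _, u, v in edges:
        if n_groups >= n_clades:
            break
        g.remove_edge(u, v)
        side_u = nx.node_connected_component(g, u)
        side_v = nx.node_connected_component(g, v)
        if side_u & leaf_set and side_v & leaf_set:
            n_groups += 1
        else:
            g.add_edge(u, v)
    assignment: dict[str, int] = {}
    next_id = 0
    for leaf in leaves:
        if leaf in assignment:
            continue
        comp = nx.node_connected_component(g, leaf)
        for other in leaves:
            if other in comp and other not in assignment:
                assignment[other] = next_id
        next_id += 1
    return assignment


def clade_entropy(n_normal: int, n_cancer: int) -> float:
    """Binary Shannon entropy (bits) of a clade's origin mixture."""
    if n_normal < 0 or n_cancer < 0:
        raise ValueError("counts must be non-negative")
    total = n_normal + n_cancer
    if total < 1:
        raise ValueError("clade must contain at least one cell")
    h = 0.0
    for count in (n_normal, n_cancer):
        p = count / total
        if p > 0:
            h -= p * np.log2(p)
    return float(h)


def count_clades(assignment: dict[str, int], labels: pd.Series
                 ) -> list[CladeCount]:
    """Tally origins per clade and score each with clade_entropy."""
    clades: dict[int, list[str]] = {}
    for cell, cid in assignment.items():
        clades.setdefault(cid, []).append(cell)
    out = []
    for cid in sorted(clades):
        members = clades[cid]
        n_n = sum(1 for c in members if labels[c] == "normal")
        n_c = sum(1 for c in members if labels[c] == "cancer")
        out.append(CladeCount(cid, n_n, n_c, clade_entropy(n_n, n_c),
                              tuple(members)))
    return out


def call_transition_state(clade_counts: list[CladeCount],
                          threshold: float = 0.8) -> TransitionCall:
    """Flag clades with entropy >= threshold as the transition state."""
    if not clade_counts:
        raise ValueError("no clades supplied")
    flagged = tuple(c.clade_id for c in clade_counts if c.entropy >= threshold)
    cells = tuple(cell for c in clade_counts if c.clade_id in flagged
                  for cell in c.members)
    return TransitionCall(flagged, cells, threshold, tuple(clade_counts))


def critical_transition_index(expr: pd.DataFrame) -> float:
    """Mean |gene-gene Pearson r| over mean |cell-cell Pearson r|.

    ``expr`` is cells x genes; constant genes and constant cells are
    excluded before the respective correlation, and diagonals are excluded
    from both means.
    """
    x = expr.to_numpy(dtype=float)
    if x.shape[0] < 3 or x.shape[1] < 3:
        raise ValueError("need at least 3 cells and 3 genes")
    gene_keep = x.std(axis=0) > 0
    cell_keep = x.std(axis=1) > 0
    if gene_keep.sum() < 2 or cell_keep.sum() < 2:
        raise ValueError("matrix too degenerate for correlation")
    gg = np.corrcoef(x[:, gene_keep], rowvar=False)
    cc = np.corrcoef(x[cell_keep, :], rowvar=True)

    def _mean_offdiag(c):
        n = c.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return float(np.abs(c[mask]).mean())

    return _mean_offdiag(gg) / _mean_offdiag(cc)


def transition_state_from_cnv(cnv: pd.DataFrame, labels: pd.Series,
                              n_clades: int = 30, threshold: float = 0.8,
                              tree: TreeNode | None = None,
                              ) -> tuple[TransitionCall, TreeNode, dict[str, int]]:
    """CNV matrix -> tree -> clades -> entropy -> transition call."""
    if tree is None:
        tree = build_nj_tree(cnv)
    n_clades = min(n_clades, len(list(tree.tips())))
    assignment = partition_clades(tree, n_clades)
    counts = count_clades(assignment, labels)
    return call_transition_state(counts, threshold), tree, assignment
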