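"""GRN skeleton construction from pseudotime-ordered expression.

Takes a prior signed interaction network plus a cell-by-gene expression
matrix ordered by pseudotime and produces the pruned, feedback-restricted
skeleton used for Boolean rule inference:

1. per-gene moving-average smoothing along pseudotime (window < 10% of cells),
2. per-gene binarization by two-means clustering of the smoothed values,
3. pruning of prior edges by |Spearman rho| >= cutoff (default 0.7), with the
   edge sign taken from the sign of rho,
4. iterative removal of terminal (outdegree-0) nodes,
5. restriction to strongly connected components of size >= 2 (the feedback
   core that can support multistability), keeping edges among retained nodes,
6. self-activation added to any node left without an activating input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import SignedNetwork

__all__ = [
    "TrajectoryData",
    "smooth",
    "smooth_matrix",
    "binarize",
    "binarize_matrix",
    "prune_by_correlation",
    "remove_terminal_nodes",
    "extract_scc",
    "add_self_activation",
    "build_skeleton",
    "default_window",
]


@dataclass
class TrajectoryData:
    """Pseudotime-ordered cells with raw, smoothed and binarized expression.

    ``raw``/``smoothed``/``binarized`` are cells-x-genes DataFrames sharing
    index (cell ids, in pseudotime order) and columns (genes).  ``labels``
    maps cells to their origin ('normal'/'cancer'); ``backbone`` holds the
    noiseless binary path when the trajectory is synthetic.
    """

    cells: tuple[str, ...]
    pseudotime: np.ndarray
    raw: pd.DataFrame
    smoothed: pd.DataFrame | None = None
    binarized: pd.DataFrame | None = None
    labels: pd.Series | None = None
    backbone: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        pt = np.asarray(self.pseudotime, dtype=float)
        if np.any(np.diff(pt) < 0):
            raise ValueError("pseudotime must be non-decreasing")
        for name in ("smoothed", "binarized"):
            m = getattr(self, name)
            if m is not None and m.shape != self.raw.shape:
                raise ValueError(f"{name} matrix shape differs from raw")
        if self.binarized is not None:
            vals = self.binarized.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("binarized entries must be 0/1")

    @property
    def n_cells(self) -> int:
        return self.raw.shape[0]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.raw.columns)


def default_window(n_cells: int) -> int:
    """Default smoothing window: 8% of the cell count (inside the <10% bound)."""
    return max(1, int(np.floor(0.08 * n_cells)))


def smooth(series, window: int) -> np.ndarray:
    """Centered moving average with truncated edge windows.

    ``window`` is the full width; at the edges the window is clipped to the
    available cells so the output has the input's length.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    half = window // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1) if window % 2 else min(n, i + half)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def smooth_matrix(raw: pd.DataFrame, window: int) -> pd.DataFrame:
    """Smooth every gene column along the pseudotime order."""
    out = {g: smooth(raw[g].to_numpy(), window) for g in raw.columns}
    return pd.DataFrame(out, index=raw.index)[raw.columns]


def binarize(series) -> tuple[np.ndarray, bool]:
    """Two-means binarization of one gene's smoothed profile.

    Finds the split of the sorted values minimizing total within-cluster
    variance (the global optimum of 1-D k-means with k=2); the cluster with
    the higher mean becomes 1.  A constant series cannot be split: it maps
    to all zeros with ``degenerate=True``.

    Returns (binary array, degenerate flag).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2 or np.all(x == x[0]):
        return np.zeros(n, dtype=int), True
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.cumsum(xs)
    csum2 = np.cumsum(xs ** 2)
    best_cost, best_split = np.inf, 1
    for split in range(1, n):       # low cluster = xs[:split]
        s1, s2 = csum[split - 1], csum[-1] - csum[split - 1]
        q1, q2 = csum2[split - 1], csum2[-1] - csum2[split - 1]
        cost = (q1 - s1 ** 2 / split) + (q2 - s2 ** 2 / (n - split))
        if cost < best_cost - 1e-12:
            best_cost, best_split = cost, split
    threshold = (xs[best_split - 1] + xs[best_split]) / 2.0
    return (x > threshold).astype(int), False


def binarize_matrix(smoothed: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Binarize every gene; returns (matrix, list of degenerate genes)."""
    out = {}
    degenerate = []
    for g in smoothed.columns:
        b, flag = binarize(smoothed[g].to_numpy())
        out[g] = b
        if flag:
            degenerate.append(g)
    if degenerate:
        warnings.warn(
            f"constant expression for {len(degenerate)} gene(s) "
            f"({', '.join(degenerate[:5])}...); binarized to all zeros",
            stacklevel=2)
    return pd.DataFrame(out, index=smoothed.index)[smoothed.columns], degenerate


class EmptyNetworkError(ValueError):
    """No edges survive correlation pruning."""


class NoFeedbackError(ValueError):
    """The pruned network contains no strongly connected component >= 2."""


def prune_by_correlation(prior: SignedNetwork, smoothed: pd.DataFrame,
                         cutoff: float = 0.7) -> SignedNetwork:
    """Keep prior edges whose endpoints have |Spearman rho| >= cutoff.

    The retained edge's sign is the sign of rho (positive correlation =
    activation, negative = inhibition), overriding the prior sign; conflicts
    are reported as warnings.  Prior nodes absent from the matrix are dropped.
    """
    genes = set(smoothed.columns)
    kept_nodes = [n for n in prior.nodes if n in genes]
    node_set = set(kept_nodes)
    edges: dict[tuple[str, str], int] = {}
    conflicts = []
    for (u, v), prior_sign in prior.edges.items():
        if u not in node_set or v not in node_set:
            continue
        if u == v:
            rho = 1.0   # self-correlation is identically 1
        else:
            rho = stats.spearmanr(smoothed[u], smoothed[v]).statistic
        if not np.isfinite(rho) or abs(rho) < cutoff:
            continue
        sign = 1 if rho > 0 else -1
        if sign != prior_sign:
            conflicts.append((u, v))
        edges[(u, v)] = sign
    if not edges:
        raise EmptyNetworkError(
            f"no prior edge reaches |rho| >= {cutoff}; nothing to infer")
    if conflicts:
        warnings.warn(
            f"{len(conflicts)} edge sign(s) overridden by data correlation: "
            f"{conflicts[:5]}", stacklevel=2)
    used = {u for u, _ in edges} | {v for _, v in edges}
    return SignedNetwork(tuple(n for n in kept_nodes if n in used), edges)


def remove_terminal_nodes(net: SignedNetwork) -> SignedNetwork:
    """Iteratively delete outdegree-0 nodes (self-loops count as outgoing)."""
    g = net.to_networkx()
    while True:
        dead = [n for n in g.nodes if g.out_degree(n) == 0]
        if not dead:
            break
        g.remove_nodes_from(dead)
    keep = set(g.nodes)
    return net.subnetwork(keep)


def extract_scc(net: SignedNetwork) -> SignedNetwork:
    """Restrict to the union of strongly connected components of size >= 2.

    All edges among retained nodes survive, including bridges between
    components.  Raises :class:`NoFeedbackError` when no such component
    exists (a DAG cannot support multistability).
    """
    g = net.to_networkx()
    keep: set[str] = set()
    for comp in nx.strongly_connected_components(g):
        if len(comp) >= 2:
            keep |= comp
    if not keep:
        raise NoFeedbackError("no feedback loop (SCC of size >= 2) in network")
    return net.subnetwork(keep)


def add_self_activation(net: SignedNetwork) -> SignedNetwork:
    """Add a positive self-loop to every node lacking an activating input."""
    edges = dict(net.edges)
    for n in net.nodes:
        has_activation = any(v == n and s == 1 for (u, v), s in edges.items())
        if not has_activation:
            edges[(n, n)] = 1
    return SignedNetwork(net.nodes, edges)


def build_skeleton(prior: SignedNetwork, raw: pd.DataFrame,
                   window: int | None = None, cutoff: float = 0.7,
                   ) -> tuple[SignedNetwork, pd.DataFrame, pd.DataFrame]:
    """Full skeleton pipeline: smooth -> prune -> de-terminal -> SCC -> self-act.

    Returns (skeleton, smoothed matrix, binarized matrix); the matrices cover
    all genes of ``raw`` so callers can subset as needed.
    """
    if window is None:
        window = default_window(raw.shape[0])
    smoothed = smooth_matrix(raw, window)
    binarized, _ = binarize_matrix(smoothed)
    net = prune_by_correlation(prior, smoothed, cutoff)
    net = remove_terminal_nodes(net)
    net = extract_scc(net)
    net = add_self_activation(net)
    return net, smoothed, binarized
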