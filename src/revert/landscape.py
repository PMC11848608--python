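"""Attractor landscape quantification of a Boolean network.

Under synchronous update the state space of an n-gene Boolean network is a
deterministic transition graph whose terminal cycles are the attractors
(length-1 cycles are point attractors).  The landscape is summarized along a
virtual normal->cancer axis:

* ``effective_distance`` projects a state onto the axis from the normal
  anchor state (d = 0) to the cancer anchor state (d = 1);
* ``attractor_entropy`` measures each attractor's depth as the Shannon
  entropy of where single-rule perturbations of basin states re-converge;
* ``cancer_score`` collapses the landscape to a scalar: the sum over
  attractors of (1 - S_k/S_max) * basin fraction * distance, i.e. deep, wide
  valleys near the cancer pole score high.

States are passed around as tuples of 0/1 in network gene order; internally
the dynamics run on integer bitmasks (bit i = gene i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import BooleanNetwork, BooleanRule

__all__ = [
    "AttractorSet",
    "LandscapeSummary",
    "synchronous_step",
    "find_attractors",
    "anchor_states",
    "effective_distance",
    "attractor_entropy",
    "cancer_score",
    "quantify_landscape",
    "map_cells_to_landscape",
]

EXHAUSTIVE_LIMIT = 25


class _Stepper:
    """Compiled synchronous dynamics on integer bitmask states."""

    def __init__(self, net: BooleanNetwork):
        self.net = net
        self.n = net.n_genes
        pos = {g: i for i, g in enumerate(net.genes)}
        self._gene_specs = []
        for i, g in enumerate(net.genes):
            rule = net.rules[g]
            regs = tuple(pos[r] for r in rule.regulators)
            self._gene_specs.append((i, regs, rule.table))

    def step(self, state: int) -> int:
        out = 0
        for i, regs, table in self._gene_specs:
            idx = 0
            for p in regs:
                idx = (idx << 1) | ((state >> p) & 1)
            out |= table[idx] << i
        return out

    def converge(self, state: int, cache: dict[int, int] | None = None
                 ) -> tuple[tuple[int, ...], int]:
        """Iterate to the terminal cycle.

        Returns (canonical cycle as sorted-rotation tuple of int states,
        first cycle state hit).  ``cache`` maps state -> cycle id is NOT used
        here; callers that need cross-call caching use :func:`find_attractors`.
        """
        seen: dict[int, int] = {}
        path: list[int] = []
        s = state
        while s not in seen:
            seen[s] = len(path)
            path.append(s)
            s = self.step(s)
        cycle = path[seen[s]:]
        return _canonical_cycle(cycle), s


def _converge_specs(specs, state: int) -> tuple[int, ...]:
    """Iterate compiled gene specs from ``state`` to the canonical cycle."""
    seen: dict[int, int] = {}
    path: list[int] = []
    s = state
    while s not in seen:
        seen[s] = len(path)
        path.append(s)
        out = 0
        for i, regs, table in specs:
            idx = 0
            for p in regs:
                idx = (idx << 1) | ((s >> p) & 1)
            out |= table[idx] << i
        s = out
    return _canonical_cycle(path[seen[s]:])


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Rotate so the smallest state comes first (cycles compare equal under
    rotation)."""
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def _int_to_vec(state: int, n: int) -> tuple[int, ...]:
    return tuple((state >> i) & 1 for i in range(n))


def _vec_to_int(vec) -> int:
    out = 0
    for i, b in enumerate(vec):
        out |= (int(b) & 1) << i
    return out


def synchronous_step(net: BooleanNetwork, v: tuple[int, ...]) -> tuple[int, ...]:
    """One synchronous update of state ``v`` (every gene simultaneously)."""
    return net.step(tuple(v))


@dataclass
class AttractorSet:
    """Attractors of a network with basin bookkeeping.

    ``attractors[k]`` is an ordered list of state tuples (length 1 = point
    attractor); ``basin_counts[k]`` counts the initial states that converged
    to attractor k; ``basin_states[k]`` stores those initial states (used to
    sample basin members for entropy estimation).  Ordering is canonical:
    descending basin count, then lexicographically smallest state.
    """

    network: BooleanNetwork
    attractors: list[tuple[tuple[int, ...], ...]]
    basin_counts: list[int]
    basin_states: list[list[tuple[int, ...]]]
    n_initial: int
    exhaustive: bool

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    @property
    def basin_fractions(self) -> np.ndarray:
        return np.asarray(self.basin_counts, dtype=float) / self.n_initial

    def is_point(self, k: int) -> bool:
        return len(self.attractors[k]) == 1

    def verify_closed(self) -> bool:
        """Every attractor must be closed under one synchronous step."""
        for cyc in self.attractors:
            states = set(cyc)
            for i, s in enumerate(cyc):
                nxt = self.network.step(s)
                if nxt != cyc[(i + 1) % len(cyc)] or nxt not in states:
                    return False
        return True


def find_attractors(net: BooleanNetwork,
                    initial_states=None,
                    n_random: int | None = None,
                    exhaustive: bool = False,
                    seed: int | None = None) -> AttractorSet:
    """Locate attractors and basins from a set of initial states.

    Exactly one of ``initial_states`` (explicit list of state tuples),
    ``n_random`` (random initial states, with replacement) or
    ``exhaustive=True`` (all 2**n states; n <= 25) selects the mode.
    """
    n = net.n_genes
    if exhaustive:
        if n > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive mode limited to {EXHAUSTIVE_LIMIT} genes, got {n}")
        inits = range(2 ** n)
        total = 2 ** n
    elif initial_states is not None:
        inits = [_vec_to_int(v) for v in initial_states]
        total = len(inits)
    elif n_random is not None:
        rng = np.random.default_rng(seed)
        inits = [int(x) for x in rng.integers(0, 2 ** n, size=n_random)]
        total = n_random
    else:
        raise ValueError("provide initial_states, n_random or exhaustive=True")

    stepper = _Stepper(net)
    state_to_attr: dict[int, int] = {}   # any visited state -> attractor idx
    cycles: list[tuple[int, ...]] = []
    counts: list[int] = []
    members: list[list[int]] = []

    for s0 in inits:
        path = []
        s = s0
        while s not in state_to_attr:
            path.append(s)
            nxt = stepper.step(s)
            if nxt in path or nxt in state_to_attr:
                if nxt not in state_to_attr:
                    # closed a new cycle within this walk; trace it out
                    cyc_states = [nxt]
                    t = stepper.step(nxt)
                    while t != nxt:
                        cyc_states.append(t)
                        t = stepper.step(t)
                    cyc = _canonical_cycle(cyc_states)
                    idx = len(cycles)
                    cycles.append(cyc)
                    counts.append(0)
                    members.append([])
                    for c in cyc:
                        state_to_attr[c] = idx
            s = nxt
        idx = state_to_attr[s]
        for p in path:
            state_to_attr[p] = idx
        counts[idx] += 1
        members[idx].append(s0)

    order = sorted(
        range(len(cycles)),
        key=lambda k: (-counts[k], tuple(_int_to_vec(cycles[k][0], n))),
    )
    return AttractorSet(
        network=net,
        attractors=[tuple(_int_to_vec(s, n) for s in cycles[k]) for k in order],
        basin_counts=[counts[k] for k in order],
        basin_states=[[_int_to_vec(s, n) for s in members[k]] for k in order],
        n_initial=total,
        exhaustive=exhaustive,
    )


def anchor_states(trajectory, fraction: float = 0.2
                  ) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Normal/cancer anchor states from the ends of a pseudotime ordering.

    Per-gene mean of the binarized matrix over the first/last
    ``fraction`` of cells, rounded with ties (mean exactly 0.5) going to 1.

    ``trajectory`` is anything with a ``binarized`` cells-x-genes DataFrame
    ordered by pseudotime, or such a DataFrame itself.
    """
    binarized = getattr(trajectory, "binarized", trajectory)
    n_cells = binarized.shape[0]
    if n_cells < 5:
        raise ValueError("need at least 5 cells to define anchor states")
    w = max(1, int(round(fraction * n_cells)))
    head = binarized.iloc[:w].mean(axis=0).to_numpy()
    tail = binarized.iloc[-w:].mean(axis=0).to_numpy()
    v_n = tuple(int(x >= 0.5) for x in head)
    v_c = tuple(int(x >= 0.5) for x in tail)
    if v_n == v_c:
        raise ValueError("degenerate normal-cancer axis: anchors coincide")
    return v_n, v_c


def effective_distance(v, v_n, v_c) -> float:
    """Projection of state ``v`` onto the normal->cancer axis.

    d = (v - v_N) . (v_C - v_N) / |v_C - v_N|^2, so d(v_N) = 0 and
    d(v_C) = 1; states beyond the anchors may fall outside [0, 1].
    """
    v = np.asarray(v, dtype=float)
    v_n = np.asarray(v_n, dtype=float)
    v_c = np.asarray(v_c, dtype=float)
    axis = v_c - v_n
    denom = float(axis @ axis)
    if denom == 0.0:
        raise ValueError("degenerate normal-cancer axis: anchors coincide")
    return float((v - v_n) @ axis / denom)


def _attractor_distance(cycle, v_n, v_c) -> float:
    """d of an attractor: mean over its cycle states (a point attractor's
    own d)."""
    return float(np.mean([effective_distance(s, v_n, v_c) for s in cycle]))


def _entropy_bits(probs) -> float:
    return float(-sum(p * math.log2(p) for p in probs if p > 0))


def attractor_entropy(net: BooleanNetwork,
                      attractor_set: AttractorSet,
                      n_perturbations_per_state: int = 100,
                      seed: int | None = None,
                      basin_state_cap: int = 512,
                      ) -> tuple[list[float], list[list[float]]]:
    """Per-attractor entropy S_k from random single-rule perturbations.

    For each sampled basin state j of attractor i, ``n`` independent trials
    each pick one gene uniformly, randomly permute the output column of its
    truth table, run the perturbed network from j to convergence, and map the
    perturbed attractor back to an original attractor by re-converging its
    first cycle state under the unperturbed rules.  P_k over trials gives the
    state entropy S_i^j = -sum_k P_k log2 P_k; S_i is the mean over sampled
    basin states.  Outcomes landing on an attractor absent from
    ``attractor_set`` count as their own category (keeps sum(P) = 1).

    Returns (S per attractor, per-attractor list of per-state S_i^j).
    """
    if attractor_set.n_attractors < 1:
        raise ValueError("need at least one attractor")
    if n_perturbations_per_state < 1:
        raise ValueError("n_perturbations_per_state must be >= 1")
    rng = np.random.default_rng(seed)
    stepper = _Stepper(net)
    n = net.n_genes
    canon_to_idx = {
        _canonical_cycle([_vec_to_int(s) for s in cyc]): k
        for k, cyc in enumerate(attractor_set.attractors)
    }
    # memo: original-rule convergence of perturbed outcomes
    reconverge_memo: dict[int, tuple[int, ...]] = {}
    base_specs = stepper._gene_specs

    s_per_attractor: list[float] = []
    s_states: list[list[float]] = []
    for k in range(attractor_set.n_attractors):
        basin = attractor_set.basin_states[k]
        if not basin:
            # attractor known but no sampled basin member: use a cycle state
            basin = [attractor_set.attractors[k][0]]
        if len(basin) > basin_state_cap:
            pick = rng.choice(len(basin), size=basin_state_cap, replace=False)
            basin = [basin[i] for i in pick]
        entropies = []
        for vec in basin:
            j_int = _vec_to_int(vec)
            outcomes: dict = {}
            specs = list(base_specs)
            for _ in range(n_perturbations_per_state):
                gi = int(rng.integers(n))
                i, regs, table = base_specs[gi]
                perm = rng.permutation(len(table))
                specs[gi] = (i, regs, tuple(table[p] for p in perm))
                pcyc = _converge_specs(specs, j_int)
                specs[gi] = base_specs[gi]
                anchor = pcyc[0]
                if anchor not in reconverge_memo:
                    reconverge_memo[anchor] = stepper.converge(anchor)[0]
                ocyc = reconverge_memo[anchor]
                key = canon_to_idx.get(ocyc, ("extra", ocyc))
                outcomes[key] = outcomes.get(key, 0) + 1
            probs = [c / n_perturbations_per_state for c in outcomes.values()]
            entropies.append(_entropy_bits(probs))
        s_states.append(entropies)
        s_per_attractor.append(float(np.mean(entropies)))
    return s_per_attractor, s_states


def cancer_score(d: list[float], s: list[float], basin: list[int],
                 s_max: float | None = None) -> float:
    """Scalar landscape malignancy.

    score = sum_k (1 - S_k/S_max) * (B_k / sum_j B_j) * max(d_k, 0).

    ``s_max`` defaults to log2(number of attractors); for a single attractor
    S_max = 0 and the depth factor is taken as 1 (the limit, since S is then
    also 0).  Distances are clamped at 0: a valley behind the normal anchor
    contributes no malignancy.
    """
    d = list(d)
    s = list(s)
    basin = list(basin)
    if not (len(d) == len(s) == len(basin)):
        raise ValueError("d, s, basin must have equal length")
    if any(b < 0 for b in basin) or any(x < 0 for x in s):
        raise ValueError("basin counts and entropies must be non-negative")
    total = float(sum(basin))
    if total <= 0:
        raise ValueError("total basin size must be positive")
    if s_max is None:
        s_max = math.log2(len(d)) if len(d) > 1 else 0.0
    if s_max < 0:
        raise ValueError("S_max must be non-negative")
    score = 0.0
    for d_k, s_k, b_k in zip(d, s, basin):
        depth = 1.0 if s_max == 0 else (1.0 - s_k / s_max)
        score += depth * (b_k / total) * max(d_k, 0.0)
    return score


@dataclass
class LandscapeSummary:
    """Quantified attractor landscape plus the scalar cancer score."""

    attractor_set: AttractorSet
    v_normal: tuple[int, ...]
    v_cancer: tuple[int, ...]
    d: list[float]
    s: list[float]
    s_states: list[list[float]] = field(repr=False, default_factory=list)
    s_max: float = 0.0
    score: float = 0.0

    @property
    def basin_counts(self) -> list[int]:
        return self.attractor_set.basin_counts

    @property
    def basin_fractions(self) -> np.ndarray:
        return self.attractor_set.basin_fractions

    def to_dict(self) -> dict:
        return {
            "n_attractors": self.attractor_set.n_attractors,
            "attractors": [
                ["".join(map(str, s)) for s in cyc]
                for cyc in self.attractor_set.attractors
            ],
            "d": self.d,
            "s": self.s,
            "basin_counts": self.basin_counts,
            "basin_fractions": self.basin_fractions.tolist(),
            "s_max": self.s_max,
            "cancer_score": self.score,
            "v_normal": list(self.v_normal),
            "v_cancer": list(self.v_cancer),
        }


def quantify_landscape(net: BooleanNetwork,
                       v_normal, v_cancer,
                       n_initial: int = 1000,
                       n_perturbations: int = 100,
                       seed: int | None = None,
                       exhaustive: bool = False) -> LandscapeSummary:
    """Full landscape pipeline: attractors -> distances -> entropy -> score."""
    aset = find_attractors(net, n_random=None if exhaustive else n_initial,
                           exhaustive=exhaustive, seed=seed)
    d = [_attractor_distance(cyc, v_normal, v_cancer) for cyc in aset.attractors]
    entropy_seed = None if seed is None else seed + 1
    s, s_states = attractor_entropy(net, aset, n_perturbations, seed=entropy_seed)
    s_max = math.log2(aset.n_attractors) if aset.n_attractors > 1 else 0.0
    score = cancer_score(d, s, aset.basin_counts, s_max)
    return LandscapeSummary(aset, tuple(v_normal), tuple(v_cancer),
                            d, s, s_states, s_max, score)


def map_cells_to_landscape(net: BooleanNetwork, binarized, v_normal, v_cancer,
                           summary: LandscapeSummary | None = None):
    """Map single cells onto the landscape via their binarized states.

    Each cell's binarized expression vector (over network genes) is used as an
    initial state and iterated to its attractor; the cell is annotated with
    the attractor index, its own effective distance d, and (when a
    ``summary`` with per-state entropies is supplied) the attractor's S_k.

    Returns a DataFrame with one row per cell.
    """
    import pandas as pd

    genes = list(net.genes)
    mat = binarized[genes] if hasattr(binarized, "columns") else binarized
    stepper = _Stepper(net)
    canon_cache: dict[tuple, int] = {}
    rows = []
    for cell_idx in range(mat.shape[0]):
        vec = tuple(int(x) for x in np.asarray(mat)[cell_idx])
        cyc, _ = stepper.converge(_vec_to_int(vec))
        key = cyc
        if key not in canon_cache:
            canon_cache[key] = -1
            if summary is not None:
                src = summary.attractor_set
            else:
                src = None
            if src is not None:
                for k, acyc in enumerate(src.attractors):
                    if _canonical_cycle([_vec_to_int(s) for s in acyc]) == cyc:
                        canon_cache[key] = k
                        break
        attr_idx = canon_cache[key]
        attr_states = [_int_to_vec(s, net.n_genes) for s in cyc]
        d_attr = float(np.mean([effective_distance(s, v_normal, v_cancer)
                                for s in attr_states]))
        row = {
            "cell": (mat.index[cell_idx] if hasattr(mat, "index") else cell_idx),
            "attractor": attr_idx,
            "d_cell": effective_distance(vec, v_normal, v_cancer),
            "d_attractor": d_attr,
        }
        if summary is not None and 0 <= attr_idx < len(summary.s):
            row["s_attractor"] = summary.s[attr_idx]
        rows.append(row)
    return pd.DataFrame(rows)
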