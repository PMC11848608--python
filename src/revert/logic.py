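"""Boolean rule inference from pseudotime input-output pairs.

For each gene, the binarized trajectory supplies input-output pairs
{(I_t, O_{t+k})}: the regulator state vector at ordered position t and the
gene's value k positions later, with the step k strictly larger than the
smoothing window so input and output windows cannot overlap.  Candidate
Boolean functions are every truth table over the gene's signed regulators
that is (a) monotone consistent with each edge sign and (b) essential in
every regulator; the fitted rule maximizes the score

    S(f) = #{t : f(I_t) = O_{t+k}},   0 <= S(f) <= m = n_cells - k.

Ties at the optimum are OR-combined pointwise, recording the tied set as
provenance.  Exhaustive enumeration over this class is cheap for <= 4
regulators, which is the default cap (excess regulators are dropped by
|Spearman rho| ranking with a warning).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .network import BooleanNetwork, BooleanRule, SignedNetwork

__all__ = [
    "IOPairs",
    "make_io_pairs",
    "score_function",
    "enumerate_candidates",
    "infer_rule",
    "infer_network",
    "agreement_level",
]

MAX_REGULATORS = 4


@dataclass(frozen=True)
class IOPairs:
    """Input-output pairs for one gene's rule fit.

    ``inputs[t]`` is the regulator state tuple at ordered position t,
    ``outputs[t]`` the gene's binarized value at position t + k; there are
    exactly m = n_cells - k pairs.
    """

    gene: str
    regulators: tuple[str, ...]
    inputs: tuple[tuple[int, ...], ...]
    outputs: tuple[int, ...]
    k: int

    @property
    def m(self) -> int:
        return len(self.outputs)


def make_io_pairs(binarized: pd.DataFrame, gene: str,
                  regulators: tuple[str, ...], k: int,
                  window: int | None = None) -> IOPairs:
    """Build {(I_t, O_{t+k})} from a pseudotime-ordered binarized matrix.

    When ``window`` is given, ``k`` must exceed it so the averaged input and
    output windows never overlap.
    """
    n_cells = binarized.shape[0]
    if window is not None and k <= window:
        raise ValueError(
            f"step k={k} must exceed the smoothing window ({window}) to "
            "prevent input/output window overlap")
    if k < 1 or k >= n_cells:
        raise ValueError(f"step k must be in [1, {n_cells - 1}], got {k}")
    reg_mat = binarized[list(regulators)].to_numpy(dtype=int)
    out_vec = binarized[gene].to_numpy(dtype=int)
    m = n_cells - k
    inputs = tuple(tuple(int(b) for b in reg_mat[t]) for t in range(m))
    outputs = tuple(int(out_vec[t + k]) for t in range(m))
    return IOPairs(gene, tuple(regulators), inputs, outputs, k)


def _table_index(state: tuple[int, ...]) -> int:
    idx = 0
    for b in state:
        idx = (idx << 1) | b
    return idx


def score_function(table: tuple[int, ...], pairs: IOPairs) -> int:
    """S(f): number of pairs where the table reproduces the output."""
    return sum(1 for i, o in zip(pairs.inputs, pairs.outputs)
               if table[_table_index(i)] == o)


@lru_cache(maxsize=None)
def _candidate_tables(signs: tuple[int, ...]) -> tuple[tuple[int, ...], ...]:
    """All truth tables monotone in each signed input with every input
    essential, in lexicographic table order."""
    n = len(signs)
    size = 2 ** n
    out = []
    for bits in itertools.product((0, 1), repeat=size):
        ok = True
        essential = [False] * n
        for j in range(n):
            bit = 1 << (n - 1 - j)
            for idx in range(size):
                if not idx & bit:
                    continue
                lo, hi = bits[idx ^ bit], bits[idx]
                if lo != hi:
                    essential[j] = True
                    # hi is the value with input j active
                    if signs[j] == 1 and hi < lo:
                        ok = False
                        break
                    if signs[j] == -1 and hi > lo:
                        ok = False
                        break
            if not ok:
                break
        if ok and all(essential):
            out.append(bits)
    return tuple(out)


def enumerate_candidates(regulators_with_signs: tuple[tuple[str, int], ...],
                         max_regulators: int = MAX_REGULATORS,
                         ) -> list[tuple[int, ...]]:
    """Candidate truth tables for a gene's signed regulator set.

    The caller must have reduced the regulator set to ``max_regulators``
    already (see :func:`infer_network` for the |rho|-ranked reduction).
    """
    if not 1 <= len(regulators_with_signs) <= max_regulators:
        raise ValueError(
            f"need 1..{max_regulators} regulators, got {len(regulators_with_signs)}")
    signs = tuple(s for _, s in regulators_with_signs)
    if any(s not in (1, -1) for s in signs):
        raise ValueError("regulator signs must be +-1")
    return list(_candidate_tables(signs))


def infer_rule(gene: str, pairs: IOPairs,
               candidates: list[tuple[int, ...]]) -> BooleanRule:
    """Best-scoring candidate; ties are OR-combined pointwise.

    The reported score is recomputed for the combined table, and the tied
    tables are kept as provenance.
    """
    if not candidates:
        raise ValueError(f"no candidate function for gene {gene!r}")
    scores = [score_function(tab, pairs) for tab in candidates]
    best = max(scores)
    tied = [tab for tab, s in zip(candidates, scores) if s == best]
    if len(tied) == 1:
        table = tied[0]
        provenance: tuple = ()
    else:
        table = tuple(int(any(t[i] for t in tied)) for i in range(len(tied[0])))
        provenance = tuple(tied)
    return BooleanRule(gene=gene, regulators=pairs.regulators,
                       table=tuple(table),
                       score=score_function(tuple(table), pairs),
                       provenance=provenance)


def _reduce_regulators(gene: str, regs: list[tuple[str, int]],
                       binarized: pd.DataFrame, smoothed: pd.DataFrame | None,
                       max_regulators: int) -> list[tuple[str, int]]:
    """Keep the max_regulators regulators with highest |Spearman rho| to the
    target (computed on smoothed values when available)."""
    if len(regs) <= max_regulators:
        return regs
    ref = smoothed if smoothed is not None else binarized
    strength = {}
    for r, _ in regs:
        rho = stats.spearmanr(ref[r], ref[gene]).statistic
        strength[r] = abs(rho) if np.isfinite(rho) else 0.0
    ranked = sorted(regs, key=lambda rs: -strength[rs[0]])
    kept = sorted(ranked[:max_regulators], key=lambda rs: regs.index(rs))
    warnings.warn(
        f"gene {gene!r} has {len(regs)} regulators; kept the "
        f"{max_regulators} strongest by |rho|: {[r for r, _ in kept]}",
        stacklevel=2)
    return kept


def infer_network(binarized: pd.DataFrame, skeleton: SignedNetwork,
                  k: int | None = None, window: int | None = None,
                  max_regulators: int = MAX_REGULATORS,
                  smoothed: pd.DataFrame | None = None) -> BooleanNetwork:
    """Infer one Boolean rule per skeleton node.

    ``k`` defaults to window + 1 (the smallest step whose output window does
    not overlap the input window).
    """
    missing = [n for n in skeleton.nodes if n not in binarized.columns]
    if missing:
        raise ValueError(f"skeleton genes absent from matrix: {missing}")
    if k is None:
        if window is None:
            raise ValueError("provide k or window")
        k = window + 1
    rules = {}
    for gene in skeleton.nodes:
        regs = skeleton.regulators_of(gene)
        if not regs:
            raise ValueError(f"gene {gene!r} has no regulators in skeleton")
        regs = _reduce_regulators(gene, regs, binarized, smoothed, max_regulators)
        pairs = make_io_pairs(binarized, gene, tuple(r for r, _ in regs), k,
                              window=window)
        candidates = enumerate_candidates(tuple(regs), max_regulators)
        rules[gene] = infer_rule(gene, pairs, candidates)
    return BooleanNetwork(skeleton.nodes, rules)


def agreement_level(net: BooleanNetwork, binarized: pd.DataFrame, k: int,
                    ) -> float:
    """Mean per-gene S(f)/m: how well the fitted rules reproduce the data."""
    fracs = []
    for gene in net.genes:
        rule = net.rules[gene]
        pairs = make_io_pairs(binarized, gene, rule.regulators, k)
        fracs.append(score_function(rule.table, pairs) / pairs.m)
    return float(np.mean(fracs))
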