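"""Synthetic ground truth: bistable networks, trajectories, CNV fixtures.

The generator emulates the snapshot structure of tumorigenesis that the
pipeline assumes: a cell population captured mid-transition contains the
whole normal-to-cancer path, so a pseudotime ordering of one synthetic
"patient" sweeps from a normal attractor state to a cancer attractor state.

Ground-truth networks are built around mutual-inhibition toggle pairs.  Each
pair is deliberately asymmetric, reflecting a transition state in which the
normal attractor has already been destabilized while the cancer attractor
dominates: the normal-pole gene A needs both itself and the absence of its
antagonist (A AND NOT B), whereas the cancer-pole gene B sustains itself or
switches on whenever A is lost (B OR NOT A).  Both poles are exact fixed
points under synchronous update, but the cancer basin is the larger and
deeper valley, so the unperturbed cancer score of the ground-truth landscape
exceeds 0.5 - the regime in which reversion screening is meaningful.

Trajectories place every gene's switching time inside a central transition
window of pseudotime (default the middle 10%), so the terminal 20% windows
used to anchor the normal/cancer axis are pure stable states on either side
of a rapid critical transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grn import TrajectoryData
from .network import BooleanNetwork, BooleanRule, SignedNetwork

__all__ = [
    "GroundTruth",
    "make_bistable_network",
    "simulate_trajectory",
    "make_cnv_fixture",
    "generate",
]

# master pair rules, regulator order (self, partner):
#   normal pole A: A AND NOT B    cancer pole B: B OR NOT A
_POLE_A_TABLE = (0, 0, 1, 0)
_POLE_B_TABLE = (1, 0, 1, 1)
# satellite pair rules, slaved to the master pair (A, B):
#   P = A AND (P OR NOT Q)   over (P, Q, A)
#   Q = B OR (NOT P AND NOT A)   over (P, A, B)
_SAT_P_TABLE = (0, 1, 0, 0, 0, 1, 0, 1)
_SAT_Q_TABLE = (1, 1, 0, 1, 0, 1, 0, 1)


@dataclass
class GroundTruth:
    """A generated network with designated normal/cancer fixed points."""

    network: BooleanNetwork
    normal_state: tuple[int, ...]
    cancer_state: tuple[int, ...]
    seed: int
    trajectory: TrajectoryData | None = None
    master_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.network.step(self.normal_state) != self.normal_state:
            raise ValueError("normal state is not a fixed point")
        if self.network.step(self.cancer_state) != self.cancer_state:
            raise ValueError("cancer state is not a fixed point")
        if self.normal_state == self.cancer_state:
            raise ValueError("normal and cancer states coincide")

    @property
    def prior_network(self) -> SignedNetwork:
        """The true signed skeleton (the 'prior knowledge' a user would
        bring); signs follow each rule's monotone direction."""
        edges = {(u, v): s for u, v, s in self.network.signed_edges()}
        return SignedNetwork(self.network.genes, edges)


def make_bistable_network(n_genes: int, n_toggle_pairs: int = 1,
                          seed: int = 0) -> GroundTruth:
    """Sign-labeled bistable network with verified normal/cancer fixed points.

    Genes ``0..2*n_toggle_pairs-1`` form cancer-dominant toggle pairs (see
    module docstring); the remaining genes are downstream readouts driven by
    one or two toggle genes through random monotone AND/OR rules, so their
    values flip between the two designated states but they feed nothing back
    (they are pruned away by SCC extraction, as peripheral genes should be).
    """
    if n_toggle_pairs < 1:
        raise ValueError("need at least one toggle pair")
    if not 2 * n_toggle_pairs <= n_genes <= 30:
        raise ValueError(
            f"n_genes must be in [{2 * n_toggle_pairs}, 30], got {n_genes}")
    rng = np.random.default_rng(seed)
    genes = tuple(f"G{i + 1}" for i in range(n_genes))
    rules: dict[str, BooleanRule] = {}
    normal: list[int] = []
    cancer: list[int] = []
    core: list[str] = []
    master_a, master_b = genes[0], genes[1]
    for p in range(n_toggle_pairs):
        a, b = genes[2 * p], genes[2 * p + 1]
        if p == 0:
            rules[a] = BooleanRule(a, (a, b), _POLE_A_TABLE)
            rules[b] = BooleanRule(b, (b, a), _POLE_B_TABLE)
        else:
            # satellite pair slaved to the master switch: forced to the
            # master's pole at either fixed point, mutually inhibitory in
            # between, so the global attractors stay exactly two
            rules[a] = BooleanRule(a, (a, b, master_a), _SAT_P_TABLE)
            rules[b] = BooleanRule(b, (a, master_a, master_b), _SAT_Q_TABLE)
        normal += [1, 0]
        cancer += [0, 1]
        core += [a, b]
    state_n = dict(zip(core, normal))
    state_c = dict(zip(core, cancer))
    for g in genes[2 * n_toggle_pairs:]:
        # redraw until the readout separates the two states (an AND/OR of
        # mixed signs can otherwise evaluate equal at both poles)
        while True:
            n_reg = int(rng.integers(1, 3))
            regs = tuple(rng.choice(core, size=n_reg, replace=False))
            signs = tuple(int(s) for s in rng.choice([1, -1], size=n_reg))
            if n_reg == 1:
                table = (0, 1) if signs[0] == 1 else (1, 0)
            else:
                combine_or = bool(rng.integers(2))
                table = tuple(
                    _lit(i >> 1, signs[0]) | _lit(i & 1, signs[1]) if combine_or
                    else _lit(i >> 1, signs[0]) & _lit(i & 1, signs[1])
                    for i in range(4)
                )
            rule = BooleanRule(g, regs, table)
            if rule.evaluate(state_n) != rule.evaluate(state_c):
                break
        rules[g] = rule
        normal.append(rule.evaluate(state_n))
        cancer.append(rule.evaluate(state_c))
    net = BooleanNetwork(genes, rules)
    return GroundTruth(
        network=net,
        normal_state=tuple(normal),
        cancer_state=tuple(cancer),
        seed=seed,
        master_pair=(genes[0], genes[1]),
    )


def _lit(bit: int, sign: int) -> int:
    return bit if sign == 1 else 1 - bit


def simulate_trajectory(gt: GroundTruth, n_cells: int = 200,
                        flip_noise: float = 0.05, seed: int = 0,
                        transition_window: tuple[float, float] = (0.45, 0.55),
                        jitter: float = 0.3,
                        drift: float = 0.2) -> TrajectoryData:
    """Noisy monotone trajectory from the normal to the cancer state.

    Each gene that differs between the two states switches once, at a
    changepoint drawn uniformly inside ``transition_window``; the noiseless
    backbone is therefore a monotone path with pure end segments.  Each
    binary entry is flipped independently with probability ``flip_noise``,
    and continuous expression is the (noisy) binary value plus a positive
    Uniform(0, jitter) offset plus a graded ``drift`` ramp toward the gene's
    cancer-state level.  The ramp mimics the graded expression real
    trajectories show within phases; without it the plateau ranks of a step
    profile are pure noise, which caps the rank correlation between two
    co-switching genes near 0.75 regardless of noise level.  Drift and
    jitter together stay well below the unit binarization gap, so two-means
    binarization of the smoothed profile still recovers the binary signal
    exactly.
    """
    if not 0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must be in [0, 0.5)")
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    lo, hi = transition_window
    if not 0 < lo <= hi < 1:
        raise ValueError("transition_window must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    genes = gt.network.genes
    pt = np.linspace(0.0, 1.0, n_cells)
    backbone = np.empty((n_cells, len(genes)), dtype=int)
    for j, g in enumerate(genes):
        v_n, v_c = gt.normal_state[j], gt.cancer_state[j]
        if v_n == v_c:
            backbone[:, j] = v_n
        else:
            cp = rng.uniform(lo, hi)
            backbone[:, j] = np.where(pt < cp, v_n, v_c)
    flips = rng.random(backbone.shape) < flip_noise
    noisy = np.where(flips, 1 - backbone, backbone)
    ramp = np.zeros((n_cells, len(genes)))
    for j in range(len(genes)):
        if gt.cancer_state[j] > gt.normal_state[j]:
            ramp[:, j] = drift * pt
        elif gt.cancer_state[j] < gt.normal_state[j]:
            ramp[:, j] = drift * (1.0 - pt)
    raw = noisy + rng.uniform(0.0, jitter, size=backbone.shape) + ramp
    cells = tuple(f"cell{i + 1:04d}" for i in range(n_cells))
    mid = (lo + hi) / 2.0
    labels = pd.Series(np.where(pt < mid, "normal", "cancer"),
                       index=cells, name="origin")
    cols = list(genes)
    traj = TrajectoryData(
        cells=cells,
        pseudotime=pt,
        raw=pd.DataFrame(raw, index=cells, columns=cols),
        labels=labels,
        backbone=pd.DataFrame(backbone, index=cells, columns=cols),
    )
    return traj


def make_cnv_fixture(n_normal: int, n_cancer: int, n_mixed: int,
                     n_bins: int = 200, seed: int = 0,
                     amplitude: float = 0.5, noise_sd: float = 0.05,
                     ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Cell-by-bin copy-number matrix with a planted mixed (transition) group.

    Normal cells sit on a flat baseline (log2 ratio 0); cancer cells share a
    planted segmental gain/loss profile; mixed cells carry half the profile
    (an intermediate genome) with alternating true origins, so a tree built
    on the matrix isolates them as a clade of maximal origin entropy.

    Returns (matrix, origin labels, mixed cell ids).
    """
    if min(n_normal, n_cancer) < 1 or n_mixed < 0 or n_bins < 10:
        raise ValueError("need >=1 normal and cancer cell and >=10 bins")
    rng = np.random.default_rng(seed)
    n_segments = 10
    bounds = np.linspace(0, n_bins, n_segments + 1).astype(int)
    profile = np.zeros(n_bins)
    altered = rng.choice(n_segments, size=max(2, n_segments * 4 // 10),
                         replace=False)
    for s in altered:
        sign = 1 if rng.integers(2) else -1
        profile[bounds[s]:bounds[s + 1]] = sign * amplitude

    def _cells(prefix, count):
        return [f"{prefix}{i + 1}" for i in range(count)]

    ids = _cells("N", n_normal) + _cells("C", n_cancer) + _cells("M", n_mixed)
    rows, labels = [], []
    for _ in range(n_normal):
        rows.append(rng.normal(0.0, noise_sd, n_bins))
        labels.append("normal")
    for _ in range(n_cancer):
        rows.append(profile + rng.normal(0.0, noise_sd, n_bins))
        labels.append("cancer")
    for i in range(n_mixed):
        rows.append(0.5 * profile + rng.normal(0.0, noise_sd, n_bins))
        labels.append("normal" if i % 2 == 0 else "cancer")
    mat = pd.DataFrame(np.asarray(rows), index=ids,
                       columns=[f"bin{j + 1}" for j in range(n_bins)])
    return mat, pd.Series(labels, index=ids, name="origin"), ids[n_normal + n_cancer:]


def generate(n_genes: int = 8, n_toggle_pairs: int = 1, n_cells: int = 200,
             flip_noise: float = 0.05, seed: int = 0) -> GroundTruth:
    """Convenience: network plus trajectory under one seed."""
    gt = make_bistable_network(n_genes, n_toggle_pairs, seed=seed)
    gt.trajectory = simulate_trajectory(gt, n_cells=n_cells,
                                        flip_noise=flip_noise, seed=seed + 1)
    return gt
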