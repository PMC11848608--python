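"""In-silico reversion screening: gene fixations that flatten the landscape.

A candidate intervention fixes one or two genes to 0 (knockdown) or 1
(overexpression), replacing their update rules by constants, and the full
landscape quantification is recomputed under the perturbed dynamics.  The
best reversion targets are the fixations that minimize the cancer score;
a final score <= 0.1 counts as a successful reversion, and double
perturbations are drawn from the top five single-gene hits (each at its
winning direction).

The hyperparameter-ensemble scan reruns the whole build -> infer ->
landscape -> screen chain across a grid of (smoothing window, step size,
correlation cutoff), admits runs whose network size lies in [10, 30] with
an initial cancer score above 0.5, and tallies how often each perturbation
set pushes the score below 0.15 - a consensus that is robust to the
arbitrariness of any single hyperparameter choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn import build_skeleton, default_window
from .landscape import LandscapeSummary, quantify_landscape
from .logic import infer_network
from .network import BooleanNetwork, BooleanRule, SignedNetwork

__all__ = [
    "PerturbationResult",
    "EnsembleRecord",
    "apply_fixation",
    "screen_single",
    "screen_double",
    "ensemble_scan",
    "common_targets",
    "combine_rank_scores",
]

SUCCESS_SCORE = 0.1
CONSENSUS_SCORE = 0.15
MIN_ENSEMBLE_SIZE = 10
MAX_ENSEMBLE_SIZE = 30
MIN_INITIAL_SCORE = 0.5


@dataclass
class PerturbationResult:
    """One evaluated fixation with its recomputed landscape."""

    fixation: dict[str, int]
    summary: LandscapeSummary
    rank: int | None = None

    @property
    def score(self) -> float:
        return self.summary.score

    @property
    def label(self) -> str:
        if not self.fixation:
            return "control"
        return "+".join(f"{g}={v}" for g, v in sorted(self.fixation.items()))


def apply_fixation(net: BooleanNetwork, fixes: dict[str, int]) -> BooleanNetwork:
    """Fix genes to constants; all other rules are left untouched."""
    for g, v in fixes.items():
        if g not in net.genes:
            raise KeyError(f"unknown gene {g!r}")
        if v not in (0, 1):
            raise ValueError(f"fixation value for {g!r} must be 0 or 1")
    rules = dict(net.rules)
    for g, v in fixes.items():
        rules[g] = BooleanRule(gene=g, regulators=(), table=(v,))
    return BooleanNetwork(net.genes, rules)


def _fixation_seed(base_seed: int | None, index: int) -> int | None:
    """Deterministic per-fixation seed so screens are reproducible and the
    control row reproduces the standalone landscape bit-for-bit."""
    if base_seed is None:
        return None
    return (base_seed + 7919 * index) % (2 ** 31)


def screen_single(net: BooleanNetwork, v_normal, v_cancer,
                  n_initial: int = 1000, n_perturbations: int = 100,
                  seed: int | None = None,
                  exhaustive: bool = False) -> list[PerturbationResult]:
    """Evaluate all 2*n single fixations plus the unperturbed control.

    Returns results ranked ascending by cancer score (rank 0 = strongest
    reversion); the control carries an empty fixation map.
    """
    cases: list[dict[str, int]] = [{}]
    cases += [{g: v} for g in net.genes for v in (0, 1)]
    results = []
    for idx, fixes in enumerate(cases):
        perturbed = apply_fixation(net, fixes)
        summary = quantify_landscape(
            perturbed, v_normal, v_cancer, n_initial=n_initial,
            n_perturbations=n_perturbations,
            seed=_fixation_seed(seed, 0 if not fixes else idx),
            exhaustive=exhaustive)
        results.append(PerturbationResult(fixes, summary))
    results.sort(key=lambda r: (r.score, r.label))
    for rank, r in enumerate(results):
        r.rank = rank
    return results


def top_single_directions(singles: list[PerturbationResult], top: int = 5
                          ) -> list[tuple[str, int]]:
    """The ``top`` distinct genes by best single-fixation score, each at its
    winning direction (control rows are skipped)."""
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    for r in singles:
        if not r.fixation:
            continue
        (gene, value), = r.fixation.items()
        if gene in seen:
            continue
        seen.add(gene)
        out.append((gene, value))
        if len(out) == top:
            break
    return out


def screen_double(net: BooleanNetwork, v_normal, v_cancer,
                  singles: list[PerturbationResult], top: int = 5,
                  n_initial: int = 1000, n_perturbations: int = 100,
                  seed: int | None = None,
                  exhaustive: bool = False) -> list[PerturbationResult]:
    """All pairs among the top single hits, flagging scores <= 0.1.

    Each gene enters at the direction that won its single screen; with t
    distinct top genes the screen evaluates C(t, 2) pairs.
    """
    directions = top_single_directions(singles, top)
    if len(directions) < 2:
        import warnings
        warnings.warn("fewer than 2 distinct genes among top singles; "
                      "double screen degenerate", stacklevel=2)
        return []
    results = []
    for idx, ((g1, v1), (g2, v2)) in enumerate(
            itertools.combinations(directions, 2)):
        fixes = {g1: v1, g2: v2}
        perturbed = apply_fixation(net, fixes)
        summary = quantify_landscape(
            perturbed, v_normal, v_cancer, n_initial=n_initial,
            n_perturbations=n_perturbations,
            seed=_fixation_seed(seed, 1000 + idx),
            exhaustive=exhaustive)
        results.append(PerturbationResult(fixes, summary))
    results.sort(key=lambda r: (r.score, r.label))
    for rank, r in enumerate(results):
        r.rank = rank
    return results


def results_table(results: list[PerturbationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "rank": r.rank,
            "fixation": r.label,
            "cancer_score": r.score,
            "n_attractors": r.summary.attractor_set.n_attractors,
            "success": r.score <= SUCCESS_SCORE and bool(r.fixation),
        })
    return pd.DataFrame(rows)


@dataclass
class EnsembleRecord:
    """One hyperparameter set's network, initial score and best reversions."""

    params: dict
    network_size: int
    initial_score: float
    admitted: bool
    best_doubles: list[PerturbationResult] = field(default_factory=list)
    failure: str | None = None


def ensemble_scan(prior: SignedNetwork, raw: pd.DataFrame,
                  grid: list[dict] | None = None,
                  n_initial: int = 1000, n_perturbations: int = 50,
                  seed: int = 0, top: int = 5,
                  ) -> tuple[list[EnsembleRecord], pd.DataFrame]:
    """Rerun the full chain per hyperparameter set and build a consensus.

    ``grid`` entries may set ``window`` (cells), ``k`` (step) and ``cutoff``;
    defaults follow window in {5%, 8%} of cells, k in {window+1, 2*window},
    cutoff in {0.6, 0.7}.  A record is admitted when the inferred network
    has 10-30 nodes and the unperturbed cancer score exceeds 0.5; the
    consensus table counts, per fixation set, how many admitted records
    scored it below 0.15.  An empty ensemble yields an empty table, not an
    exception.
    """
    from .landscape import anchor_states

    n_cells = raw.shape[0]
    if grid is None:
        grid = []
        for frac in (0.05, 0.08):
            w = max(1, int(np.floor(frac * n_cells)))
            for k in (w + 1, 2 * w):
                for cutoff in (0.6, 0.7):
                    grid.append({"window": w, "k": k, "cutoff": cutoff})
    if not grid:
        raise ValueError("empty hyperparameter grid")

    records: list[EnsembleRecord] = []
    consensus: dict[str, int] = {}
    for i, params in enumerate(grid):
        window = params.get("window") or default_window(n_cells)
        k = params.get("k") or window + 1
        cutoff = params.get("cutoff", 0.7)
        run_seed = (seed + 104729 * i) % (2 ** 31)
        try:
            skel, smoothed, binarized = build_skeleton(
                prior, raw, window=window, cutoff=cutoff)
            net = infer_network(binarized[list(skel.nodes)], skel, k=k,
                                window=window, smoothed=smoothed)
            sub = binarized[list(net.genes)]
            v_n, v_c = anchor_states(sub)
            base = quantify_landscape(net, v_n, v_c, n_initial=n_initial,
                                      n_perturbations=n_perturbations,
                                      seed=run_seed)
        except ValueError as exc:
            records.append(EnsembleRecord(params, 0, float("nan"),
                                          admitted=False, failure=str(exc)))
            continue
        admitted = (MIN_ENSEMBLE_SIZE <= net.n_genes <= MAX_ENSEMBLE_SIZE
                    and base.score > MIN_INITIAL_SCORE)
        rec = EnsembleRecord(dict(params, k=k, window=window, cutoff=cutoff),
                             net.n_genes, base.score, admitted)
        if admitted:
            singles = screen_single(net, v_n, v_c, n_initial=n_initial,
                                    n_perturbations=n_perturbations,
                                    seed=run_seed)
            doubles = screen_double(net, v_n, v_c, singles, top=top,
                                    n_initial=n_initial,
                                    n_perturbations=n_perturbations,
                                    seed=run_seed)
            rec.best_doubles = doubles[:top]
            hits = {r.label for r in singles + doubles
                    if r.fixation and r.score < CONSENSUS_SCORE}
            for label in hits:
                consensus[label] = consensus.get(label, 0) + 1
        records.append(rec)
    table = pd.DataFrame(
        [{"fixation": lab, "n_records": n} for lab, n in
         sorted(consensus.items(), key=lambda kv: (-kv[1], kv[0]))])
    return records, table


def common_targets(tf_a: str, tf_b: str,
                   edges: list[tuple[str, str, int]],
                   ) -> tuple[set[str], set[str]]:
    """Targets co-regulated by both TFs with consistent signs.

    ``edges`` are (tf, target, sign) regulon links.  Returns (positively
    co-regulated, negatively co-regulated); targets with mixed signs across
    the two TFs fall in neither set.
    """
    sources = {u for u, _, _ in edges}
    for tf in (tf_a, tf_b):
        if tf not in sources:
            raise KeyError(f"transcription factor {tf!r} absent from edge list")
    by_tf: dict[str, dict[str, int]] = {tf_a: {}, tf_b: {}}
    for u, v, s in edges:
        if u in by_tf:
            by_tf[u][v] = s
    shared = set(by_tf[tf_a]) & set(by_tf[tf_b])
    pos = {t for t in shared if by_tf[tf_a][t] == 1 and by_tf[tf_b][t] == 1}
    neg = {t for t in shared if by_tf[tf_a][t] == -1 and by_tf[tf_b][t] == -1}
    return pos, neg


def combine_rank_scores(table: pd.DataFrame, columns: list[str]) -> pd.Series:
    """Generic refinement plumbing: mean of per-column ranks (ascending =
    better) across user-supplied per-gene score columns."""
    ranks = table[columns].rank(ascending=True)
    return ranks.mean(axis=1).sort_values()
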