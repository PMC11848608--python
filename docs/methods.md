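# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## Transition-state detection

Cells are embedded by their copy-number profiles (cells × bins, any
numeric dosage scale) and related by a neighbor-joining tree over Euclidean
distances; NJ occasionally produces negative branch lengths, which are
clamped to zero.  The tree is cut into `n_clades` leaf groups (default 30)
by removing edges greedily in order of decreasing branch length; a removal
only counts when both sides retain a leaf, so each accepted cut splits one
clade in two, and ties are broken by traversal order.  The cutting method
is a design choice — any partition into connected leaf groups would do —
and `n_clades` should be scaled with cohort size (30 is appropriate for
hundreds of cells; it is clipped to the leaf count).

Each clade's mixture of normal- vs cancer-origin cells is scored with the
binary Shannon entropy `H = −p_n log₂ p_n − p_c log₂ p_c` (0·log 0 ≡ 0),
so `H ∈ [0, 1]` bits.  Clades with `H ≥ threshold` are called the
transition state.  The default threshold of **0.8 bits** is the smallest
round value that a 3:1 mixture (H ≈ 0.811) still clears: a clade
three-quarters pure is the weakest mixture we are willing to call "mixed".

The critical-transition index is the mean absolute pairwise Pearson
correlation between genes divided by the mean absolute pairwise Pearson
correlation between cells, diagonals excluded, constant rows/columns
dropped beforehand.  Absolute values are used for both numerator and
denominator; signed means would let anticorrelated pairs cancel and make
the index sign-convention dependent.  Spearman would be an equally
defensible choice; Pearson is the convention in the tipping-point
literature this index follows.

## Binarization and skeleton construction

Expression is smoothed per gene with a centered moving average along the
pseudotime order (truncated windows at the edges, output length = input
length).  The default window is ⌊0.08·n_cells⌋, inside the sub-10% regime
that removes cell-level stochasticity without erasing the transition
itself.  Binarization is two-means: the split of the sorted smoothed
values minimizing total within-cluster variance (the global 1-D k-means
optimum, found exactly by scanning the n−1 possible splits); the
higher-mean cluster maps to 1.  A constant series cannot be split and maps
to all-zeros with a warning — such genes carry no trajectory information.

Prior-network edges are kept when |Spearman ρ| between the smoothed
profiles of their endpoints reaches the cutoff (default 0.7); the retained
sign is the sign of ρ, overriding the prior annotation (with a warning on
conflicts), because the trajectory being modeled is the authority on how
the two genes co-move in *this* tissue.  The correlation filter applies to
prior edges only, not to all gene pairs: the prior encodes which
interactions are mechanistically plausible, and correlation alone cannot
add direction.  Terminal (outdegree-0) nodes are deleted iteratively —
they read the dynamics but cannot influence them — and the network is
restricted to strongly connected components of size ≥ 2, the feedback core
that can support multistability.  Singleton components are dropped even
though a self-loop technically is feedback: an isolated self-activator
only freezes its own state.  Nodes left without any activating input get a
positive self-loop, without which their rule class (sign-monotone in every
regulator) could never hold them ON.

## Rule inference

For gene g with regulators R, input–output pairs are
`{(I_t, O_{t+k})}_{t=1..m}`, `m = n_cells − k`, where `I_t` is the
binarized regulator vector at ordered position t and `O_{t+k}` the gene's
binarized value k positions later.  `k` must exceed the smoothing window
(default `k = window + 1`) so the averaged windows behind input and output
never share cells — otherwise the same measurements would appear on both
sides of the causal arrow.

The candidate class is every truth table over R that is (a) monotone
consistent with each edge sign and (b) essential in every regulator.
These are exactly the functions expressible with the skeleton's signed
edges and no vacuous regulators; the class is small (1, 2, 9, 114
candidates for 1–4 regulators) and is enumerated exhaustively in a fixed
lexicographic order, so tie sets are reproducible without any solver
dependency.  Regulator sets beyond 4 are reduced to the 4 highest-|ρ|
regulators with a warning (a 5-input class would have ~6000 candidates and
rapidly overfit m ≈ 180 pairs).

The score `S(f) = Σ_t 1[f(I_t) = O_{t+k}]` is maximized; all argmax-tied
candidates are combined by pointwise OR, with the tied set recorded as
provenance and the reported score recomputed for the combined table.  The
OR convention preserves every regulatory mechanism consistent with the
data but biases combined rules toward activation; see *Limitations*.

## Landscape quantification

Dynamics are synchronous: all genes update simultaneously, making the
state-transition graph deterministic.  Attractors are found by iterating
initial states to their terminal cycle (visited-state cache shared across
walks; cycles canonicalized by rotation), from either all 2ⁿ states
(exhaustive, n ≤ 25) or `n_initial` uniform random states (default 1000;
basin counts are then sample counts).  Attractors are ordered by
descending basin, then lexicographically.

The normal/cancer anchors `v_N, v_C` are the per-gene means of the
binarized matrix over the first/last 20% of the pseudotime order, rounded
with ties going to 1.  Any state projects onto the normal→cancer axis as

    d(v) = (v − v_N)·(v_C − v_N) / |v_C − v_N|²,

so `d(v_N) = 0`, `d(v_C) = 1`, and states beyond the anchors fall outside
[0, 1].  A cyclic attractor's d is the mean over its cycle states.

Attractor entropy measures valley depth.  For each basin state j (all of
them, or 512 sampled when the basin is larger), `n_perturb` trials
(default 100) each pick one gene uniformly, apply a uniform random
permutation to the output column of its truth table, iterate the perturbed
network from j to convergence, and map the outcome back to an original
attractor by re-converging its first cycle state under the unperturbed
rules.  Outcomes that re-converge to an attractor absent from the original
set are counted as their own category, keeping ΣP = 1.  The state entropy
is `S_i^j = −Σ_k P_k log₂ P_k` and the attractor entropy `S_i` its basin
mean; `S_max = log₂ N` for N attractors.  A fresh perturbation is drawn
per trial (no perturbed network is reused), which makes trials i.i.d. and
the entropy a well-defined expectation.

The cancer score is

    CS = Σ_k (1 − S_k/S_max) · (B_k / Σ_j B_j) · max(d_k, 0),

i.e. deep (low-entropy), wide (large-basin) valleys near the cancer pole
dominate.  The basin normalization runs over *all* attractors, making the
weights a probability distribution.  For a single attractor S_max = 0 and
the depth factor is defined as 1 (the continuous limit, since S is then
also 0).  Distances are clamped at zero inside the score only — a valley
behind the normal anchor is not negative malignancy — while raw d values
are reported unclamped.

## Reversion screening

A fixation replaces a gene's rule by a constant (0 = knockdown,
1 = overexpression); other rules are untouched.  The single screen
evaluates all 2n fixations plus the unperturbed control with the full
landscape recomputation; per-fixation seeds are derived deterministically
from the base seed so the screen is reproducible and the control row
reproduces the standalone landscape bit-for-bit.  The double screen takes
the top-5 distinct genes (each at its winning direction) and evaluates all
C(5,2) pairs through the same code path; a final score ≤ 0.1 is flagged a
successful reversion.  The ensemble scan reruns
build → infer → landscape → screen per hyperparameter set (defaults:
window ∈ {5%, 8%} of cells, k ∈ {window+1, 2·window}, cutoff ∈ {0.6,
0.7}), admits runs with 10–30 network nodes and initial score > 0.5, and
tallies per fixation set how many admitted runs scored it < 0.15.

`common_targets` intersects the signed target sets of two transcription
factors from a regulon edge list (same-sign targets only); a generic
mean-of-ranks utility is provided for combining user-supplied per-gene
score columns, since any specific weighting between, say, dependency and
enrichment evidence is a downstream analysis choice, not part of the
method.

## Synthetic data: what it emulates and what it does not

The generator encodes the snapshot picture of tumorigenesis: one sampled
population contains the entire normal→cancer path, so pseudotime-ordering
its cells recovers the transition.  Networks are built around a
mutual-inhibition master switch that is deliberately *asymmetric* —
normal pole `A = A & !B`, cancer pole `B = B | !A` — a transition state in
which the normal attractor is already destabilized (it holds only when
both A is on and B is off) while the cancer attractor self-sustains.
Both poles are exact synchronous fixed points, but the cancer basin is
the wider, deeper valley, so unperturbed cancer scores land near 0.75 —
the > 0.5 regime in which a reversion screen is meaningful rather than
trivial.  Additional toggle pairs are satellites slaved to the master
(`P = A & (P | !Q)`, `Q = B | (!P & !A)`), keeping exactly two global
attractors and full reversion under the master double fixation; leftover
genes are downstream readouts driven by the core, guaranteed to separate
the two states, and correctly discarded by SCC extraction.

Trajectories draw one changepoint per differing gene uniformly inside the
central 10% of pseudotime: a critical transition is abrupt, and the pure
20% end segments are exactly what the anchor-state definition assumes.
Continuous expression is the (noise-flipped) binary value plus
Uniform(0, 0.3) jitter plus a graded 0.2 ramp toward the gene's
cancer-state level.  The ramp models the graded within-phase expression
real trajectories show; without it a step profile's plateau ranks are pure
noise, which analytically caps the Spearman correlation between two
co-switching genes near 0.75 and puts the 0.7 edge-retention cutoff on a
knife edge.  Jitter plus ramp stay below the unit gap between the binary
levels, so two-means binarization of the smoothed profile recovers the
binary signal exactly.

Deliberately **not** emulated: scRNA-seq count noise (dropout, library
size, overdispersion), doublets, batch effects, pseudotime estimation
error, and CNV inference error (the CNV fixture plants clean segmental
gains/losses at ±0.5 with σ = 0.05 noise, mixed cells at half dosage).
Passing tests therefore demonstrate correctness of the algorithms under
the model's assumptions, not robustness to every artifact of real data.

## Numerical conventions and degenerate cases

- Truth tables index with the first regulator as the most significant bit;
  rule files round-trip byte-identically via full-minterm DNF.
- Basin fractions always sum to 1 by construction; attractors are verified
  closed under one synchronous step.
- Spearman with zero variance (constant gene) yields NaN and drops the
  edge; an empty pruned network and a feedback-free (DAG) network raise
  dedicated errors rather than returning empty results.
- Coinciding anchors (v_N = v_C) are a degenerate axis and raise.
- All randomness flows through `numpy.random.default_rng` seeds; every
  generator, sampler and screen is bit-reproducible under a fixed seed.
- Default problem sizes (200-cell trajectories, 8–12 gene networks, 1000
  initial states, 100 perturbations per basin state, 20-seed experiments)
  were chosen so the full experiment battery completes in about a minute
  while leaving Monte-Carlo error well below the decision thresholds
  (basin fractions ±1.4%, entropy ±0.05).

## Known limitations

- **OR-combination bias.** A single monotone trajectory cannot distinguish
  all members of the candidate class for multi-regulator genes; the OR
  rule then inflates combined rules toward activation.  For feedback genes
  slaved to a master switch this systematically retains a bistable
  residue after the master is fixed: in 10-gene cores the post-fixation
  cancer score floors near m/n (≈ 0.4 with four slaved pairs) instead of
  ~0.  Consequently the ensemble consensus bar (< 0.15) is reachable for
  the master pair itself on small cores, but not for large inferred cores,
  even when the ground-truth network reverts perfectly.  Screens on
  ground-truth rule files do not suffer from this.
- Attractor entropy is a Monte-Carlo estimate; comparing landscapes across
  runs requires shared seeds (the screens do this internally).
- Sampled attractor search can miss basins smaller than ~1/n_initial; the
  exhaustive mode is exact but limited to 25 genes.
- The rule class excludes non-monotone regulation (e.g. XOR-like dual
  roles) by construction.
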