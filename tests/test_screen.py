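import numpy as np
import pandas as pd
import pytest

from revert.landscape import anchor_states, find_attractors, quantify_landscape
from revert.network import BooleanNetwork, BooleanRule
from revert.screen import (
    apply_fixation,
    common_targets,
    combine_rank_scores,
    ensemble_scan,
    results_table,
    screen_double,
    screen_single,
    top_single_directions,
)
from revert.synthetic import generate
from revert.grn import build_skeleton, default_window
from revert.logic import infer_network


class TestApplyFixation:
    def test_toggle_fix_a_off_leaves_single_attractor(self, symmetric_toggle):
        fixed = apply_fixation(symmetric_toggle, {"A": 0})
        aset = find_attractors(fixed, exhaustive=True)
        assert aset.attractors == [((0, 1),)]
        assert aset.basin_counts == [4]

    def test_fix_all_genes_yields_the_fixation_vector(self, skewed_toggle):
        fixed = apply_fixation(skewed_toggle, {"A": 1, "B": 0})
        aset = find_attractors(fixed, exhaustive=True)
        assert aset.attractors == [((1, 0),)]

    def test_empty_fixation_is_identity(self, skewed_toggle):
        fixed = apply_fixation(skewed_toggle, {})
        for s in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            assert fixed.step(s) == skewed_toggle.step(s)

    def test_unknown_gene_rejected(self, skewed_toggle):
        with pytest.raises(KeyError):
            apply_fixation(skewed_toggle, {"Z": 1})

    def test_fixed_genes_hold_value_in_all_attractors(self, skewed_toggle):
        fixed = apply_fixation(skewed_toggle, {"B": 1})
        aset = find_attractors(fixed, exhaustive=True)
        b_idx = fixed.index("B")
        for cyc in aset.attractors:
            assert all(s[b_idx] == 1 for s in cyc)


class TestSingleScreen:
    def test_master_switch_fixations_rank_top(self, skewed_toggle):
        singles = screen_single(skewed_toggle, (1, 0), (0, 1),
                                n_initial=400, n_perturbations=50, seed=3)
        # ranking is a permutation of control + 2n fixations
        assert len(singles) == 2 * 2 + 1
        assert [r.rank for r in singles] == list(range(5))
        # restoring either pole beats the control
        control = next(r for r in singles if not r.fixation)
        best = singles[0]
        assert best.fixation in ({"A": 1}, {"B": 0})
        assert best.score < control.score

    def test_baseline_reproduced_bit_identically(self, skewed_toggle):
        singles = screen_single(skewed_toggle, (1, 0), (0, 1),
                                n_initial=300, n_perturbations=40, seed=11)
        control = next(r for r in singles if not r.fixation)
        alone = quantify_landscape(skewed_toggle, (1, 0), (0, 1),
                                   n_initial=300, n_perturbations=40, seed=11)
        assert control.score == alone.score
        assert control.summary.basin_counts == alone.basin_counts

    def test_neutral_fixation_matches_baseline_exhaustively(self):
        # C copies A but regulates nothing that feeds back; fixing C at the
        # value it holds in every attractor leaves the landscape unchanged
        net = BooleanNetwork(("A", "B", "C"), {
            "A": BooleanRule("A", ("A", "B"), (0, 0, 1, 0)),
            "B": BooleanRule("B", ("B", "A"), (1, 0, 1, 1)),
            "C": BooleanRule("C", ("C",), (0, 1)),
        })
        base = find_attractors(net, exhaustive=True)
        fixed = apply_fixation(net, {"C": 0})
        after = find_attractors(fixed, exhaustive=True)
        base_states = {a for cyc in base.attractors for a in cyc
                       if a[2] == 0}
        after_states = {a for cyc in after.attractors for a in cyc}
        assert after_states <= base_states


class TestDoubleScreen:
    def test_planted_pair_wins_and_reverts(self, skewed_toggle):
        singles = screen_single(skewed_toggle, (1, 0), (0, 1),
                                n_initial=400, n_perturbations=50, seed=5)
        doubles = screen_double(skewed_toggle, (1, 0), (0, 1), singles,
                                n_initial=400, n_perturbations=50, seed=5)
        assert doubles[0].fixation == {"A": 1, "B": 0}
        assert doubles[0].score <= 0.1

    def test_pair_count_for_five_top_genes(self):
        genes = tuple("ABCDE")
        rules = {}
        for i, g in enumerate(genes):
            prev = genes[i - 1]
            rules[g] = BooleanRule(g, (g, prev), (0, 1, 1, 1))
        net = BooleanNetwork(genes, rules)
        v_n, v_c = (0,) * 5, (1,) * 5
        singles = screen_single(net, v_n, v_c, n_initial=200,
                                n_perturbations=20, seed=1)
        doubles = screen_double(net, v_n, v_c, singles, top=5,
                                n_initial=200, n_perturbations=20, seed=1)
        assert len(doubles) == 10

    def test_top_directions_deduplicate_genes(self, skewed_toggle):
        singles = screen_single(skewed_toggle, (1, 0), (0, 1),
                                n_initial=200, n_perturbations=20, seed=2)
        tops = top_single_directions(singles, top=5)
        assert len(tops) == 2
        assert len({g for g, _ in tops}) == 2

    def test_results_table_flags_success(self, skewed_toggle):
        singles = screen_single(skewed_toggle, (1, 0), (0, 1),
                                n_initial=200, n_perturbations=20, seed=2)
        doubles = screen_double(skewed_toggle, (1, 0), (0, 1), singles,
                                n_initial=200, n_perturbations=20, seed=2)
        tab = results_table(doubles)
        assert bool(tab.iloc[0]["success"]) == bool(
            tab.iloc[0]["cancer_score"] <= 0.1)


class TestEnsemble:
    def test_admitted_records_rank_planted_switch_first(self):
        gt = generate(n_genes=12, n_toggle_pairs=5, n_cells=200,
                      flip_noise=0.0, seed=1)
        grid = [{"window": 10, "k": 11, "cutoff": 0.7},
                {"window": 16, "k": 17, "cutoff": 0.7}]
        records, consensus = ensemble_scan(
            gt.prior_network, gt.trajectory.raw, grid=grid,
            n_initial=400, n_perturbations=30, seed=0)
        admitted = [r for r in records if r.admitted]
        assert admitted, "expected admitted records for a 10-node core"
        a, b = gt.master_pair
        for r in admitted:
            assert 10 <= r.network_size <= 30
            assert r.initial_score > 0.5
            # the strongest double intervention involves the master switch
            top = r.best_doubles[0]
            assert set(top.fixation) & {a, b}
            assert top.score < r.initial_score
        if not consensus.empty:
            assert (consensus["n_records"] <= len(admitted)).all()

    def test_low_initial_score_excluded(self):
        # a single dominant normal attractor: initial score far below 0.5
        gt = generate(n_genes=10, n_toggle_pairs=5, n_cells=200,
                      flip_noise=0.0, seed=2)
        records, _ = ensemble_scan(gt.prior_network, gt.trajectory.raw,
                                   grid=[{"window": 16, "k": 17,
                                          "cutoff": 0.99}],
                                   n_initial=100, n_perturbations=10, seed=0)
        assert all(not r.admitted for r in records)


class TestCommonTargets:
    EDGES = [
        ("TF1", "t1", 1), ("TF2", "t1", 1),      # positive in both
        ("TF1", "t2", -1), ("TF2", "t2", -1),    # negative in both
        ("TF1", "t3", 1), ("TF2", "t3", -1),     # mixed -> neither
        ("TF1", "t4", 1),                        # only one TF
    ]

    def test_hand_enumerated_sets(self):
        pos, neg = common_targets("TF1", "TF2", self.EDGES)
        assert pos == {"t1"}
        assert neg == {"t2"}

    def test_missing_tf_rejected(self):
        with pytest.raises(KeyError):
            common_targets("TF1", "TFX", self.EDGES)

    def test_rank_combination_orders_by_mean_rank(self):
        df = pd.DataFrame({"dep": [0.1, 0.5, 0.9], "enr": [0.2, 0.1, 0.9]},
                          index=["g1", "g2", "g3"])
        combined = combine_rank_scores(df, ["dep", "enr"])
        assert list(combined.index) == ["g1", "g2", "g3"]
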