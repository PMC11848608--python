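import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from revert.landscape import (
    anchor_states,
    attractor_entropy,
    cancer_score,
    effective_distance,
    find_attractors,
    map_cells_to_landscape,
    quantify_landscape,
    synchronous_step,
)
from revert.network import BooleanNetwork, BooleanRule
from revert.synthetic import generate
from revert.grn import build_skeleton, default_window
from revert.logic import infer_network


class TestSynchronousStep:
    def test_fixed_point_stays(self, symmetric_toggle):
        assert synchronous_step(symmetric_toggle, (1, 0)) == (1, 0)

    def test_simultaneous_update(self, oscillator):
        # A' = !B, B' = A evaluated on the OLD state
        assert synchronous_step(oscillator, (0, 0)) == (1, 0)

    def test_deterministic(self, skewed_toggle):
        s = (1, 1)
        assert (synchronous_step(skewed_toggle, s)
                == synchronous_step(skewed_toggle, s))


class TestFindAttractors:
    def test_toggle_exhaustive(self, symmetric_toggle):
        aset = find_attractors(symmetric_toggle, exhaustive=True)
        as_sets = {frozenset(a) for a in aset.attractors}
        assert as_sets == {frozenset({(0, 1)}), frozenset({(1, 0)}),
                           frozenset({(0, 0), (1, 1)})}
        by_len = sorted(aset.basin_counts)
        assert by_len == [1, 1, 2]
        assert aset.verify_closed()

    def test_oscillator_single_four_cycle(self, oscillator):
        aset = find_attractors(oscillator, exhaustive=True)
        assert aset.n_attractors == 1
        assert len(aset.attractors[0]) == 4
        assert aset.basin_counts == [4]

    def test_sampled_deterministic_under_seed(self, skewed_toggle):
        a1 = find_attractors(skewed_toggle, n_random=1000, seed=7)
        a2 = find_attractors(skewed_toggle, n_random=1000, seed=7)
        assert a1.attractors == a2.attractors
        assert a1.basin_counts == a2.basin_counts

    def test_sampled_subset_of_exhaustive_with_proportional_basins(
            self, symmetric_toggle):
        ex = find_attractors(symmetric_toggle, exhaustive=True)
        sm = find_attractors(symmetric_toggle, n_random=1000, seed=1)
        ex_sets = {frozenset(a): b / ex.n_initial
                   for a, b in zip(ex.attractors, ex.basin_counts)}
        for attr, count in zip(sm.attractors, sm.basin_counts):
            assert frozenset(attr) in ex_sets
            assert count / 1000 == pytest.approx(
                ex_sets[frozenset(attr)], abs=0.05)

    def test_basin_fractions_sum_to_one(self, skewed_toggle):
        aset = find_attractors(skewed_toggle, n_random=500, seed=3)
        assert aset.basin_fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_size_guard(self):
        genes = tuple(f"G{i}" for i in range(26))
        rules = {g: BooleanRule(g, (g,), (0, 1)) for g in genes}
        with pytest.raises(ValueError):
            find_attractors(BooleanNetwork(genes, rules), exhaustive=True)


class TestAnchors:
    def test_noiseless_fixture_anchors_equal_truth(self):
        gt = generate(n_genes=6, n_cells=100, flip_noise=0.0, seed=3)
        w = default_window(100)
        _, _, binarized = build_skeleton(gt.prior_network, gt.trajectory.raw,
                                         window=w)
        v_n, v_c = anchor_states(binarized)
        assert v_n == gt.normal_state
        assert v_c == gt.cancer_state

    def test_rounding_with_tie_to_one(self):
        df = pd.DataFrame({"a": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                           "b": [1, 0, 0, 0, 0, 1, 1, 1, 1, 1]})
        v_n, v_c = anchor_states(df, fraction=0.2)
        assert v_n == (1, 1)   # mean 0.5 rounds up
        assert v_c == (0, 1)

    def test_degenerate_axis_rejected(self):
        df = pd.DataFrame({"a": [1] * 10, "b": [0] * 10})
        with pytest.raises(ValueError):
            anchor_states(df, fraction=1.0)


class TestEffectiveDistance:
    @pytest.mark.parametrize("v,expected", [
        ((0, 0), 0.0),
        ((1, 1), 1.0),
        ((1, 0), 0.5),
        ((0, 1), 0.5),
    ])
    def test_projection_on_diagonal_axis(self, v, expected):
        assert effective_distance(v, (0, 0), (1, 1)) == pytest.approx(expected)

    def test_beyond_anchor_exceeds_one(self):
        assert effective_distance((2, 2), (0, 0), (1, 1)) == pytest.approx(2.0)

    def test_degenerate_axis_raises(self):
        with pytest.raises(ValueError):
            effective_distance((1, 0), (1, 1), (1, 1))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=3, max_size=8))
    def test_anchor_endpoints_map_to_zero_and_one(self, bits):
        v_n = tuple(bits)
        v_c = tuple(1 - b for b in bits)
        assert effective_distance(v_n, v_n, v_c) == pytest.approx(0.0)
        assert effective_distance(v_c, v_n, v_c) == pytest.approx(1.0)


class TestAttractorEntropy:
    def test_single_attractor_has_zero_entropy(self):
        net = BooleanNetwork(("A",), {"A": BooleanRule("A", ("A",), (1, 1))})
        aset = find_attractors(net, exhaustive=True)
        s, _ = attractor_entropy(net, aset, 50, seed=0)
        assert s == [0.0]

    def test_entropy_bounded_by_log2_n(self, symmetric_toggle):
        aset = find_attractors(symmetric_toggle, exhaustive=True)
        s, s_states = attractor_entropy(symmetric_toggle, aset, 200, seed=1)
        bound = math.log2(aset.n_attractors)
        assert all(0 <= v <= bound + 1e-9 for v in s)
        assert all(0 <= v <= bound + 1e-9
                   for per in s_states for v in per)

    def test_estimates_stable_under_doubling(self, skewed_toggle):
        aset = find_attractors(skewed_toggle, exhaustive=True)
        s1, _ = attractor_entropy(skewed_toggle, aset, 400, seed=5)
        s2, _ = attractor_entropy(skewed_toggle, aset, 800, seed=6)
        assert np.allclose(s1, s2, atol=0.05)


class TestCancerScore:
    def test_single_normal_attractor_scores_zero(self):
        assert cancer_score([0.0], [0.0], [100], 0.0) == 0.0

    def test_single_cancer_attractor_scores_one(self):
        assert cancer_score([1.0], [0.0], [100], 0.0) == 1.0

    def test_two_attractor_arithmetic(self):
        assert cancer_score([0.0, 1.0], [0.0, 0.0], [600, 400], 1.0) \
            == pytest.approx(0.4)

    def test_negative_distance_clamped(self):
        assert cancer_score([-0.5, 1.0], [0.0, 0.0], [500, 500], 1.0) \
            == pytest.approx(0.5)

    def test_monotone_in_distance_and_heavy_basins(self):
        d, s, b = [0.2, 0.8], [0.3, 0.3], [500, 500]
        base = cancer_score(d, s, b, 1.0)
        assert cancer_score([0.3, 0.8], s, b, 1.0) > base
        # growing the basin of the above-average-d attractor raises the score
        assert cancer_score(d, s, [500, 600], 1.0) > base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cancer_score([0.5], [-0.1], [10], 1.0)
        with pytest.raises(ValueError):
            cancer_score([0.5], [0.1], [0], 1.0)


class TestQuantifyAndMapping:
    def test_skewed_toggle_summary(self, skewed_toggle):
        ls = quantify_landscape(skewed_toggle, (1, 0), (0, 1),
                                n_initial=1000, n_perturbations=100, seed=2)
        assert ls.attractor_set.n_attractors == 2
        assert ls.s_max == pytest.approx(1.0)
        # cancer basin dominates: 3 of 4 states
        assert ls.score > 0.5

    def test_cells_map_to_expected_attractors(self):
        gt = generate(n_genes=6, n_cells=100, flip_noise=0.0, seed=3)
        w = default_window(100)
        skel, _, binarized = build_skeleton(gt.prior_network,
                                            gt.trajectory.raw, window=w)
        net = infer_network(binarized[list(skel.nodes)], skel, window=w)
        sub = binarized[list(net.genes)]
        v_n, v_c = anchor_states(sub)
        ls = quantify_landscape(net, v_n, v_c, n_initial=200,
                                n_perturbations=20, seed=0)
        mapping = map_cells_to_landscape(net, sub, v_n, v_c, ls)
        assert len(mapping) == 100
        assert mapping.iloc[0]["d_attractor"] == pytest.approx(0.0)
        assert mapping.iloc[-1]["d_attractor"] == pytest.approx(1.0)
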