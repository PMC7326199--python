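"""Constant-sign machinery: unobserved paths, molecular distance,
sum-product and infinitesimal monotonicity, and induced regulatory graphs."""

import math

import numpy as np
import pytest

from grnode.csp import (
    BOTH, EMPTY, MINUS, PLUS,
    b_inf, b_sum, check_dependency, gene_regulatory_graph, gnw_to_ode_system,
    molecular_distance, molecular_graph, sum_product_delta, unobserved_paths,
)
from grnode.gnw import sample_model
from grnode.graphs import flowering_graph

from conftest import random_signed_digraph


def positive_states(rng, n, count):
    return [(rng.uniform(0.05, 1.0, n), None) for _ in range(count)]


class TestPaths:
    def test_complex_layer_has_one_three_hop_path(self, example2_system):
        mg = molecular_graph(example2_system)
        paths = unobserved_paths(mg, 2, i=1, j=2, q=3)
        assert paths == [(2, 5, 3, 1)]

    def test_complex_layer_has_one_four_hop_path(self, example2_system):
        mg = molecular_graph(example2_system)
        paths = unobserved_paths(mg, 2, i=1, j=2, q=4)
        assert paths == [(2, 5, 4, 3, 1)]

    def test_disconnected_pair_has_no_paths(self, example2_system):
        mg = molecular_graph(example2_system)
        for q in range(1, 5):
            assert unobserved_paths(mg, 2, i=2, j=1, q=q) == []

    def test_self_effect_rejected(self, example2_system):
        mg = molecular_graph(example2_system)
        with pytest.raises(ValueError):
            unobserved_paths(mg, 2, i=1, j=1, q=2)

    def test_molecular_distance(self, example2_system):
        mg = molecular_graph(example2_system)
        assert molecular_distance(mg, 2, 1, 2) == 3
        assert math.isinf(molecular_distance(mg, 2, 2, 1))

    def test_gnw_edges_are_distance_two(self):
        model = sample_model(flowering_graph(), 0)
        sys = gnw_to_ode_system(model)
        mg = molecular_graph(sys)
        for (i, j) in model.graph.edges:
            assert molecular_distance(mg, 5, i, j) == 2
        assert math.isinf(molecular_distance(mg, 5, 3, 1))  # no edge 3->1


class TestSumProduct:
    def test_boundary_point_gives_zero(self, example1_system):
        # l1*l2 = x1*x2*x3^2 exactly at (1, 1, 1) with unit parameters
        delta = sum_product_delta(example1_system, 3, 4,
                                  np.array([1, 1, 1, 0.0]), (1.0, 1.0))
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_below_boundary_positive(self, example1_system):
        delta = sum_product_delta(example1_system, 3, 4,
                                  np.array([1, 1, 0.5, 0.0]), (1.0, 1.0))
        assert delta > 0

    def test_no_path_raises(self, example1_system):
        with pytest.raises(ValueError):
            sum_product_delta(example1_system, 4, 3, np.zeros(4), (1.0, 1.0))

    @pytest.mark.parametrize("x3,expected", [
        (0.2, PLUS), (0.5, PLUS), (0.9, PLUS),
        (1.2, MINUS), (2.0, MINUS), (5.0, MINUS),
    ])
    def test_sign_regions(self, example1_system, x3, expected):
        state = np.array([1.0, 1.0, x3, 0.0])
        assert b_sum(example1_system, 3, 4, state, (1.0, 1.0)) == expected

    def test_boundary_classified_indeterminate(self, example1_system):
        state = np.array([1.0, 1.0, 1.0, 0.0])
        assert b_sum(example1_system, 3, 4, state, (1.0, 1.0)) == BOTH

    def test_no_path_gives_empty(self, example1_system):
        assert b_sum(example1_system, 4, 3, np.ones(4), (1.0, 1.0)) == EMPTY

    def test_gnw_edge_signs_match_graph(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_signed_digraph(rng, n_max=5)
            model = sample_model(g, int(rng.integers(2 ** 31)))
            sys = gnw_to_ode_system(model)
            state = rng.uniform(0.05, 1.0, 2 * g.n_vertices)
            for (i, j) in g.edges:
                expected = PLUS if g.sign[(i, j)] > 0 else MINUS
                assert b_sum(sys, i, j, state, None) == expected


class TestAnalyticPartials:
    def test_match_finite_differences(self):
        rng = np.random.default_rng(13)
        model = sample_model(flowering_graph(), 29)
        sys = gnw_to_ode_system(model)
        n_int = sys.n_internal
        for _ in range(5):
            state = rng.uniform(0.1, 1.0, n_int)
            for (k, l) in sys.dependency:
                analytic = sys.partial(k, l, state)
                step = 1e-6
                up = state.copy(); up[k - 1] += step
                dn = state.copy(); dn[k - 1] -= step
                fd = (sys.rhs(up, None)[l - 1] - sys.rhs(dn, None)[l - 1]) / (2 * step)
                assert analytic == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestInfinitesimalProbe:
    def test_no_path_gives_empty(self, example2_system):
        assert b_inf(example2_system, 2, 1, np.array([0.3, 0.2, 0.3, 0.5, 0.1])) \
            == EMPTY

    def test_shortest_path_dominates_in_complex_layer(self, example2_system):
        # 3-hop activating path beats the 4-hop repressing one near t=0
        state = np.array([0.3, 0.2, 0.3, 0.5, 0.15])
        assert b_inf(example2_system, 1, 2, state) == PLUS

    def test_sign_switch_detected(self, example1_system):
        lo = b_inf(example1_system, 3, 4, np.array([1, 1, 0.5, 0.0]), (1.0, 1.0))
        hi = b_inf(example1_system, 3, 4, np.array([1, 1, 2.0, 0.0]), (1.0, 1.0))
        assert lo == PLUS
        assert hi == MINUS

    def test_self_effect_rejected(self, example1_system):
        with pytest.raises(ValueError):
            b_inf(example1_system, 3, 3, np.ones(4), (1.0, 1.0))

    def test_agrees_with_sum_product_on_sampled_models(self):
        rng = np.random.default_rng(19)
        for _ in range(5):
            g = random_signed_digraph(rng, n_max=4)
            model = sample_model(g, int(rng.integers(2 ** 31)))
            sys = gnw_to_ode_system(model)
            state = rng.uniform(0.05, 1.0, 2 * g.n_vertices)
            for (i, j) in g.edges:
                bs = b_sum(sys, i, j, state, None)
                if bs in (PLUS, MINUS):
                    assert b_inf(sys, i, j, state, None) == bs


class TestGeneRegulatoryGraph:
    def test_flowering_graph_recovered(self):
        g = flowering_graph()
        model = sample_model(g, 101)
        sys = gnw_to_ode_system(model)
        rng = np.random.default_rng(7)
        grg = gene_regulatory_graph(sys, positive_states(rng, 10, 100))
        assert grg.csp
        assert grg.to_signed_digraph() == g

    def test_straddling_sample_breaks_csp(self, example1_system):
        sample = [
            (np.array([1.0, 1.0, 0.5, 0.0]), (1.0, 1.0)),
            (np.array([1.0, 1.0, 2.0, 0.0]), (1.0, 1.0)),
        ]
        grg = gene_regulatory_graph(example1_system, sample)
        assert grg.edge_signs[(3, 4)] == BOTH
        assert not grg.csp
        with pytest.raises(ValueError):
            grg.to_signed_digraph()

    def test_single_generic_state_always_csp(self, example1_system):
        grg = gene_regulatory_graph(
            example1_system, [(np.array([1.0, 1.0, 0.5, 0.0]), (1.0, 1.0))]
        )
        assert grg.csp

    def test_union_is_monotone_in_the_sample(self):
        model = sample_model(flowering_graph(), 3)
        sys = gnw_to_ode_system(model)
        rng = np.random.default_rng(23)
        sample = positive_states(rng, 10, 8)
        small = gene_regulatory_graph(sys, sample[:3])
        large = gene_regulatory_graph(sys, sample)
        for pair, signs in small.edge_signs.items():
            assert signs <= large.edge_signs[pair]

    def test_empty_sample_rejected(self, example1_system):
        with pytest.raises(ValueError):
            gene_regulatory_graph(example1_system, [])

    def test_report_is_json_ready(self):
        model = sample_model(flowering_graph(), 3)
        sys = gnw_to_ode_system(model)
        rng = np.random.default_rng(2)
        rep = gene_regulatory_graph(sys, positive_states(rng, 10, 5)).report()
        assert rep["csp"] is True
        assert len(rep["edges"]) == 7


class TestDependencyCheck:
    def test_inactive_declared_edge_warns(self):
        def rhs(state, params):
            return np.array([0.0, state[0]])

        from grnode.csp import OdeSystem
        sys = OdeSystem(
            n_obs=2, n_unobs=0, rhs=rhs,
            dependency=frozenset({(1, 2), (2, 1)}),  # (2,1) never active
        )
        with pytest.warns(UserWarning, match="never active"):
            missing = check_dependency(sys, [np.ones(2), np.full(2, 0.3)])
        assert missing == {(2, 1)}
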