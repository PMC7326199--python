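"""Module activation kinetics, production rates, dynamics, enumeration,
random sampling and parameter accounting."""

import itertools
import math

import numpy as np
import pytest

from grnode.gnw import (
    GnwModel, ModuleStructure, RegModule,
    count_parameters, count_partitions, derivative_field,
    enumerate_module_structures, model_from_json, model_to_json,
    module_activation, module_activation_partials, nondimensionalize,
    normalized_expression, production_rate, sample_model, set_partitions,
)
from grnode.graphs import SignedDigraph, flowering_graph, repressilator_graph

from conftest import random_signed_digraph


def single_gene_model(alpha=1.0, delta=1.0, rho=1.0, production="linear"):
    g = SignedDigraph(n_vertices=1, sign={})
    return GnwModel(
        graph=g, modules={1: ()}, alpha_basal={1: alpha}, k={}, h={},
        rho={1: rho}, delta_m={1: delta}, production=production,
    )


def make_structure(activators, deactivators=(), c=1, r=0):
    a, d = frozenset(activators), frozenset(deactivators)
    return ModuleStructure(a | d, a, d, c, r)


class TestNormalizedExpression:
    @pytest.mark.parametrize("y,k,h,expected", [
        (0.7, 0.7, 3, 1.0),
        (0.5, 1.0, 2, 0.25),
        (0.0, 0.3, 2, 0.0),
    ])
    def test_values(self, y, k, h, expected):
        assert normalized_expression(y, k, h) == pytest.approx(expected)

    def test_negative_protein_rejected(self):
        with pytest.raises(ValueError):
            normalized_expression(-0.1, 1.0, 2)


class TestModuleActivation:
    def test_type1_single_activator(self):
        m = make_structure([1])
        assert module_activation(m, {1: 1.0}) == pytest.approx(0.5)

    def test_type2_pair(self):
        m = make_structure([1, 2], c=1, r=1)
        assert module_activation(m, {1: 1.0, 2: 1.0}) == pytest.approx(0.5)

    def test_type3_one_each(self):
        m = make_structure([1], [2], c=1, r=1)
        assert module_activation(m, {1: 1.0, 2: 1.0}) == pytest.approx(1 / 3)

    def test_missing_input_rejected(self):
        m = make_structure([1, 2], r=1)
        with pytest.raises(ValueError):
            module_activation(m, {1: 1.0})

    def test_forcing_type3_on_type2_module_rejected(self):
        m = make_structure([1, 2], c=1, r=1)  # complex, no deactivators
        with pytest.raises(ValueError):
            module_activation(m, {1: 1.0, 2: 1.0}, module_type=3)

    def test_single_input_must_be_independent_activator(self):
        with pytest.raises(ValueError):
            make_structure([1], r=1)
        with pytest.raises(ValueError):
            ModuleStructure(frozenset({1}), frozenset(), frozenset({1}), -1, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_activation_in_unit_interval_and_monotone(self, seed):
        # random module with up to 4 inputs: 0 < M < 1 and dM/dnu has the
        # sign of the input's role, for every type
        rng = np.random.default_rng(seed)
        n_in = int(rng.integers(2, 5))
        inputs = list(range(1, n_in + 1))
        n_act = int(rng.integers(1, n_in + 1))
        r = int(rng.integers(0, 2))
        m = make_structure(inputs[:n_act], inputs[n_act:],
                           c=int(rng.choice([1, -1])), r=r)
        nu = {i: float(rng.uniform(0.1, 3.0)) for i in inputs}
        M = module_activation(m, nu)
        assert 0.0 < M < 1.0
        grads = module_activation_partials(m, nu)
        eps = 1e-7
        for i in inputs:
            up = dict(nu); up[i] += eps
            dn = dict(nu); dn[i] -= eps
            fd = (module_activation(m, up) - module_activation(m, dn)) / (2 * eps)
            assert grads[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)
            if i in m.activators:
                assert grads[i] > 0
            else:
                assert grads[i] < 0


class TestProductionRate:
    def _one_module_model(self, alpha, beta, c, production="linear"):
        g = SignedDigraph(n_vertices=2, sign={(1, 2): c})
        mod = RegModule(2, make_structure([1], c=c), beta)
        return GnwModel(
            graph=g, modules={1: (), 2: (mod,)},
            alpha_basal={1: 0.5, 2: alpha}, k={(1, 2): 1.0}, h={(1, 2): 1},
            rho={1: 1.0, 2: 1.0}, delta_m={1: 0.5, 2: 1.0},
            production=production,
        )

    def test_enhancer_half_activation(self):
        # M = nu/(1+nu) = 0.5 at y = k, so rate = 0.2 + 0.8 * 0.5
        model = self._one_module_model(0.2, 0.8, c=1)
        assert production_rate(model, 2, [1.0, 0.0]) == pytest.approx(0.6)

    def test_all_modules_off_gives_basal(self):
        for mode in ("linear", "truncated", "clip"):
            model = self._one_module_model(0.2, 0.8, c=1, production=mode)
            assert production_rate(model, 2, [0.0, 0.0]) == pytest.approx(0.2)

    def test_truncated_silencer_clips_to_zero(self):
        # fully active silencer: alpha 0.1, effect -0.5 -> clip(-0.4) = 0
        model = self._one_module_model(0.1, 0.5, c=-1, production="truncated")
        big_y = 1e9  # M -> 1
        assert production_rate(model, 2, [big_y, 0.0]) == pytest.approx(0.0, abs=1e-8)

    def test_unregulated_gene_returns_basal(self):
        model = single_gene_model(alpha=0.7)
        assert production_rate(model, 1, [0.3]) == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(8))
    def test_expectation_form_matches_linear_without_clipping(self, seed):
        # the per-configuration expectation with *unclipped* activities
        # collapses to basal + sum c*beta*M for any number of modules
        rng = np.random.default_rng(seed)
        n_mod = int(rng.integers(1, 5))
        mods = []
        for idx in range(n_mod):
            c = int(rng.choice([1, -1]))
            mods.append((c, float(rng.uniform(0.1, 1.0)), float(rng.uniform(0, 1))))
        alpha = float(rng.uniform(0, 0.3))
        linear = alpha + sum(c * b * M for c, b, M in mods)
        expect = 0.0
        for states in itertools.product((0, 1), repeat=n_mod):
            a_s = alpha + sum(c * b for (c, b, _), s in zip(mods, states) if s)
            p = math.prod(M if s else 1 - M for (_, _, M), s in zip(mods, states))
            expect += a_s * p
        assert expect == pytest.approx(linear, rel=1e-12)


class TestDynamics:
    def test_fixed_point_is_stationary(self):
        model = single_gene_model(alpha=1.0, delta=1.0)
        dx, dy = derivative_field(model)([1.0], [1.0])
        assert dx == pytest.approx(0.0)
        assert dy == pytest.approx(0.0)

    def test_isolated_gene_from_origin(self):
        model = single_gene_model(alpha=1.0, delta=1.0)
        dx, dy = derivative_field(model)([0.0], [0.0])
        assert dx[0] == pytest.approx(1.0)
        assert dy[0] == pytest.approx(0.0)

    def test_negative_state_rejected(self):
        model = single_gene_model()
        with pytest.raises(ValueError):
            derivative_field(model)([-0.1], [0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_mrna_rate_bounded_by_degradation(self, seed):
        # nondimensionalized: 0 <= f_j <= delta_j, so |dx_j| <= delta_j on [0,1]
        rng = np.random.default_rng(seed)
        g = random_signed_digraph(rng, n_max=5)
        model = sample_model(g, int(rng.integers(2 ** 31)))
        field = derivative_field(model)
        n = model.n_genes
        delta = np.array([model.delta_m[j] for j in range(1, n + 1)])
        for _ in range(5):
            dx, _ = field(rng.uniform(0, 1, n), rng.uniform(0, 1, n))
            assert np.all(dx >= -delta - 1e-12)
            assert np.all(dx <= delta + 1e-12)


class TestNondimensionalize:
    def test_degradation_equals_total_production(self):
        g = SignedDigraph(n_vertices=2, sign={(1, 2): 1})
        mod = RegModule(2, make_structure([1]), 0.8)
        model = GnwModel(
            graph=g, modules={1: (), 2: (mod,)},
            alpha_basal={1: 1.0, 2: 0.2}, k={(1, 2): 1.0}, h={(1, 2): 2},
            rho={1: 1.0, 2: 1.0}, delta_m={1: 9.0, 2: 9.0},
        )
        nd = nondimensionalize(model)
        assert nd.delta_m[2] == pytest.approx(1.0)
        assert nd.delta_m[1] == pytest.approx(1.0)
        again = nondimensionalize(nd)
        assert again.delta_m == nd.delta_m

    def test_all_zero_rates_rejected(self):
        model = single_gene_model(alpha=0.0)
        with pytest.raises(ValueError):
            nondimensionalize(model)


class TestEnumeration:
    def test_flowering_counts(self):
        g = flowering_graph()
        counts = {j: len(enumerate_module_structures(g, j)) for j in range(1, 6)}
        assert counts == {1: 1, 2: 1, 3: 3, 4: 1, 5: 5}
        assert counts[3] * counts[5] == 15

    def test_unregulated_gene_empty(self):
        g = SignedDigraph(n_vertices=2, sign={(1, 2): 1})
        assert enumerate_module_structures(g, 1) == []

    def test_gene3_structures_in_canonical_order(self):
        # two + regulators: one independent module, one synergistic module,
        # then two single-activator modules
        g = flowering_graph()
        s1, s2, s3 = enumerate_module_structures(g, 3)
        assert len(s1) == 1 and s1[0].r == 0 and s1[0].inputs == {1, 2}
        assert len(s2) == 1 and s2[0].r == 1
        assert len(s3) == 2 and all(len(m.inputs) == 1 for m in s3)

    def test_gene5_structures_match_known_forms(self):
        # one + (gene 4) and one - (gene 3) regulator: enhancer/silencer x
        # independent/synergistic on the joint module, then two modules
        g = flowering_graph()
        structs = enumerate_module_structures(g, 5)
        shapes = [
            tuple((m.c, m.r, tuple(sorted(m.activators))) for m in s)
            for s in structs
        ]
        assert shapes == [
            ((1, 0, (4,)),),
            ((-1, 0, (3,)),),
            ((1, 1, (4,)),),
            ((-1, 1, (3,)),),
            ((-1, 0, (3,)), (1, 0, (4,))),
        ]

    def test_all_structures_sign_consistent_and_unique(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = random_signed_digraph(rng, n_max=5)
            for j in range(1, g.n_vertices + 1):
                structs = enumerate_module_structures(g, j)
                assert len(set(structs)) == len(structs)
                for s in structs:
                    for m in s:
                        assert m.sign_consistent(g, j)

    def test_partition_count_matches_bell_number(self):
        for K in range(1, 7):
            assert len(list(set_partitions(range(K)))) == count_partitions(K)


class TestBellNumbers:
    def test_first_ten(self):
        assert [count_partitions(k) for k in range(1, 11)] == \
            [1, 2, 5, 15, 52, 203, 877, 4140, 21147, 115975]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            count_partitions(0)


class TestSampleModel:
    def test_flowering_structures_come_from_enumeration(self):
        g = flowering_graph()
        opts3 = enumerate_module_structures(g, 3)
        opts5 = enumerate_module_structures(g, 5)
        for seed in range(10):
            m = sample_model(g, seed)
            assert tuple(mm.structure for mm in m.modules[3]) in opts3
            assert tuple(mm.structure for mm in m.modules[5]) in opts5

    def test_repressilator_modules_are_single_activator_silencers(self):
        m = sample_model(repressilator_graph(), 5)
        for j in range(1, 6):
            (mod,) = m.modules[j]
            assert mod.c == -1
            assert mod.r == 0
            assert len(mod.activators) == 1
            assert not mod.deactivators

    def test_same_seed_identical_serialization(self):
        g = flowering_graph()
        assert model_to_json(sample_model(g, 9)) == model_to_json(sample_model(g, 9))

    def test_sign_consistency_over_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            g = random_signed_digraph(rng)
            m = sample_model(g, int(rng.integers(2 ** 31)))
            for j in range(1, g.n_vertices + 1):
                for mod in m.modules[j]:
                    assert mod.sign_consistent(g, j)
            # nondimensionalized by construction
            for j in range(1, g.n_vertices + 1):
                total = m.alpha_basal[j] + sum(mm.beta for mm in m.modules[j])
                assert m.delta_m[j] == pytest.approx(total)


class TestCountParameters:
    @pytest.mark.parametrize("cls,S,expected", [
        ("F[1,1]+", 1, 34),
        ("F[3,5]+", 1, 36),
        ("F[1,1]-", 1, 34),
        ("R", 1, 30),
        ("F[1,1]+", 2, 44),
        ("F[1,1]+", 5, 74),
        ("F[1,1]+", 10, 124),
        ("F[3,5]+", 10, 126),
        ("R", 10, 120),
    ])
    def test_table_of_counts(self, cls, S, expected):
        assert count_parameters(cls, S) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            count_parameters("Q[1,1]+", 1)


class TestSerialization:
    def test_round_trip(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            g = random_signed_digraph(rng, n_max=5)
            m = sample_model(g, int(rng.integers(2 ** 31)))
            m2 = model_from_json(model_to_json(m))
            assert model_to_json(m) == model_to_json(m2)
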