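"""Network generation: degree sampling, wiring, biases, rule tables, I/O."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hetrbn import (
    BiasDistributionSpec,
    DegreeDistributionSpec,
    SpecError,
    build_rbn,
    build_regular_topology,
    build_rules,
    model_from_json,
    model_to_json,
    sample_biases,
    sample_out_degrees,
    wire_from_out_degrees,
)


class TestSampleOutDegrees:
    def test_regular_is_constant(self, rng):
        out = sample_out_degrees(DegreeDistributionSpec("regular", 2), 9, rng)
        assert out.tolist() == [2] * 9

    def test_poisson_mean_recovers_k(self, rng):
        out = sample_out_degrees(DegreeDistributionSpec("poisson", 5.0), 10_000, rng)
        assert abs(out.mean() - 5.0) < 3 * np.sqrt(5.0 / 10_000)

    def test_exponential_is_overdispersed_relative_to_poisson(self, rng):
        poi = sample_out_degrees(DegreeDistributionSpec("poisson", 5.0), 10_000, rng)
        exp = sample_out_degrees(DegreeDistributionSpec("exponential", 5.0), 10_000, rng)
        assert exp.var() > poi.var()

    def test_exponential_min_degree_flag(self, rng):
        out = sample_out_degrees(
            DegreeDistributionSpec("exponential", 1.0, min_degree=1), 2_000, rng
        )
        assert out.min() >= 1

    def test_regular_requires_integer_k(self):
        with pytest.raises(SpecError):
            DegreeDistributionSpec("regular", 2.5)

    @pytest.mark.parametrize("kind,mean", [("poisson", 4.0), ("exponential", 4.0)])
    def test_distribution_recovery_gof(self, kind, mean, rng):
        """Chi-square goodness of fit against the target pmf at alpha=0.01."""
        n = 10_000
        out = sample_out_degrees(DegreeDistributionSpec(kind, mean), n, rng)
        hi = int(out.max())
        counts = np.bincount(out, minlength=hi + 1)
        if kind == "poisson":
            pmf = stats.poisson.pmf(np.arange(hi + 1), mean)
        else:
            # discretization: round-to-nearest of Exp(mean), floored at 0
            edges = np.arange(hi + 2) - 0.5
            cdf = stats.expon.cdf(np.clip(edges, 0, None), scale=mean)
            pmf = np.diff(cdf)
        pmf = np.append(pmf, 1.0 - pmf.sum())  # tail bucket
        counts = np.append(counts, 0)
        keep = pmf * n >= 5
        chi2 = ((counts[keep] - n * pmf[keep]) ** 2 / (n * pmf[keep])).sum()
        chi2 += (counts[~keep].sum() - n * pmf[~keep].sum()) ** 2 / max(
            n * pmf[~keep].sum(), 1e-12
        )
        dof = keep.sum()  # conservative
        assert stats.chi2.sf(chi2, dof) > 0.01


class TestWiring:
    def test_all_zero_out_degrees_gives_empty_graph(self, rng):
        topo = wire_from_out_degrees([0, 0, 0], rng)
        assert all(len(lst) == 0 for lst in topo.in_neighbors)
        assert topo.out_degree.tolist() == [0, 0, 0]

    def test_single_node_forced_self_loop(self, rng):
        topo = wire_from_out_degrees([3], rng)
        # duplicates collapse: one distinct target available
        assert topo.in_neighbors[0].tolist() == [0]

    def test_edge_conservation(self, rng):
        for _ in range(20):
            degs = rng.integers(0, 8, size=30)
            topo = wire_from_out_degrees(degs, rng)
            assert topo.in_degree.sum() == topo.out_degree.sum()
            assert np.array_equal(topo.out_degree, np.minimum(degs, 30))

    def test_expected_in_degree_symmetric(self, rng):
        total = np.zeros(2)
        n_trials = 400
        for _ in range(n_trials):
            topo = wire_from_out_degrees([2, 2], rng)
            total += topo.in_degree
        assert np.allclose(total / n_trials, 2.0)  # N=2, d=2 forces both targets

    def test_in_neighbor_lists_are_distinct(self, rng):
        topo = wire_from_out_degrees(rng.integers(0, 30, size=50), rng)
        for lst in topo.in_neighbors:
            assert len(set(lst.tolist())) == len(lst)

    def test_negative_degree_rejected(self, rng):
        with pytest.raises(SpecError):
            wire_from_out_degrees([1, -1], rng)


class TestRegularTopology:
    def test_fixed_in_degree(self, rng):
        topo = build_regular_topology(9, 2, rng)
        assert all(len(lst) == 2 for lst in topo.in_neighbors)

    def test_single_node_self_loop(self, rng):
        topo = build_regular_topology(1, 1, rng)
        assert topo.in_neighbors[0].tolist() == [0]

    def test_mean_out_degree_exact(self, rng):
        topo = build_regular_topology(50, 5, rng)
        assert topo.out_degree.mean() == 5.0  # edge-count conservation

    def test_invalid_k(self, rng):
        with pytest.raises(SpecError):
            build_regular_topology(5, 0, rng)


class TestSampleBiases:
    def test_point_is_constant(self, rng):
        assert sample_biases(BiasDistributionSpec("point", 0.5), 5, rng).tolist() == [0.5] * 5

    def test_triangular_mean(self, rng):
        b = sample_biases(BiasDistributionSpec("triangular", 0.5), 10_000, rng)
        assert abs(b.mean() - 0.5) < 0.01

    def test_uniform_sd_matches_theory(self, rng):
        b = sample_biases(BiasDistributionSpec("uniform", 0.5), 10_000, rng)
        assert abs(b.std() - 0.288) < 0.01  # 1/sqrt(12)

    def test_gaussian_respects_domain(self, rng):
        spec = BiasDistributionSpec("gaussian", 0.5, sd=0.5, domain=(0.2, 0.8))
        b = sample_biases(spec, 5_000, rng)
        assert b.min() >= 0.2 and b.max() <= 0.8
        assert abs(b.mean() - 0.5) < 0.02  # symmetric truncation preserves the mean

    def test_asymmetric_triangular_mode(self, rng):
        b = sample_biases(BiasDistributionSpec("triangular", 0.25), 20_000, rng)
        # mode at 0.25 on [0,1]: mean of triangular(0, 0.25, 1) = 5/12
        assert abs(b.mean() - 5 / 12) < 0.01

    def test_domain_outside_unit_interval_rejected(self):
        with pytest.raises(SpecError):
            BiasDistributionSpec("uniform", 0.5, domain=(-0.1, 1.0))
        with pytest.raises(SpecError):
            BiasDistributionSpec("point", 0.9, domain=(0.0, 0.5))


class TestBuildRules:
    @pytest.mark.parametrize("bias,value", [(1.0, 1), (0.0, 0)])
    def test_degenerate_bias(self, bias, value, rng):
        topo = build_regular_topology(10, 2, rng)
        rules = build_rules(topo, [bias] * 10, rng)
        assert all((t == value).all() for t in rules.tables)

    def test_table_sizes_match_in_degree(self, rng):
        topo = wire_from_out_degrees(rng.integers(0, 6, size=20), rng)
        rules = build_rules(topo, [0.5] * 20, rng)
        for a, t in enumerate(rules.tables):
            assert t.size == 2 ** len(topo.in_neighbors[a])

    def test_pooled_fraction_of_ones(self, rng):
        topo = build_regular_topology(50, 4, rng)
        rules = build_rules(topo, [0.7] * 50, rng)
        pooled = np.concatenate(rules.tables)
        se = np.sqrt(0.7 * 0.3 / pooled.size)
        assert abs(pooled.mean() - 0.7) < 3 * se


class TestBuildRbnAndSerialization:
    def test_same_seed_identical_serialized_models(self):
        spec_s = DegreeDistributionSpec("poisson", 3.0)
        spec_f = BiasDistributionSpec("triangular", 0.5)
        docs = [
            model_to_json(
                build_rbn(40, spec_s, spec_f, np.random.default_rng(7), seed=7)
            )
            for _ in range(2)
        ]
        assert docs[0] == docs[1]

    def test_homogeneous_case_mean_in_degree(self, rng):
        model = build_rbn(
            100,
            DegreeDistributionSpec("poisson", 5.0),
            BiasDistributionSpec("point", 0.5),
            rng,
        )
        assert abs(model.topology.in_degree.mean() - 5.0) < 1.0

    def test_heterogeneous_case_biases_distinct(self, rng):
        model = build_rbn(
            100,
            DegreeDistributionSpec("exponential", 5.0),
            BiasDistributionSpec("triangular", 0.5),
            rng,
        )
        assert len(np.unique(model.rules.bias)) == 100

    def test_json_round_trip_lossless(self, rng):
        model = build_rbn(
            25,
            DegreeDistributionSpec("exponential", 3.0),
            BiasDistributionSpec("uniform", 0.5),
            rng,
            seed=0,
        )
        clone = model_from_json(model_to_json(model))
        assert model_to_json(clone) == model_to_json(model)
        for a in range(25):
            assert np.array_equal(clone.rules.tables[a], model.rules.tables[a])
            assert np.array_equal(
                clone.topology.in_neighbors[a], model.topology.in_neighbors[a]
            )

    def test_meta_records_config(self, rng):
        model = build_rbn(
            10,
            DegreeDistributionSpec("poisson", 2.0),
            BiasDistributionSpec("point", 0.5),
            rng,
            seed=99,
        )
        doc = json.loads(model_to_json(model))
        assert doc["meta"]["seed"] == 99
        assert doc["meta"]["structural"]["kind"] == "poisson"


@given(st.lists(st.integers(min_value=0, max_value=10), min_size=1, max_size=40),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_edge_conservation_property(degs, seed):
    """Sum of in-degrees always equals the sum of realized out-degrees."""
    topo = wire_from_out_degrees(degs, np.random.default_rng(seed))
    assert topo.in_degree.sum() == topo.out_degree.sum()
    assert (topo.out_degree <= np.minimum(degs, len(degs))).all()
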