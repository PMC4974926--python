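import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from beesem.causal_engine import (CausalModel, basis_set, dsep_test, fisher_c,
                                  implied_covariance, model_aic,
                                  partial_correlation,
                                  partial_correlation_from_cov,
                                  path_coefficients, prune_model, rank_models,
                                  support_class, PathEstimate)
from beesem.errors import (DegenerateInputError, DomainError,
                           InsufficientDataError, ModelError)
from beesem.models import simplified_model
from _oracles import d_separated, partial_corr_by_precision

import networkx as nx


def model_from_edges(edges, n_nodes, name="m"):
    nodes = tuple(f"V{i}" for i in range(n_nodes))
    return CausalModel(name=name, variables=nodes,
                       edges=tuple((f"V{i}", f"V{j}") for i, j in edges))


class TestCausalModel:
    def test_cycle_rejected(self):
        with pytest.raises(ModelError, match="cyclic"):
            CausalModel("c", ("A", "B"), (("A", "B"), ("B", "A")))

    def test_self_loop_rejected(self):
        with pytest.raises(ModelError, match="self-loop"):
            CausalModel("c", ("A",), (("A", "A"),))

    def test_dangling_edge_rejected(self):
        with pytest.raises(ModelError, match="outside"):
            CausalModel("c", ("A",), (("A", "B"),))


class TestBasisSet:
    def test_three_node_chain_has_single_claim(self):
        chain = CausalModel("chain", ("A", "B", "C"), (("A", "B"), ("B", "C")))
        claims = basis_set(chain)
        assert [(c.x, c.y, c.z) for c in claims] == [("A", "C", ("B",))]

    def test_complete_dag_has_empty_basis_set(self):
        full = CausalModel("full", ("A", "B", "C"),
                           (("A", "B"), ("A", "C"), ("B", "C")))
        assert basis_set(full) == []

    def test_simplified_study_model_has_one_claim_with_two_df(self):
        m = simplified_model("total_cells")
        claims = basis_set(m)
        assert len(claims) == 1
        c = claims[0]
        assert {c.x, c.y} == {"elevation", "stability"}
        assert c.z == ("flower_richness",)

    def test_claim_override_replaces_derived_conditioning_set(self):
        chain = CausalModel("chain", ("A", "B", "C"), (("A", "B"), ("B", "C")),
                            claim_overrides={("A", "C"): ("B", "A")})
        # override is taken verbatim (sorted), not derived
        assert basis_set(chain)[0].z == ("A", "B")

    def test_every_claim_is_d_separated_all_dags_up_to_four_nodes(self):
        # exhaustive over topologically-ordered representatives
        from _oracles import all_dags_upper_triangular
        for n_nodes in (2, 3, 4):
            nodes = [f"V{i}" for i in range(n_nodes)]
            for edges in all_dags_upper_triangular(n_nodes):
                model = model_from_edges(edges, n_nodes)
                named = [(f"V{i}", f"V{j}") for i, j in edges]
                for c in basis_set(model):
                    assert d_separated(named, c.x, c.y, c.z, nodes)
                    g = model.graph()
                    assert nx.is_d_separator(g, {c.x}, {c.y}, set(c.z))


class TestPartialCorrelation:
    def test_empty_conditioning_set_is_pearson(self, rng):
        x = rng.normal(size=40)
        y = x * 0.3 + rng.normal(size=40)
        r, p, n = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)
        assert n == 40

    def test_duplicate_vector_has_unit_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, _ = partial_correlation(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-12

    def test_worked_example_matches_residual_regression(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        z = np.array([0.0, 0.0, 1.0, 1.0])
        # residualize by hand on [1, z]
        def resid(v):
            design = np.column_stack([np.ones(4), z])
            beta = np.linalg.solve(design.T @ design, design.T @ v)
            return v - design @ beta
        rx, ry = resid(x), resid(y)
        expected = rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))
        r, _, _ = partial_correlation(x, y, [z])
        assert r == pytest.approx(expected, abs=1e-12)

    def test_matches_precision_matrix_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(8, 40))
            k = int(rng.integers(0, 4))
            data = rng.normal(size=(n, k + 2))
            zs = [data[:, 2 + j] for j in range(k)]
            r, _, _ = partial_correlation(data[:, 0], data[:, 1], zs)
            assert r == pytest.approx(
                partial_corr_by_precision(data[:, 0], data[:, 1], zs), abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        frame = pd.DataFrame(rng.normal(size=(30, 4)),
                             columns=["x", "y", "z1", "z2"])
        out = pingouin.partial_corr(frame, x="x", y="y", covar=["z1", "z2"])
        r, p, _ = partial_correlation(frame["x"], frame["y"],
                                      [frame["z1"], frame["z2"]])
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), rel=1e-6)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5),
           c=st.floats(0.1, 10), d=st.floats(-5, 5))
    def test_symmetry_and_affine_invariance(self, a, b, c, d):
        rng = np.random.default_rng(99)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        z = rng.normal(size=25)
        r_xy, p_xy, _ = partial_correlation(x, y, [z])
        r_yx, p_yx, _ = partial_correlation(y, x, [z])
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        r_t, _, _ = partial_correlation(a * x + b, c * y + d, [a * z + d])
        assert r_t == pytest.approx(r_xy, abs=1e-9)

    def test_insufficient_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            partial_correlation([1.0, 2.0], [2.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            partial_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestFisherC:
    def test_all_ones_give_zero(self):
        assert fisher_c([1.0, 1.0, 1.0]) == 0.0

    def test_single_exp_minus_one_gives_two(self):
        assert fisher_c([math.exp(-1)]) == pytest.approx(2.0)

    def test_two_halves(self):
        assert fisher_c([0.5, 0.5]) == pytest.approx(2.7726, abs=1e-4)

    @given(ps=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
           qs=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6))
    def test_additive_over_disjoint_claim_sets(self, ps, qs):
        assert fisher_c(ps + qs) == pytest.approx(fisher_c(ps) + fisher_c(qs),
                                                  rel=1e-9, abs=1e-9)

    def test_monotone_decreasing_in_each_p(self):
        base = [0.5, 0.3]
        assert fisher_c([0.4, 0.3]) > fisher_c(base) > fisher_c([0.5, 0.4])

    def test_zero_p_is_infinite_with_warning(self):
        with pytest.warns(UserWarning, match="rejected"):
            assert fisher_c([0.0, 0.5]) == math.inf

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            fisher_c([1.5])


class TestDsepTest:
    def test_saturated_model_convention(self, small_sites_frame):
        full = CausalModel("sat", ("elevation", "flower_richness"),
                           (("elevation", "flower_richness"),))
        res = dsep_test(full, small_sites_frame)
        assert (res.C, res.k, res.df, res.p_value) == (0.0, 0, 0, 1.0)
        assert res.saturated

    def test_fields_consistent_with_claims(self, small_sites_frame):
        m = simplified_model("total_cells")
        res = dsep_test(m, small_sites_frame)
        assert res.k == len(res.claims) == 1
        assert res.df == 2
        assert res.C == pytest.approx(-2 * math.log(res.claims[0].p_value))
        assert res.p_value == pytest.approx(
            float(stats.chi2.sf(res.C, 2)))

    def test_missing_variable_rejected(self, small_sites_frame):
        m = simplified_model("nonexistent_response")
        with pytest.raises(DomainError, match="nonexistent_response"):
            dsep_test(m, small_sites_frame)


class TestModelAic:
    def test_formula_values(self):
        from beesem.causal_engine import DSepResult
        res = DSepResult(model="m", C=10.0, k=2, df=4, p_value=0.04, claims=())
        assert model_aic(res, K=3, n=14, formula="shipley").AIC == 16.0
        assert model_aic(res, K=3, n=14, formula="shipley_corrected").AIC == \
            pytest.approx(10 + 6 * 14 / 10)
        assert model_aic(res, K=3, n=14, formula="as_printed").AIC == \
            pytest.approx(2 * math.log(10) + 6)

    def test_printed_formula_undefined_for_nonpositive_C(self):
        from beesem.causal_engine import DSepResult
        res = DSepResult(model="m", C=0.0, k=0, df=0, p_value=1.0, claims=())
        with pytest.raises(DomainError):
            model_aic(res, K=2, n=14, formula="as_printed")

    @pytest.mark.parametrize("delta,expected", [
        (2.9, "substantial"), (8.0, "less"), (11.0, "none")])
    def test_support_classes(self, delta, expected):
        assert support_class(delta) == expected

    def test_identical_models_share_zero_delta(self):
        from beesem.causal_engine import DSepResult
        res = DSepResult(model="a", C=5.0, k=1, df=2, p_value=0.3, claims=())
        s1 = model_aic(res, K=2, n=14)
        s2 = model_aic(
            DSepResult(model="b", C=5.0, k=1, df=2, p_value=0.3, claims=()),
            K=2, n=14)
        ranked = rank_models([s1, s2])
        assert all(s.delta_AIC == 0.0 for s in ranked)
        assert [s.model for s in ranked] == ["a", "b"]  # name tie-break


class TestPathCoefficients:
    def test_sole_parent_edge_reduces_to_pearson(self, small_sites_frame):
        m = CausalModel("m", ("elevation", "flower_richness"),
                        (("elevation", "flower_richness"),))
        est = path_coefficients(m, small_sites_frame)[0]
        r_ref, _ = stats.pearsonr(small_sites_frame["elevation"],
                                  small_sites_frame["flower_richness"])
        assert est.coefficient == pytest.approx(r_ref, abs=1e-12)

    def test_coparents_enter_the_conditioning_set(self, small_sites_frame):
        m = simplified_model("total_cells")
        ests = {e.edge: e for e in path_coefficients(m, small_sites_frame)}
        r, _, _ = partial_correlation(
            small_sites_frame["stability"], small_sites_frame["total_cells"],
            [small_sites_frame["elevation"], small_sites_frame["flower_richness"]])
        assert ests[("stability", "total_cells")].coefficient == pytest.approx(r)


class TestPruneModel:
    def _estimates(self, model, pvals):
        return [PathEstimate(edge=e, coefficient=0.5, p_value=p, n=14)
                for e, p in zip(model.edges, pvals)]

    def test_all_significant_edges_keep_model_unchanged(self):
        m = simplified_model("total_cells")
        pruned = prune_model(m, self._estimates(m, [0.01] * len(m.edges)))
        assert pruned.edges == m.edges

    def test_keep_list_protects_non_significant_edges(self):
        m = simplified_model("total_cells")
        pvals = [0.9 if e in m.keep_edges else 0.01 for e in m.edges]
        pruned = prune_model(m, self._estimates(m, pvals))
        assert set(m.keep_edges) <= set(pruned.edges)

    def test_pruning_to_empty_model_warns(self):
        m = CausalModel("m", ("A", "B"), (("A", "B"),))
        with pytest.warns(UserWarning, match="every edge"):
            prune_model(m, self._estimates(m, [0.99]))

    def test_removing_an_edge_never_shrinks_the_basis_set(self, rng):
        # random 5-node DAGs: dropping one edge adds >= 0 claims
        for _ in range(60):
            n_nodes = 5
            edges = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)
                     if rng.random() < 0.4]
            if not edges:
                continue
            model = model_from_edges(edges, n_nodes)
            smaller = model_from_edges(edges[1:], n_nodes)
            assert len(basis_set(smaller)) >= len(basis_set(model))


class TestImpliedCovariance:
    def test_chain_correlation_is_product_of_coefficients(self):
        chain = CausalModel("chain", ("A", "B", "C"), (("A", "B"), ("B", "C")))
        sigma = implied_covariance(
            chain, {("A", "B"): 0.5, ("B", "C"): 0.4},
            {"A": 1.0, "B": 1 - 0.25, "C": 1 - 0.16})
        assert sigma.loc["A", "C"] == pytest.approx(0.2)
        assert np.allclose(np.diag(sigma), 1.0)
        # conditioning on the mediator annihilates the correlation
        assert partial_correlation_from_cov(sigma, "A", "C", ("B",)) == \
            pytest.approx(0.0, abs=1e-12)
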