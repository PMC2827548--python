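"""Differential evolution, vertex rounding, exhaustive oracle, full pipeline."""

import numpy as np
import pytest

from gkonp.dds_model import objective_exact
from gkonp.optimize import (
    CapExceededError,
    DEConfig,
    differential_evolution,
    exhaustive_search,
    gkonp,
    round_to_vertex,
)
from gkonp.path_engine import (
    MultilinearObjective,
    PathTerm,
    enumerate_terms_exact,
    evaluate,
    fdp,
    negative_gene_set,
)

from conftest import small_random_models


def _toy_objective():
    # f(s) = s0 + s1 - 3 s0 s1; best vertex value 1 at (1,0) or (0,1)
    return MultilinearObjective(2, 0, [
        PathTerm(1.0, frozenset({0})),
        PathTerm(1.0, frozenset({1})),
        PathTerm(-3.0, frozenset({0, 1})),
    ])


class TestDifferentialEvolution:
    @pytest.mark.parametrize("coef, optimum", [(1.0, 1.0), (-1.0, 0.0)])
    def test_monotone_single_variable_converges(self, coef, optimum):
        obj = MultilinearObjective(2, 1, [PathTerm(coef, frozenset({0}))])
        s, _ = differential_evolution(obj, [0], DEConfig(seed=1, max_generations=100))
        assert s[0] == pytest.approx(optimum, abs=1e-3)
        assert s[1] == 1.0  # non-decision coordinate held intact

    def test_finds_the_best_vertex_region(self):
        obj = _toy_objective()
        s, diag = differential_evolution(obj, [0, 1], DEConfig(seed=3))
        assert evaluate(obj, s) == pytest.approx(1.0, abs=1e-6)
        assert diag["generations"] >= 1

    def test_empty_decision_set_returns_baseline(self):
        obj = _toy_objective()
        s, diag = differential_evolution(obj, [], DEConfig(seed=0))
        np.testing.assert_array_equal(s, np.ones(2))
        assert diag["generations"] == 0

    def test_deterministic_under_fixed_seed(self):
        obj = _toy_objective()
        s1, _ = differential_evolution(obj, [0, 1], DEConfig(seed=11))
        s2, _ = differential_evolution(obj, [0, 1], DEConfig(seed=11))
        np.testing.assert_array_equal(s1, s2)


class TestRoundToVertex:
    def test_coordinatewise_optimal_vertex_is_a_fixed_point(self):
        obj = _toy_objective()
        s = np.array([0.0, 1.0])
        np.testing.assert_array_equal(round_to_vertex(obj, s, [0, 1]), s)

    def test_hand_slope_example(self):
        obj = _toy_objective()
        out = round_to_vertex(obj, np.array([0.5, 0.5]), [0, 1])
        np.testing.assert_array_equal(out, [0.0, 1.0])
        assert evaluate(obj, out) == pytest.approx(1.0)

    def test_zero_slope_keeps_the_gene(self):
        obj = MultilinearObjective(2, 1, [PathTerm(2.0, frozenset({1}))])
        out = round_to_vertex(obj, np.array([0.3, 1.0]), [0])
        assert out[0] == 1.0

    def test_never_decreases_the_objective(self):
        rng = np.random.default_rng(7)
        for model in small_random_models(n_genes=8, n_models=5, seed=101):
            obj = enumerate_terms_exact(model)
            decision = sorted(set(range(8)) - {model.target})
            for _ in range(20):
                s = rng.random(8)
                s[model.target] = 1.0
                v = round_to_vertex(obj, s, decision)
                assert np.isin(v, (0.0, 1.0)).all()
                assert evaluate(obj, v) >= evaluate(obj, s) - 1e-12

    def test_fractional_maximum_never_beats_best_vertex(self):
        """The multilinear objective is affine per coordinate, so its maximum
        over the hypercube is attained at a vertex."""
        rng = np.random.default_rng(13)
        for model in small_random_models(n_genes=8, n_models=5, seed=113):
            obj = enumerate_terms_exact(model)
            decision = sorted(set(range(8)) - {model.target})
            best_vertex = exhaustive_search(model).objective
            S = rng.random((2000, 8))
            S[:, model.target] = 1.0
            from gkonp.path_engine import evaluate_batch
            assert evaluate_batch(obj, S).max() <= best_vertex + 1e-9


class TestExhaustiveSearch:
    def test_empty_candidate_set_is_the_baseline(self, two_gene_inhibitor):
        res = exhaustive_search(two_gene_inhibitor, candidate_genes=[])
        assert res.knockout == [] and res.objective == 0.0

    def test_two_gene_inhibitor(self, two_gene_inhibitor):
        res = exhaustive_search(two_gene_inhibitor)
        assert res.knockout == ["G1"] and res.objective == 1.0

    def test_nonnegative_model_keeps_everything(self, toys):
        model = toys["all_positive_chain"]["model"]
        res = exhaustive_search(model)
        assert res.knockout == []
        assert res.objective == toys["all_positive_chain"]["optimal_value"]

    def test_cap_enforced(self, two_gene_inhibitor):
        with pytest.raises(CapExceededError):
            exhaustive_search(two_gene_inhibitor, cap=1)

    def test_target_cannot_be_candidate(self, two_gene_inhibitor):
        with pytest.raises(ValueError):
            exhaustive_search(two_gene_inhibitor, candidate_genes=[1])

    def test_restriction_to_negative_genes_is_lossless(self):
        """Searching only over genes on negative paths reaches the same
        optimum as the unrestricted search."""
        for model in small_random_models(n_genes=9, n_models=8, seed=131):
            gneg = sorted(negative_gene_set(enumerate_terms_exact(model)))
            full = exhaustive_search(model)
            restricted = exhaustive_search(model, candidate_genes=gneg)
            assert restricted.objective == pytest.approx(full.objective, rel=1e-12, abs=1e-12)


class TestGkonpPipeline:
    def test_matches_oracle_on_toys(self, toys):
        for name, fx in toys.items():
            res = gkonp(fx["model"], epsilon=0.0, config=DEConfig(seed=2))
            assert res.objective == pytest.approx(fx["optimal_value"], rel=1e-12), name
            assert res.knockout == fx["optimal_knockout"], name

    def test_empty_negative_set_short_circuits(self, toys):
        model = toys["all_positive_chain"]["model"]
        res = gkonp(model, epsilon=1e-3)
        assert res.knockout == [] and res.candidates == []
        assert res.diagnostics["restarts"] == 0

    def test_reports_both_exact_and_surrogate_values(self, two_gene_inhibitor):
        res = gkonp(two_gene_inhibitor, epsilon=0.0, config=DEConfig(seed=4))
        assert res.objective == pytest.approx(objective_exact(two_gene_inhibitor, res.s))
        assert res.objective_approx == pytest.approx(res.objective)  # exact surrogate

    def test_never_beats_and_usually_matches_exhaustive(self):
        for model in small_random_models(n_genes=9, n_models=5, seed=139):
            res = gkonp(model, epsilon=1e-3, config=DEConfig(seed=8))
            opt = exhaustive_search(model)
            assert res.objective <= opt.objective + 1e-9
            assert res.objective == pytest.approx(opt.objective, rel=1e-9)

    def test_deterministic_under_fixed_seed(self):
        model = small_random_models(n_genes=10, n_models=1, seed=149)[0]
        r1 = gkonp(model, epsilon=1e-3, config=DEConfig(seed=42))
        r2 = gkonp(model, epsilon=1e-3, config=DEConfig(seed=42))
        assert r1.knockout == r2.knockout
        assert r1.objective == r2.objective
        np.testing.assert_array_equal(r1.s, r2.s)

    def test_independent_optimizer_reaches_the_same_relaxed_optimum(self):
        """Cross-check with scipy's differential evolution as an independent
        optimizer of the hypercube relaxation: both searches must reach the
        same (vertex-attained) optimum."""
        from scipy.optimize import differential_evolution as scipy_de
        model = small_random_models(n_genes=7, n_models=1, seed=163)[0]
        obj = enumerate_terms_exact(model)
        decision = sorted(int(i) for i in negative_gene_set(obj))
        assert decision  # the instance has negative paths to act on

        def neg_relaxed(x):
            s = np.ones(model.n)
            s[decision] = x
            return -evaluate(obj, s)

        ref = scipy_de(neg_relaxed, [(0.0, 1.0)] * len(decision), seed=1,
                       tol=1e-12, maxiter=500)
        ours = gkonp(model, epsilon=0.0, config=DEConfig(seed=5))
        assert ours.objective == pytest.approx(-ref.fun, abs=1e-6)

    def test_knockout_is_within_candidate_set(self):
        for model in small_random_models(n_genes=10, n_models=3, seed=151):
            res = gkonp(model, epsilon=1e-3, config=DEConfig(seed=6))
            assert set(res.knockout) <= set(res.candidates)
            assert model.target_name not in res.knockout
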