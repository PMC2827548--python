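"""Seeded benchmark studies: the package's self-validation battery.

Each study regenerates its inputs from a seed, runs the relevant pipeline
pieces, and returns summary statistics.  The studies mirror the simulation
protocol used to benchmark the heuristic against the exhaustive oracle
(random sparse models, unit initial concentrations, first gene as target)
plus the structural properties the method rests on: exactness of the path
algebra, vertex optimality of the relaxation, soundness of the
negative-path restriction, and the vertex-cover equivalence.
"""

from __future__ import annotations

import itertools

import numpy as np

from .dds_model import objective_exact, objective_exact_many
from .optimize import DEConfig, exhaustive_search, gkonp, round_to_vertex
from .path_engine import (
    enumerate_terms_exact,
    evaluate,
    evaluate_batch,
    fdp,
    negative_gene_set,
)
from .synthetic_data import EnsembleSpec, random_sparse_dds
from .vc_reduction import VCInstance, verify_equivalence

__all__ = [
    "oracle_equivalence_study",
    "agreement_study",
    "vc_equivalence_study",
    "vertex_optimality_study",
    "restriction_study",
    "fdp_study",
]


def oracle_equivalence_study(
    seed: int,
    n_models: int = 50,
    n_genes: int = 10,
    horizon: int = 8,
    knockouts_per_model: int = 200,
) -> dict:
    """Exactness of the path algebra against the matrix-power objective.

    For each random sparse model, evaluates the exact multilinear polynomial
    (full enumeration, and the filtered builder at prune coefficient 0) on
    random binary knockouts and compares with the matrix-power objective.
    Returns the largest relative deviation observed.
    """
    spec = EnsembleSpec(n_genes=n_genes, horizon=horizon, seed=seed, n_models=n_models)
    rng = np.random.default_rng(seed + 1)
    max_rel = 0.0
    checks = 0
    for model in random_sparse_dds(spec):
        obj_enum = enumerate_terms_exact(model)
        obj_fdp0 = fdp(model, 0.0)
        S = (rng.random((knockouts_per_model, model.n)) < 0.5).astype(float)
        S[:, model.target] = 1.0
        exact = objective_exact_many(model, S)
        scale = np.maximum(np.abs(exact), 1e-12)
        for obj in (obj_enum, obj_fdp0):
            rel = np.abs(evaluate_batch(obj, S) - exact) / scale
            max_rel = max(max_rel, float(rel.max()))
        checks += knockouts_per_model
    return {"max_rel_error": max_rel, "n_checks": checks, "n_models": n_models}


def agreement_study(
    seed: int,
    sizes: tuple = ((10, 3), (20, 3)),
    epsilon: float = 1e-3,
    config: DEConfig | None = None,
    restrict_exhaustive_from: int = 16,
) -> dict:
    """Heuristic vs. exhaustive optimum on random sparse models.

    Runs the full pipeline (prune coefficient ``epsilon``, default
    evolutionary settings, 3 restarts) and the brute-force reference on
    ``n_models`` random models per size.  For larger models the reference is
    restricted to the negative-path gene set, which is lossless.  Returns
    the number of models on which the heuristic attains the optimum exactly
    (up to 1e-9 relative).
    """
    agree = 0
    total = 0
    values = []
    for n_genes, n_models in sizes:
        spec = EnsembleSpec(n_genes=n_genes, seed=seed + n_genes, n_models=n_models)
        for model in random_sparse_dds(spec):
            cfg = config or DEConfig(seed=seed + total)
            res = gkonp(model, epsilon=epsilon, config=cfg)
            if n_genes >= restrict_exhaustive_from:
                cand = sorted(negative_gene_set(fdp(model, 0.0)))
            else:
                cand = None
            ref = exhaustive_search(model, candidate_genes=cand)
            tol = 1e-9 * max(1.0, abs(ref.objective))
            agree += abs(res.objective - ref.objective) <= tol
            total += 1
            values.append({
                "n_genes": n_genes,
                "optimal": ref.objective,
                "heuristic": res.objective,
                "knockout": res.knockout,
            })
    return {"n_agree": agree, "n_models": total, "results": values}


def vc_equivalence_study(max_vertices: int = 5) -> dict:
    """Double-oracle reduction check over every labeled graph on up to
    ``max_vertices`` vertices (including the closed-form optimum value)."""
    n_graphs = 0
    n_passed = 0
    for n in range(1, max_vertices + 1):
        pairs = list(itertools.combinations(range(n), 2))
        for bits in range(2 ** len(pairs)):
            edges = [pairs[i] for i in range(len(pairs)) if bits >> i & 1]
            report = verify_equivalence(VCInstance.from_edges(n, edges))
            n_graphs += 1
            n_passed += report["passed"]
    return {"n_graphs": n_graphs, "n_passed": n_passed}


def vertex_optimality_study(
    seed: int,
    n_models: int = 50,
    n_genes: int = 8,
    n_points: int = 10_000,
) -> dict:
    """Vertex optimality of the hypercube relaxation.

    Samples random fractional points and checks that none beats the best
    vertex (found exhaustively), and that coordinate-wise rounding never
    decreases the relaxed objective.  Returns the worst violations (both
    should be <= 0 up to numerical noise).
    """
    spec = EnsembleSpec(n_genes=n_genes, seed=seed, n_models=n_models)
    rng = np.random.default_rng(seed + 1)
    worst_excess = -np.inf
    worst_rounding_loss = -np.inf
    for model in random_sparse_dds(spec):
        obj = enumerate_terms_exact(model)
        decision = sorted(set(range(model.n)) - {model.target})
        best_vertex = exhaustive_search(model).objective
        S = rng.random((n_points, model.n))
        S[:, model.target] = 1.0
        frac_vals = evaluate_batch(obj, S)
        worst_excess = max(worst_excess, float(frac_vals.max() - best_vertex))
        k = int(np.argmax(frac_vals))
        v = round_to_vertex(obj, S[k], decision)
        worst_rounding_loss = max(
            worst_rounding_loss, float(frac_vals[k] - evaluate(obj, v))
        )
    return {
        "max_fractional_excess": worst_excess,
        "max_rounding_loss": worst_rounding_loss,
        "n_models": n_models,
        "n_points": n_points,
    }


def restriction_study(seed: int, n_models: int = 50, n_genes: int = 10) -> dict:
    """Negative-path restriction soundness.

    Compares exhaustive search restricted to the negative-path gene set with
    the unrestricted exhaustive search; the optima must coincide.
    """
    spec = EnsembleSpec(n_genes=n_genes, seed=seed, n_models=n_models)
    agree = 0
    for model in random_sparse_dds(spec):
        gneg = sorted(negative_gene_set(enumerate_terms_exact(model)))
        full = exhaustive_search(model)
        restricted = exhaustive_search(model, candidate_genes=gneg)
        tol = 1e-9 * max(1.0, abs(full.objective))
        agree += abs(full.objective - restricted.objective) <= tol
    return {"n_agree": agree, "n_models": n_models}


def fdp_study(
    seed: int,
    n_models: int = 20,
    n_genes: int = 15,
    epsilon: float = 1e-3,
) -> dict:
    """Behaviour of the filtering pass at the study's prune coefficient.

    For each model, compares the pruned polynomial with the exact objective
    at the all-intact point and the surviving path-term counts with and
    without pruning.  Reports the exact-at-zero check, the median relative
    error at ``epsilon``, and whether every model in which suffixes were
    discarded ended with strictly fewer path terms.
    """
    spec = EnsembleSpec(n_genes=n_genes, seed=seed, n_models=n_models)
    errors = []
    max_err_at_zero = 0.0
    strict_when_pruned = True
    n_pruned = 0
    for model in random_sparse_dds(spec):
        exact = objective_exact(model)
        scale = max(abs(exact), 1e-12)
        obj0 = fdp(model, 0.0)
        obj_eps = fdp(model, epsilon)
        # at prune coefficient 0 the filtered builder is the exact
        # enumeration, term for term, so this difference is exactly zero
        ones = np.ones(model.n)
        max_err_at_zero = max(
            max_err_at_zero,
            abs(evaluate(obj0, ones) - evaluate(enumerate_terms_exact(model), ones)),
        )
        errors.append(abs(evaluate(obj_eps, np.ones(model.n)) - exact) / scale)
        if obj_eps.meta["suffixes_pruned"] > 0:
            n_pruned += 1
            strict_when_pruned &= (
                obj_eps.meta["n_path_terms"] < obj0.meta["n_path_terms"]
            )
    return {
        "max_rel_error_at_zero": max_err_at_zero,
        "median_rel_error": float(np.median(errors)),
        "n_models_pruned": n_pruned,
        "strict_term_reduction_when_pruned": strict_when_pruned,
        "n_models": n_models,
    }
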