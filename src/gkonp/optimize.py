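"""Knockout optimization: differential evolution on the hypercube relaxation,
vertex rounding, an exhaustive oracle, and the full heuristic pipeline.

The multilinear objective is affine in each knockout variable, so it attains
its maximum over ``[0, 1]^d`` at a vertex of the hypercube; the pipeline
therefore searches the continuous relaxation with differential evolution
(rand/1/bin), rounds the best fractional point coordinate-wise to a vertex
without ever decreasing the objective, and re-validates the resulting binary
knockout against the exact matrix-power objective — the pruned polynomial is
only a search surrogate and never the reported value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dds_model import DDSModel, KnockoutVector, objective_exact, objective_exact_many
from .path_engine import (
    MultilinearObjective,
    evaluate,
    evaluate_batch,
    fdp,
    negative_gene_set,
    restrict,
)

__all__ = [
    "DEConfig",
    "OptimizationResult",
    "CapExceededError",
    "differential_evolution",
    "round_to_vertex",
    "exhaustive_search",
    "gkonp",
]


class CapExceededError(RuntimeError):
    """Exhaustive enumeration refused: too many candidate subsets."""


@dataclass
class DEConfig:
    """Differential-evolution settings.

    The population holds ``population_mult`` times the number of decision
    variables (kept within the usual 2–50x guidance), at least 4 so a trial
    vector can combine three distinct donors with the current individual.
    Search stops after ``max_generations`` or once the best value improves by
    less than ``stall_tol`` over ``stall_generations`` consecutive
    generations.  Restarts rerun the whole search from independent
    populations; the best exactly-validated result wins.
    """

    population_mult: int = 10
    population_size: int | None = None  # explicit override
    weight_factor: float = 0.8  # donor difference scaling, in (0, 2]
    crossover_prob: float = 0.9
    max_generations: int = 300
    stall_tol: float = 1e-8
    stall_generations: int = 50
    restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.weight_factor <= 2:
            raise ValueError("weight_factor must be in (0, 2]")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.max_generations < 1 or self.restarts < 1:
            raise ValueError("max_generations and restarts must be >= 1")

    def resolve_population(self, d: int) -> int:
        if self.population_size is not None:
            return max(4, self.population_size)
        return max(4, self.population_mult * d)


@dataclass
class OptimizationResult:
    """Outcome of a knockout search.

    ``objective`` is always the exact matrix-power value of the returned
    binary knockout; ``objective_approx`` is the surrogate polynomial's value
    at the same point (None when no surrogate was involved).
    """

    knockout: list[str]
    s: np.ndarray
    objective: float
    objective_approx: float | None
    candidates: list[str]
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "knockout": self.knockout,
            "objective": self.objective,
            "objective_approx": self.objective_approx,
            "candidates": self.candidates,
            **{k: v for k, v in self.diagnostics.items()},
        }


def _pick_distinct_donors(pop_size: int, rng: np.random.Generator) -> np.ndarray:
    """For each individual, three distinct donor indices, all != the individual."""
    idx = np.arange(pop_size)
    donors = rng.integers(0, pop_size, size=(pop_size, 3))
    while True:
        bad = (
            (donors[:, 0] == donors[:, 1])
            | (donors[:, 0] == donors[:, 2])
            | (donors[:, 1] == donors[:, 2])
            | (donors == idx[:, None]).any(axis=1)
        )
        if not bad.any():
            return donors
        donors[bad] = rng.integers(0, pop_size, size=(int(bad.sum()), 3))


def differential_evolution(
    obj: MultilinearObjective,
    decision_genes: list[int],
    config: DEConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Maximize the relaxed objective over ``[0, 1]^d`` with rand/1/bin DE.

    Only the listed decision genes vary; every other coordinate is held at 1.
    Each trial vector combines three distinct donor individuals
    (``donor1 + F * (donor2 - donor3)``, clipped to the box — on a box,
    clipping an infeasible trial is equivalent to rejecting it without
    wasting the evaluation), crosses over coordinate-wise with probability
    ``crossover_prob`` (one coordinate forced from the trial), and replaces
    the current individual only when it improves the objective.

    Returns the best full-length fractional vector found and a diagnostics
    dict; deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    decision = sorted(decision_genes)
    d = len(decision)
    base = np.ones(obj.n)
    if d == 0:
        return base, {"generations": 0, "evaluations": 0}

    sub = restrict(obj, decision)
    cols = np.array(decision, dtype=int)

    def batch_value(P: np.ndarray) -> np.ndarray:
        S = np.ones((P.shape[0], obj.n))
        S[:, cols] = P
        return evaluate_batch(sub, S)

    pop_size = config.resolve_population(d)
    pop = rng.random((pop_size, d))
    vals = batch_value(pop)
    evaluations = pop_size

    best_window = vals.max()
    stall = 0
    gen = 0
    for gen in range(1, config.max_generations + 1):
        donors = _pick_distinct_donors(pop_size, rng)
        trial = pop[donors[:, 0]] + config.weight_factor * (
            pop[donors[:, 1]] - pop[donors[:, 2]]
        )
        np.clip(trial, 0.0, 1.0, out=trial)
        cross = rng.random((pop_size, d)) < config.crossover_prob
        forced = rng.integers(0, d, size=pop_size)
        cross[np.arange(pop_size), forced] = True
        trial = np.where(cross, trial, pop)
        trial_vals = batch_value(trial)
        evaluations += pop_size
        improved = trial_vals > vals
        pop[improved] = trial[improved]
        vals[improved] = trial_vals[improved]

        best = vals.max()
        if best - best_window < config.stall_tol:
            stall += 1
            if stall >= config.stall_generations:
                break
        else:
            stall = 0
            best_window = best

    out = base.copy()
    out[cols] = pop[int(np.argmax(vals))]
    return out, {"generations": gen, "evaluations": evaluations}


def round_to_vertex(
    obj: MultilinearObjective,
    s_frac: np.ndarray,
    decision_genes: list[int],
) -> np.ndarray:
    """Round a fractional point to a hypercube vertex, never losing value.

    The objective restricted to one coordinate is affine, ``a * s_i + b``;
    moving ``s_i`` to 1 when the slope ``a`` is positive (or zero — keeping a
    gene is the biologically cheaper choice) and to 0 when negative can only
    increase the value.  Coordinate passes repeat until a full pass changes
    nothing.
    """
    s = np.asarray(s_frac, dtype=float).copy()
    decision = sorted(decision_genes)
    if not decision:
        return s
    sub = restrict(obj, decision)
    coefs = sub._coefs
    members = sub._members
    for _ in range(len(decision) + 1):
        changed = False
        for i in decision:
            rows = members[i]
            if not rows.any():
                new = 1.0
            else:
                prods = np.ones(int(rows.sum()))
                for j in decision:
                    if j == i:
                        continue
                    if s[j] != 1.0:
                        prods[members[j][rows]] *= s[j]
                slope = float(prods @ coefs[rows])
                new = 1.0 if slope >= 0 else 0.0
            if new != s[i]:
                s[i] = new
                changed = True
        if not changed:
            break
    return s


def _subsets_in_preference_order(candidates: list[int]):
    """Subsets by increasing size, lexicographic within a size."""
    for k in range(len(candidates) + 1):
        yield from itertools.combinations(candidates, k)


def exhaustive_search(
    model: DDSModel,
    candidate_genes: "list[int] | None" = None,
    cap: int = 2 ** 24,
    chunk: int = 4096,
) -> OptimizationResult:
    """Brute-force reference: evaluate the exact objective on every subset.

    Enumerates all deletion subsets of ``candidate_genes`` (default: every
    gene except the target), in increasing subset size and lexicographic
    order within a size, so ties resolve toward fewer deletions and then
    lexicographically.  Refuses more than ``cap`` subsets.
    """
    if candidate_genes is None:
        candidates = [i for i in range(model.n) if i != model.target]
    else:
        candidates = sorted(set(int(i) for i in candidate_genes))
        if model.target in candidates:
            raise ValueError("the target gene cannot be a deletion candidate")
        for i in candidates:
            if not 0 <= i < model.n:
                raise ValueError(f"candidate index {i} out of range")
    n_subsets = 2 ** len(candidates)
    if n_subsets > cap:
        raise CapExceededError(
            f"{n_subsets} subsets exceed the cap of {cap}; restrict the candidates"
        )

    best_val = -np.inf
    best_subset: tuple[int, ...] = ()
    it = _subsets_in_preference_order(candidates)
    n_eval = 0
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        S = np.ones((len(block), model.n))
        for r, subset in enumerate(block):
            S[r, list(subset)] = 0.0
        vals = objective_exact_many(model, S)
        n_eval += len(block)
        k = int(np.argmax(vals))
        if vals[k] > best_val:
            best_val = float(vals[k])
            best_subset = block[k]

    s = np.ones(model.n)
    s[list(best_subset)] = 0.0
    return OptimizationResult(
        knockout=[model.gene_names[i] for i in best_subset],
        s=s,
        objective=best_val,
        objective_approx=None,
        candidates=[model.gene_names[i] for i in candidates],
        diagnostics={"subsets_evaluated": n_eval},
    )


def gkonp(
    model: DDSModel,
    epsilon: float = 1e-3,
    config: DEConfig | None = None,
) -> OptimizationResult:
    """Full heuristic pipeline for the knockout problem.

    1. Build the (pruned) multilinear surrogate with prune coefficient
       ``epsilon``.
    2. Restrict the decision variables to the negative-path gene set; if it
       is empty, no deletion can help and the all-intact baseline is
       returned immediately.
    3. Run differential evolution on the ``[0, 1]`` relaxation (with
       restarts from independently seeded populations).
    4. Round the best fractional point to a hypercube vertex.
    5. Re-evaluate every candidate vertex — and the all-intact baseline —
       with the exact matrix-power objective; the best exact value wins,
       ties resolving toward fewer deletions then lexicographic gene order.
    """
    if config is None:
        config = DEConfig()
    obj = fdp(model, epsilon)
    gneg = sorted(negative_gene_set(obj))
    baseline = objective_exact(model, model.all_intact())

    def finish(s, exact, generations, restarts_run):
        deleted = sorted(np.flatnonzero(s == 0.0).tolist())
        return OptimizationResult(
            knockout=[model.gene_names[i] for i in deleted],
            s=s,
            objective=exact,
            objective_approx=evaluate(obj, s),
            candidates=[model.gene_names[i] for i in gneg],
            diagnostics={
                "seed": config.seed,
                "epsilon": epsilon,
                "n_terms": obj.n_terms,
                "generations": generations,
                "restarts": restarts_run,
            },
        )

    if not gneg:
        return finish(np.ones(model.n), baseline, 0, 0)

    best_s = np.ones(model.n)
    best_exact = baseline
    total_gens = 0
    seeds = np.random.SeedSequence(config.seed).spawn(config.restarts)
    for child in seeds:
        rng = np.random.default_rng(child)
        s_frac, diag = differential_evolution(obj, gneg, config, rng=rng)
        s_bin = round_to_vertex(obj, s_frac, gneg)
        exact = objective_exact(model, s_bin)
        total_gens += diag["generations"]
        if exact > best_exact or (
            exact == best_exact
            and _prefer(s_bin, best_s)
        ):
            best_exact = exact
            best_s = s_bin
    return finish(best_s, best_exact, total_gens, config.restarts)


def _prefer(s_new: np.ndarray, s_old: np.ndarray) -> bool:
    """Tie-break: fewer deletions, then lexicographically earlier deletion set."""
    del_new = sorted(np.flatnonzero(s_new == 0.0).tolist())
    del_old = sorted(np.flatnonzero(s_old == 0.0).tolist())
    if len(del_new) != len(del_old):
        return len(del_new) < len(del_old)
    return del_new < del_old
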