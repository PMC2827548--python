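"""Constructive reduction from minimum vertex cover to the knockout problem.

The knockout problem is NP-hard: any vertex-cover instance maps in
polynomial time to a two-step knockout instance whose optimal deletion sets
are exactly the minimum vertex covers.  This module builds that instance
explicitly and ships brute-force oracles for both sides, so the equivalence
is an executable, testable object rather than only a proof.

Construction (graph with ``n`` vertices, target read out at horizon 2):

* one *vertex gene* per graph vertex, one *relay gene* per vertex, the
  target gene, and one inert padding gene (all-zero row and column) that
  keeps the block shape at ``2n + 2``;
* each edge ``{i, j}`` puts a symmetric weight ``+2`` between vertex genes
  ``i`` and ``j``;
* vertex gene ``i`` feeds its relay with weight ``+1``, each relay feeds the
  target with ``+2``, each vertex gene feeds the target directly with
  ``-1``, and the target holds itself with ``+1``;
* the initial state is all ones.

Three path types then reach the target in two steps.  An intact vertex gene
contributes ``+2`` through its relay (type 2) and ``-1`` directly (type 3);
an edge with both endpoints intact contributes two negative paths worth
``-4`` in total (type 1).  With deletion set ``S`` among the vertex genes the
objective is therefore

    3n + 1 - |S| - 4 * (# edges not covered by S),

so every uncovered edge costs more than any extra deletion saves, and the
maximizers are exactly the minimum vertex covers.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dds_model import DDSModel, KnockoutVector, ModelError, objective_exact_many
from .optimize import CapExceededError

__all__ = [
    "VCInstance",
    "ReductionResult",
    "reduce_vertex_cover",
    "phi",
    "brute_force_min_vertex_cover",
    "verify_equivalence",
    "read_graph",
    "write_graph",
]

EDGE_WEIGHT = 2.0
RELAY_IN_WEIGHT = 1.0
RELAY_TO_TARGET = 2.0
VERTEX_TO_TARGET = -1.0
TARGET_SELF_LOOP = 1.0


@dataclass(frozen=True)
class VCInstance:
    """An undirected graph for the vertex-cover problem."""

    n_vertices: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.n_vertices < 0:
            raise ValueError("vertex count must be nonnegative")
        norm = set()
        for e in self.edges:
            u, v = e
            if u == v:
                raise ValueError(f"self-loop {e} not allowed")
            if not (0 <= u < self.n_vertices and 0 <= v < self.n_vertices):
                raise ValueError(f"edge {e} out of range")
            norm.add((min(u, v), max(u, v)))
        object.__setattr__(self, "edges", frozenset(norm))

    @classmethod
    def from_edges(cls, n_vertices: int, edges) -> "VCInstance":
        return cls(n_vertices, frozenset(tuple(e) for e in edges))

    def is_cover(self, subset: set[int]) -> bool:
        return all(u in subset or v in subset for u, v in self.edges)


@dataclass
class ReductionResult:
    """The knockout instance built from a graph, with its index maps."""

    model: DDSModel
    vertex_genes: list[int]
    relay_genes: list[int]
    target_gene: int
    graph: VCInstance

    def expected_objective(self, deleted_vertices: set[int]) -> float:
        """Closed-form objective for a deletion set among the vertex genes."""
        n = self.graph.n_vertices
        uncovered = sum(
            1 for u, v in self.graph.edges
            if u not in deleted_vertices and v not in deleted_vertices
        )
        return 3 * n + 1 - len(deleted_vertices) - 4 * uncovered


def reduce_vertex_cover(graph: VCInstance) -> ReductionResult:
    """Build the knockout instance whose optima are the minimum vertex covers.

    The matrix is used directly as the system matrix (the construction
    operates on the solved two-step form, no rate decomposition); horizon 2,
    all-ones initial state, and the target gene is the readout.
    """
    n = graph.n_vertices
    size = 2 * n + 2  # vertex genes, relay genes, target, inert padding
    g = 2 * n
    B = np.zeros((size, size))
    for u, v in graph.edges:
        B[u, v] = B[v, u] = EDGE_WEIGHT
    for i in range(n):
        B[n + i, i] = RELAY_IN_WEIGHT  # vertex gene i -> relay i
        B[g, n + i] = RELAY_TO_TARGET  # relay i -> target
        B[g, i] = VERTEX_TO_TARGET  # vertex gene i -> target
    B[g, g] = TARGET_SELF_LOOP
    names = (
        [f"v{i}" for i in range(n)]
        + [f"r{i}" for i in range(n)]
        + ["target", "pad"]
    )
    model = DDSModel(
        gene_names=names, M=B, x0=np.ones(size), horizon=2, target=g, dt=1.0
    )
    return ReductionResult(
        model=model,
        vertex_genes=list(range(n)),
        relay_genes=list(range(n, 2 * n)),
        target_gene=g,
        graph=graph,
    )


def phi(subset: "set[int] | frozenset[int]", n: int) -> KnockoutVector:
    """The subset-to-knockout bijection: delete exactly the subset's vertex genes.

    Relay genes, the target and the padding gene stay intact, so distinct
    vertex subsets map to distinct feasible knockouts and back.
    """
    size = 2 * n + 2
    for i in subset:
        if not 0 <= i < n:
            raise ValueError(f"vertex index {i} out of range for n={n}")
    return KnockoutVector.from_deleted(size, set(subset), target=2 * n)


def brute_force_min_vertex_cover(graph: VCInstance, cap: int = 16) -> list[frozenset[int]]:
    """All minimum vertex covers, by enumeration in increasing subset size."""
    if graph.n_vertices > cap:
        raise CapExceededError(
            f"{graph.n_vertices} vertices exceed the brute-force cap of {cap}"
        )
    vertices = range(graph.n_vertices)
    for k in range(graph.n_vertices + 1):
        covers = [
            frozenset(c)
            for c in itertools.combinations(vertices, k)
            if graph.is_cover(set(c))
        ]
        if covers:
            return covers
    return [frozenset()]


def verify_equivalence(graph: VCInstance, tol: float = 1e-9) -> dict:
    """Double-oracle check that the reduction preserves optima exactly.

    Brute-forces the knockout instance over all vertex-gene deletion subsets
    and the vertex-cover instance over all subsets, then checks that (a) the
    knockout maximizers are exactly the images of the minimum covers under
    the bijection, and (b) the optimal value matches the closed form
    ``3n + 1 - (minimum cover size)``.
    """
    red = reduce_vertex_cover(graph)
    n = graph.n_vertices
    model = red.model
    subsets = [frozenset(c) for k in range(n + 1)
               for c in itertools.combinations(range(n), k)]
    S = np.ones((len(subsets), model.n))
    for r, subset in enumerate(subsets):
        S[r, list(subset)] = 0.0
    vals = objective_exact_many(model, S)
    best = vals.max()
    maximizers = {subsets[k] for k in np.flatnonzero(vals >= best - tol)}

    min_covers = set(brute_force_min_vertex_cover(graph))
    k_min = len(next(iter(min_covers)))
    expected = 3 * n + 1 - k_min
    passed = (maximizers == min_covers) and abs(best - expected) <= tol
    return {
        "passed": bool(passed),
        "optimal_value": float(best),
        "expected_value": float(expected),
        "min_cover_size": k_min,
        "maximizers": sorted(sorted(m) for m in maximizers),
        "min_covers": sorted(sorted(c) for c in min_covers),
    }


# ---------------------------------------------------------------------------
# graph file I/O
# ---------------------------------------------------------------------------

def read_graph(path: "str | Path") -> VCInstance:
    """Read a graph from JSON ``{"n": int, "edges": [[u, v], ...]}`` or an
    edge-list TSV (one ``u<TAB>v`` pair per line; ``n`` = max index + 1)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ModelError(f"cannot read graph file {path}: {exc}") from exc
        if not isinstance(doc, dict) or "n" not in doc or "edges" not in doc:
            raise ModelError("graph JSON must be {'n': int, 'edges': [[u, v], ...]}")
        try:
            return VCInstance.from_edges(int(doc["n"]), doc["edges"])
        except (TypeError, ValueError) as exc:
            raise ModelError(f"invalid graph: {exc}") from exc
    edges = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise ModelError(f"cannot read graph file {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ModelError(f"{path}:{lineno}: expected 'u<TAB>v', got {line!r}")
        try:
            edges.append((int(parts[0]), int(parts[1])))
        except ValueError as exc:
            raise ModelError(f"{path}:{lineno}: non-integer vertex id") from exc
    n = 1 + max((max(e) for e in edges), default=-1)
    try:
        return VCInstance.from_edges(n, edges)
    except ValueError as exc:
        raise ModelError(f"invalid graph: {exc}") from exc


def write_graph(graph: VCInstance, path: "str | Path") -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            {"n": graph.n_vertices, "edges": sorted(map(list, graph.edges))}
        ))
    else:
        path.write_text(
            "".join(f"{u}\t{v}\n" for u, v in sorted(graph.edges))
        )
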