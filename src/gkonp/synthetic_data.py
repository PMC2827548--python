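"""Random sparse network ensembles and curated toy fixtures.

The random ensemble emulates the simulation-study setting used to benchmark
the heuristic: sparse regulation (each gene with at most a couple of parent
genes, so at most a few nonzero entries per row of the system matrix),
signed weights drawn uniformly from a symmetric range, one unit of initial
concentration per gene, and the first gene as the downstream target.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .dds_model import DDSModel, build_system_matrix, write_model
from .vc_reduction import VCInstance

__all__ = [
    "EnsembleSpec",
    "random_sparse_dds",
    "random_graph",
    "toy_fixtures",
    "write_ensemble",
]


@dataclass
class EnsembleSpec:
    """Parameters of a random sparse model ensemble.

    ``max_parents`` caps the nonzero off-diagonal entries per row of the
    regulation matrix (each gene draws its parent count uniformly from
    ``1 .. max_parents``); weights are uniform in
    ``[weight_low, weight_high]``.  Defaults: at most two parents per gene,
    weights in [-1, 1], unit time step, horizon 10 — a sparse, signed
    regime in which negative paths arise but trajectories stay bounded.
    """

    n_genes: int
    max_parents: int = 2
    weight_low: float = -1.0
    weight_high: float = 1.0
    dt: float = 1.0
    horizon: int = 10
    seed: int = 0
    n_models: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.max_parents < self.n_genes:
            raise ValueError("max_parents must satisfy 0 <= max_parents < n_genes")
        if not self.weight_low < self.weight_high:
            raise ValueError("weight_low must be < weight_high")
        if self.dt <= 0 or self.horizon < 1 or self.n_models < 1:
            raise ValueError("dt must be > 0, horizon >= 1, n_models >= 1")


def random_sparse_dds(spec: EnsembleSpec) -> list[DDSModel]:
    """Generate the seeded random sparse model ensemble.

    Each gene's row of the regulation matrix receives ``k`` distinct parents
    (``k`` uniform in ``1 .. max_parents``; 0 when ``max_parents`` is 0) with
    uniform signed weights; the system matrix is ``I + dt * A``; every gene
    starts at one unit of concentration and the first gene is the target.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    models = []
    for _ in range(spec.n_models):
        A = np.zeros((n, n))
        for i in range(n):
            if spec.max_parents == 0:
                continue
            k = int(rng.integers(1, spec.max_parents + 1))
            # parents are other genes; a gene's own persistence is already
            # carried by the identity part of M = I + dt*A
            others = np.delete(np.arange(n), i)
            parents = rng.choice(others, size=k, replace=False)
            A[i, parents] = rng.uniform(spec.weight_low, spec.weight_high, size=k)
        models.append(
            DDSModel(
                gene_names=[f"G{i + 1}" for i in range(n)],
                M=build_system_matrix(A, spec.dt),
                x0=np.ones(n),
                horizon=spec.horizon,
                target=0,
                dt=spec.dt,
                A=A,
            )
        )
    return models


def random_graph(n: int, edge_prob: float, seed: int) -> VCInstance:
    """Seeded Erdős–Rényi G(n, p) graph as a vertex-cover instance."""
    if not 0 <= edge_prob <= 1:
        raise ValueError(f"edge probability must be in [0, 1], got {edge_prob}")
    graph = nx.gnp_random_graph(n, edge_prob, seed=seed)
    return VCInstance.from_edges(n, graph.edges())


def toy_fixtures() -> dict[str, dict]:
    """Small curated models with brute-forced optima in their metadata.

    Returns ``{name: {"model": DDSModel, "optimal_knockout": [...],
    "optimal_value": float}}``.  The documented optima were obtained with the
    exhaustive oracle and are re-asserted by the test suite.
    """
    fixtures: dict[str, dict] = {}

    # A single inhibitor feeding the target: deleting it removes the one
    # negative path (value 0 -> 1).
    fixtures["two_gene_inhibitor"] = {
        "model": DDSModel(
            gene_names=["G1", "G2"],
            M=np.array([[1.0, 0.0], [-1.0, 1.0]]),
            x0=np.array([1.0, 1.0]),
            horizon=1,
            target=1,
        ),
        "optimal_knockout": ["G1"],
        "optimal_value": 1.0,
    }

    # Activating cascade S -> X -> T with an off-pathway repressor branch
    # S -> R -| T; deleting R alone is optimal (the cascade stays intact).
    M = np.eye(5)
    M[1, 0] = 1.0   # S activates X
    M[4, 1] = 1.0   # X activates T
    M[2, 0] = 1.0   # S activates the repressor R
    M[4, 2] = -2.0  # R represses T
    fixtures["cascade_with_repressor"] = {
        "model": DDSModel(
            gene_names=["S", "X", "R", "U", "T"],
            M=M,
            x0=np.ones(5),
            horizon=3,
            target=4,
        ),
        "optimal_knockout": ["R"],
        "optimal_value": 7.0,
    }

    # All regulation positive: no negative path, so deleting anything only
    # removes mass and the empty knockout is optimal.
    M = np.eye(4)
    M[1, 0] = 0.5
    M[2, 1] = 0.5
    M[3, 2] = 0.5
    fixtures["all_positive_chain"] = {
        "model": DDSModel(
            gene_names=["G1", "G2", "G3", "G4"],
            M=M,
            x0=np.ones(4),
            horizon=4,
            target=3,
        ),
        "optimal_knockout": [],
        "optimal_value": 5.0,
    }
    return fixtures


def write_ensemble(models: list[DDSModel], spec: EnsembleSpec, out_dir: "str | Path") -> Path:
    """Write model JSON files plus a manifest recording the generator spec.

    Returns the manifest path; the manifest lists every model file along
    with the spec (seed included) that reproduces the ensemble.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for k, model in enumerate(models):
        name = f"model_{k:03d}.json"
        write_model(model, out_dir / name)
        files.append(name)
    manifest = {"spec": asdict(spec), "files": files}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
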