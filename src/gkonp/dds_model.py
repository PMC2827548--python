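"""Discrete dynamical system (DDS) model of a gene regulatory network.

The model is the first-order linear update

    x(t+1) = M x(t),        M = I + dt * A,

where ``x(t)`` is the vector of gene concentrations at discrete time ``t``,
``A`` is the regulation (rate) matrix and ``M`` the dimensionless system
matrix.  Entry ``M[j, i]`` is the per-step multiplier from source gene ``i``
to destination gene ``j`` (columns index sources).

Knocking out a gene removes it from the network: its row and column of
``M`` and its initial concentration are zeroed.  The optimization problem
studied in this package is to choose a binary knockout vector (the target
gene fixed intact) that maximizes the target gene's concentration at a
horizon time ``T``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ModelError",
    "DDSModel",
    "KnockoutVector",
    "build_system_matrix",
    "apply_knockout",
    "simulate",
    "objective_exact",
    "objective_exact_many",
    "read_model",
    "write_model",
]

#: default absolute/relative tolerance for floating-point consistency checks
DEFAULT_TOL = 1e-9


class ModelError(ValueError):
    """Raised for malformed or inconsistent model inputs."""


def build_system_matrix(A: np.ndarray, dt: float) -> np.ndarray:
    """Return the system matrix ``M = I + dt * A``.

    Parameters
    ----------
    A:
        Square regulation matrix (rate units, per unit of real time).
    dt:
        Real time between two consecutive discrete time points; must be > 0.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ModelError(f"regulation matrix must be square, got shape {A.shape}")
    if not dt > 0:
        raise ModelError(f"time step dt must be positive, got {dt}")
    return np.eye(A.shape[0]) + dt * A


@dataclass
class KnockoutVector:
    """Binary per-gene intact/deleted assignment.

    ``s[i] = 1`` keeps gene ``i`` intact, ``s[i] = 0`` deletes it.  The
    target gene is always intact: deleting the very gene whose concentration
    is being maximized is never useful, so it is excluded by constraint.
    """

    s: np.ndarray
    target: int

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.ndim != 1:
            raise ModelError("knockout vector must be one-dimensional")
        if not np.isin(self.s, (0.0, 1.0)).all():
            raise ModelError("knockout vector entries must be 0 or 1")
        if not 0 <= self.target < self.s.size:
            raise ModelError("target index out of range")
        if self.s[self.target] != 1:
            raise ModelError("the target gene must stay intact (s[target] = 1)")

    @classmethod
    def from_deleted(cls, n: int, deleted: "set[int] | list[int]", target: int) -> "KnockoutVector":
        s = np.ones(n)
        for i in deleted:
            if not 0 <= i < n:
                raise ModelError(f"deleted gene index {i} out of range")
            s[i] = 0.0
        return cls(s, target)

    @property
    def deleted(self) -> set[int]:
        return set(np.flatnonzero(self.s == 0.0).tolist())


@dataclass
class DDSModel:
    """A DDS network model together with the knockout-optimization setup.

    Attributes
    ----------
    gene_names:
        Identifiers, one per gene; user-facing outputs are name-based.
    M:
        ``n x n`` system matrix; ``M[j, i]`` multiplies source ``i`` into
        destination ``j`` over one step.
    x0:
        Nonnegative initial concentrations (arbitrary concentration units).
    horizon:
        Number of discrete steps ``T >= 1`` at which the target is read out.
    target:
        Index of the downstream gene whose concentration is maximized.
    dt:
        Real time per step (seconds, say); only used to relate ``A`` and ``M``.
    A:
        Optional regulation matrix; if given it must satisfy
        ``M == I + dt * A`` within tolerance.
    """

    gene_names: list[str]
    M: np.ndarray
    x0: np.ndarray
    horizon: int
    target: int
    dt: float = 1.0
    A: np.ndarray | None = None
    tol: float = field(default=DEFAULT_TOL, repr=False)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        n = len(self.gene_names)
        if len(set(self.gene_names)) != n:
            raise ModelError("gene names must be unique")
        if self.M.shape != (n, n):
            raise ModelError(
                f"system matrix shape {self.M.shape} does not match {n} genes"
            )
        if self.x0.shape != (n,):
            raise ModelError(f"x0 length {self.x0.shape} does not match {n} genes")
        if (self.x0 < 0).any():
            raise ModelError("initial concentrations must be nonnegative")
        if not (isinstance(self.horizon, (int, np.integer)) and self.horizon >= 1):
            raise ModelError(f"horizon must be an integer >= 1, got {self.horizon}")
        self.horizon = int(self.horizon)
        if not 0 <= self.target < n:
            raise ModelError(f"target index {self.target} out of range for {n} genes")
        if not self.dt > 0:
            raise ModelError(f"dt must be positive, got {self.dt}")
        if self.A is not None:
            self.A = np.asarray(self.A, dtype=float)
            if self.A.shape != (n, n):
                raise ModelError("regulation matrix shape does not match gene count")
            expected = build_system_matrix(self.A, self.dt)
            if not np.allclose(expected, self.M, rtol=self.tol, atol=self.tol):
                raise ModelError("M is inconsistent with I + dt * A")

    @property
    def n(self) -> int:
        return len(self.gene_names)

    @property
    def target_name(self) -> str:
        return self.gene_names[self.target]

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise ModelError(f"unknown gene name: {name!r}") from None

    def knockout(self, deleted_names: "list[str] | set[str]" = ()) -> KnockoutVector:
        """Build a knockout vector from gene names to delete."""
        idx = {self.gene_index(name) for name in deleted_names}
        return KnockoutVector.from_deleted(self.n, idx, self.target)

    def all_intact(self) -> KnockoutVector:
        return KnockoutVector(np.ones(self.n), self.target)


def _as_mask(s: "KnockoutVector | np.ndarray", n: int, target: int | None) -> np.ndarray:
    if isinstance(s, KnockoutVector):
        if target is not None and s.target != target:
            raise ModelError("knockout vector target does not match model target")
        s = s.s
    s = np.asarray(s, dtype=float)
    if s.shape != (n,):
        raise ModelError(f"knockout vector length {s.shape} does not match {n} genes")
    if target is not None and s[target] != 1:
        raise ModelError("the target gene must stay intact (s[target] = 1)")
    return s


def apply_knockout(
    M: np.ndarray, s: "KnockoutVector | np.ndarray", target: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mask the system matrix for a knockout.

    Returns ``(M_s, mask)`` where ``M_s = D M D`` with ``D = diag(s)`` —
    every deleted gene's row *and* column are zeroed — and ``mask`` is the
    diagonal of ``D``, to be applied to ``x0`` as well.  Zeroing both row and
    column plus the initial state is the convention under which the
    matrix-power objective coincides with the path-sum objective in which a
    path's monomial carries every gene the path visits, its source included.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ModelError("system matrix must be square")
    mask = _as_mask(s, M.shape[0], target)
    return mask[:, None] * M * mask[None, :], mask


def simulate(model: DDSModel, s: "KnockoutVector | np.ndarray | None" = None) -> np.ndarray:
    """Exact trajectory ``x(t) = M(s)^t x0(s)`` for ``t = 0 .. horizon``.

    Returns an array of shape ``(horizon + 1, n)``; deleted genes are
    identically zero at all times.
    """
    if s is None:
        s = model.all_intact()
    Ms, mask = apply_knockout(model.M, s, model.target)
    traj = np.empty((model.horizon + 1, model.n))
    v = model.x0 * mask
    traj[0] = v
    for t in range(1, model.horizon + 1):
        v = Ms @ v
        traj[t] = v
    return traj


def objective_exact(model: DDSModel, s: "KnockoutVector | np.ndarray | None" = None) -> float:
    """Target-gene concentration at the horizon, ``[M(s)^T x0(s)]_g``.

    This is the exact (matrix-power) objective of the knockout problem,
    evaluated by repeated masked matrix-vector products.
    """
    if s is None:
        s = model.all_intact()
    mask = _as_mask(s, model.n, model.target)
    v = model.x0 * mask
    for _ in range(model.horizon):
        v = model.M @ v
        v *= mask
    return float(v[model.target])


def objective_exact_many(model: DDSModel, S: np.ndarray) -> np.ndarray:
    """Vectorized :func:`objective_exact` over a batch of knockout vectors.

    ``S`` has shape ``(m, n)`` with binary rows (``S[:, target]`` all 1);
    returns the ``m`` objective values.  Used by the exhaustive oracle.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] != model.n:
        raise ModelError("batch must have shape (m, n)")
    if (S[:, model.target] != 1).any():
        raise ModelError("the target gene must stay intact in every row")
    V = model.x0[None, :] * S
    MT = model.M.T
    for _ in range(model.horizon):
        V = V @ MT
        V *= S
    return V[:, model.target].copy()


# ---------------------------------------------------------------------------
# model file I/O
# ---------------------------------------------------------------------------

def _matrix_from_json(value, n: int, key: str) -> np.ndarray:
    """Decode a dense n x n list-of-rows or sparse [row, col, value] triplets.

    A list is read as dense when it has exactly ``n`` rows of length ``n``;
    otherwise it is read as triplets (for ``n == 3`` a 3x3 list is dense).
    """
    if not isinstance(value, list) or not value:
        raise ModelError(f"{key!r} must be a non-empty list")
    rows = [r for r in value if isinstance(r, list)]
    if len(rows) != len(value):
        raise ModelError(f"{key!r} must be a list of lists")
    if len(value) == n and all(len(r) == n for r in value):
        return np.asarray(value, dtype=float)
    mat = np.zeros((n, n))
    for trip in value:
        if len(trip) != 3:
            raise ModelError(f"{key!r}: sparse entries must be [row, col, value]")
        i, j, w = trip
        i, j = int(i), int(j)
        if not (0 <= i < n and 0 <= j < n):
            raise ModelError(f"{key!r}: sparse index ({i}, {j}) out of range")
        mat[i, j] = float(w)
    return mat


def _model_from_dict(doc: dict) -> DDSModel:
    for req in ("genes", "horizon", "target", "x0"):
        if req not in doc:
            raise ModelError(f"model file is missing required key {req!r}")
    genes = [str(g) for g in doc["genes"]]
    n = len(genes)
    dt = float(doc.get("dt", 1.0))
    A = _matrix_from_json(doc["A"], n, "A") if "A" in doc else None
    M = _matrix_from_json(doc["M"], n, "M") if "M" in doc else None
    if M is None:
        if A is None:
            raise ModelError("model file must provide 'A' or 'M'")
        M = build_system_matrix(A, dt)
    target = doc["target"]
    if isinstance(target, str):
        if target not in genes:
            raise ModelError(f"target gene {target!r} not among gene names")
        target = genes.index(target)
    x0 = np.asarray(doc["x0"], dtype=float)
    if x0.shape != (n,):
        raise ModelError("x0 length does not match gene count")
    return DDSModel(
        gene_names=genes, M=M, x0=x0, horizon=int(doc["horizon"]),
        target=int(target), dt=dt, A=A,
    )


def read_model(path: "str | Path", metadata_path: "str | Path | None" = None) -> DDSModel:
    """Read a model from a JSON file or a TSV matrix plus JSON metadata.

    JSON schema: ``{"genes": [...], "dt": float, "horizon": int,
    "target": "<gene name>", "x0": [...], "A" | "M": dense rows or
    [row, col, value] triplets}``.

    A ``.tsv`` path is read as a tab-separated dense system matrix with gene
    names as header row and first column (rows = destinations); the remaining
    fields come from ``metadata_path`` (default: same path with ``.json``).
    """
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        meta = Path(metadata_path) if metadata_path else path.with_suffix(".json")
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pandas raises several parse error types
            raise ModelError(f"malformed TSV matrix {path}: {exc}") from exc
        if frame.isna().any().any():
            raise ModelError(f"TSV matrix {path} is ragged or has missing entries")
        genes = [str(g) for g in frame.index]
        if [str(c) for c in frame.columns] != genes:
            raise ModelError("TSV header row and first column must list the same genes")
        try:
            doc = json.loads(meta.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ModelError(f"cannot read model metadata {meta}: {exc}") from exc
        doc = dict(doc)
        doc["genes"] = genes
        doc["M"] = frame.to_numpy(dtype=float).tolist()
        return _model_from_dict(doc)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelError("model JSON must be an object")
    return _model_from_dict(doc)


def write_model(model: DDSModel, path: "str | Path") -> None:
    """Write a model as JSON (``.json``) or TSV matrix + JSON metadata (``.tsv``)."""
    path = Path(path)
    meta = {
        "genes": model.gene_names,
        "dt": model.dt,
        "horizon": model.horizon,
        "target": model.target_name,
        "x0": model.x0.tolist(),
    }
    if path.suffix.lower() in (".tsv", ".txt"):
        frame = pd.DataFrame(model.M, index=model.gene_names, columns=model.gene_names)
        frame.to_csv(path, sep="\t")
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return
    doc = dict(meta)
    if model.A is not None:
        doc["A"] = model.A.tolist()
    doc["M"] = model.M.tolist()
    path.write_text(json.dumps(doc, indent=1))
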