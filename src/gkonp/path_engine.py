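"""Path algebra: the multilinear (pseudo-Boolean) form of the knockout objective.

A *path* is a time-indexed gene sequence ``(j_0, ..., j_T)`` ending at the
target gene; its *weight* is the product of the traversed system-matrix
entries ``M[j_{t+1}, j_t]`` and its *contribution* is the weight times the
source gene's initial concentration.  The target-gene concentration at the
horizon equals the sum of contributions over all paths, and a path survives a
knockout exactly when every gene it visits is intact.  Collecting paths by
their set of unique visited genes turns the objective into a multilinear
polynomial

    f(s) = sum_k  c_k * prod_{i in G_k} s_i ,

evaluable on the whole hypercube ``[0, 1]^n`` — the relaxation solved by the
optimizer, which is guaranteed to attain its maximum at a vertex.

The number of paths grows exponentially with the horizon, so the builder
sweeps backward in time over partial path suffixes, merging suffixes that
share a (current gene, visited-gene set) key and optionally discarding
low-weight suffixes per sign class (the filtering pass controlled by the
prune coefficient ``epsilon``).  ``epsilon = 0`` reproduces the exact
polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dds_model import DDSModel, ModelError

__all__ = [
    "PathTerm",
    "MultilinearObjective",
    "PathCountError",
    "estimate_path_count",
    "enumerate_terms_exact",
    "fdp",
    "negative_gene_set",
    "evaluate",
    "evaluate_batch",
    "restrict",
]

#: coefficients below this magnitude after collapsing are numerical noise
COEF_FLOOR = 1e-15

#: default guard on full enumeration (estimated number of paths)
DEFAULT_PATH_CAP = 10_000_000


class PathCountError(RuntimeError):
    """Full enumeration refused: estimated path count exceeds the cap.

    Use :func:`fdp` with a positive prune coefficient instead.
    """


@dataclass(frozen=True)
class PathTerm:
    """One monomial of the multilinear objective.

    ``coefficient`` is the summed contribution (weight x source initial
    concentration) of every path whose set of unique visited genes is
    ``gene_set``; the monomial's variables are exactly that set.
    """

    coefficient: float
    gene_set: frozenset[int]


@dataclass
class MultilinearObjective:
    """Collapsed sum of ``coefficient * prod(s_i for i in gene_set)`` terms.

    Terms have pairwise-distinct gene sets; evaluation at the all-ones vector
    is the plain (no-knockout) objective.  ``n`` is the ambient gene count
    and ``target`` the target-gene index (present in every gene set).
    """

    n: int
    target: int
    terms: list[PathTerm]
    meta: dict = field(default_factory=dict)
    _coefs: np.ndarray = field(init=False, repr=False)
    _members: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        sets = [t.gene_set for t in self.terms]
        if len(set(sets)) != len(sets):
            raise ValueError("objective terms must have pairwise-distinct gene sets")
        self._coefs = np.array([t.coefficient for t in self.terms], dtype=float)
        # membership[i, k] == True iff gene i occurs in term k's monomial
        members = np.zeros((self.n, len(self.terms)), dtype=bool)
        for k, t in enumerate(self.terms):
            for i in t.gene_set:
                members[i, k] = True
        self._members = members

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def genes_involved(self) -> set[int]:
        out: set[int] = set()
        for t in self.terms:
            out |= t.gene_set
        return out

    def to_records(self, gene_names: list[str]) -> list[dict]:
        """JSON-friendly dump: ``[{"genes": [...], "coef": float}, ...]``."""
        recs = []
        for t in sorted(self.terms, key=lambda t: (len(t.gene_set), sorted(t.gene_set))):
            recs.append({
                "genes": [gene_names[i] for i in sorted(t.gene_set)],
                "coef": t.coefficient,
            })
        return recs


def _sorted_terms(collapsed: dict[frozenset[int], float]) -> list[PathTerm]:
    items = [
        (gs, c) for gs, c in collapsed.items() if abs(c) > COEF_FLOOR
    ]
    items.sort(key=lambda kv: (len(kv[0]), sorted(kv[0])))
    return [PathTerm(coefficient=c, gene_set=gs) for gs, c in items]


def _prune_sign_class(entries: list[tuple[frozenset[int], float]], epsilon: float):
    """Drop low-|weight| entries whose cumulative |weight| stays within
    ``epsilon`` times the |weight| total of the entries retained.

    Entries are removed greedily in ascending |weight| order; an entry that
    would push the removed mass past the allowance is retained (ties prefer
    accuracy), and once one entry is retained all heavier ones are too.
    """
    if epsilon <= 0 or len(entries) <= 1:
        return entries
    order = sorted(range(len(entries)), key=lambda k: abs(entries[k][1]))
    total = sum(abs(entries[k][1]) for k in order)
    removed = 0.0
    cut = 0
    for pos, k in enumerate(order):
        w = abs(entries[k][1])
        if removed + w <= epsilon * (total - removed - w):
            removed += w
            cut = pos + 1
        else:
            break
    keep = set(order[cut:])
    return [entries[k] for k in sorted(keep)]


def _sweep(model: DDSModel, epsilon: float, merge: bool = True) -> MultilinearObjective:
    """Backward suffix sweep building the (possibly pruned) objective.

    A suffix entry at (gene i, time t) is a partial path from i at time t to
    the target at the horizon, carrying its weight and visited-gene set.
    Each layer extends every suffix one step back through the nonzero
    in-entries of the system matrix, then merges suffixes with identical
    (gene, visited set) keys and applies the per-bucket, per-sign filtering
    pass.  At time 0 surviving suffixes become monomials.
    """
    M = model.M
    n, T, g = model.n, model.horizon, model.target
    in_sources = [np.flatnonzero(M[i]) for i in range(n)]  # row i: sources feeding i
    suffixes_pruned = 0

    # bucket[gene] -> {visited frozenset: weight} (merged) or list of pairs
    bucket: dict[int, list[tuple[frozenset[int], float]]]
    bucket = {g: [(frozenset((g,)), 1.0)]}
    for _t in range(T):
        new: dict[int, dict | list] = {}
        for i, entries in bucket.items():
            for j in in_sources[i]:
                hop = M[i, j]
                dest = new.setdefault(j, {} if merge else [])
                if merge:
                    for vs, w in entries:
                        key = vs if j in vs else vs | {j}
                        dest[key] = dest.get(key, 0.0) + hop * w
                else:
                    for vs, w in entries:
                        key = vs if j in vs else vs | {j}
                        dest.append((key, hop * w))
        bucket = {}
        for j, dest in new.items():
            entries = list(dest.items()) if merge else dest
            entries = [(vs, w) for vs, w in entries if w != 0.0]
            pos = [(vs, w) for vs, w in entries if w > 0]
            neg = [(vs, w) for vs, w in entries if w < 0]
            kept = _prune_sign_class(pos, epsilon) + _prune_sign_class(neg, epsilon)
            suffixes_pruned += len(entries) - len(kept)
            if kept:
                bucket[j] = kept

    n_path_terms = sum(len(entries) for entries in bucket.values())
    collapsed: dict[frozenset[int], float] = {}
    for j, entries in bucket.items():
        c0 = model.x0[j]
        if c0 == 0.0:
            continue
        for vs, w in entries:
            collapsed[vs] = collapsed.get(vs, 0.0) + w * c0
    return MultilinearObjective(
        n=n, target=g, terms=_sorted_terms(collapsed),
        meta={
            "epsilon": epsilon,
            "suffixes_pruned": suffixes_pruned,
            "n_path_terms": n_path_terms,
        },
    )


def estimate_path_count(model: DDSModel) -> float:
    """Number of paths of length ``horizon`` ending at the target gene."""
    counts = (model.M != 0).astype(float)
    v = np.zeros(model.n)
    v[model.target] = 1.0
    for _ in range(model.horizon):
        v = v @ counts  # one backward step: v[j] = paths from j
    return float(v.sum())


def enumerate_terms_exact(model: DDSModel, cap: float = DEFAULT_PATH_CAP) -> MultilinearObjective:
    """Exact multilinear objective by full (merged) path enumeration.

    Refuses models whose estimated path count exceeds ``cap``; use
    :func:`fdp` with ``epsilon > 0`` for those.
    """
    count = estimate_path_count(model)
    if count > cap:
        raise PathCountError(
            f"estimated path count {count:.3g} exceeds cap {cap:.3g}; "
            "use fdp() with a positive prune coefficient"
        )
    return _sweep(model, epsilon=0.0)


def fdp(model: DDSModel, epsilon: float, merge: bool = True) -> MultilinearObjective:
    """Filtered backward path-term generation with prune coefficient ``epsilon``.

    At each backward time layer and within each (gene, time) bucket, the
    lightest same-sign suffixes are discarded as long as their cumulative
    |weight| stays at most ``epsilon`` times the |weight| total of the
    suffixes retained in that sign class.  ``epsilon = 0`` is exact.
    """
    if not 0 <= epsilon < 1:
        raise ValueError(f"prune coefficient must be in [0, 1), got {epsilon}")
    return _sweep(model, epsilon=epsilon, merge=merge)


def negative_gene_set(obj: MultilinearObjective) -> set[int]:
    """Genes occurring in any negative-coefficient term, the target excluded.

    Only these genes are useful deletion candidates: a gene appearing solely
    in nonnegative terms makes the objective nondecreasing in its knockout
    variable, so keeping it intact is always optimal.  Restricting the search
    to this set shrinks the feasible space from ``2^(n-1)`` to ``2^|G-|``.
    """
    out: set[int] = set()
    for t in obj.terms:
        if t.coefficient < 0:
            out |= t.gene_set
    out.discard(obj.target)
    return out


def _check_box(obj: MultilinearObjective, s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != (obj.n,):
        raise ValueError(f"expected a length-{obj.n} vector, got shape {s.shape}")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("knockout relaxation entries must lie in [0, 1]")
    return s


def evaluate(obj: MultilinearObjective, s: np.ndarray) -> float:
    """Evaluate the multilinear polynomial at ``s`` in ``[0, 1]^n``.

    Fractional coordinates are allowed (the relaxation used by the
    evolutionary search and the vertex-rounding step).
    """
    s = _check_box(obj, s)
    if obj.n_terms == 0:
        return 0.0
    prods = np.ones(obj.n_terms)
    for i in np.flatnonzero(s != 1.0):
        prods[obj._members[i]] *= s[i]
    return float(prods @ obj._coefs)


def evaluate_batch(obj: MultilinearObjective, S: np.ndarray) -> np.ndarray:
    """Vectorized :func:`evaluate` over rows of ``S`` (shape ``(m, n)``)."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] != obj.n:
        raise ValueError(f"expected shape (m, {obj.n})")
    if (S < 0).any() or (S > 1).any():
        raise ValueError("knockout relaxation entries must lie in [0, 1]")
    if obj.n_terms == 0:
        return np.zeros(S.shape[0])
    prods = np.ones((S.shape[0], obj.n_terms))
    for i in range(obj.n):
        col = S[:, i]
        if (col == 1.0).all():
            continue
        prods[:, obj._members[i]] *= col[:, None]
    return prods @ obj._coefs


def restrict(obj: MultilinearObjective, free_genes: list[int]) -> MultilinearObjective:
    """Collapse the objective onto a subset of free knockout variables.

    All genes outside ``free_genes`` are fixed intact (s = 1), so terms whose
    monomials agree on the free genes merge.  The result evaluates
    identically to the original whenever the fixed coordinates are 1, with
    far fewer terms — the surrogate handed to the evolutionary search.
    """
    free = frozenset(free_genes)
    collapsed: dict[frozenset[int], float] = {}
    for t in obj.terms:
        key = t.gene_set & free
        collapsed[key] = collapsed.get(key, 0.0) + t.coefficient
    terms = [PathTerm(c, gs) for gs, c in collapsed.items() if abs(c) > COEF_FLOOR or not gs]
    terms.sort(key=lambda t: (len(t.gene_set), sorted(t.gene_set)))
    return MultilinearObjective(n=obj.n, target=obj.target, terms=terms)
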