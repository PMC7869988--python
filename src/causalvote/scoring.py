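"""Intervention-masked BDeu network score.

The score of a candidate DAG given one experiment's data is the log marginal
likelihood of the data under Dirichlet parameter priors with a uniform
equivalent sample size (BDeu).  Interventions enter through the per-sample
mask: a sample in which a variable was externally clamped contributes
nothing to that variable's local score (its value carries no information
about the variable's native conditional distribution), while the same
sample still conditions the scores of the variable's children normally.

For variable ``V`` with level count ``r`` and a parent set inducing ``q``
joint parent configurations (``q = 1`` for the empty set), the local score is

    sum_j [ lnG(a_j) - lnG(a_j + N_j) ] + sum_jk [ lnG(a_jk + N_jk) - lnG(a_jk) ]

with ``a_jk = iss / (q r)``, ``a_j = iss / q`` and counts ``N`` taken only
over samples where ``V`` is unmasked.  A uniform structure prior contributes
an additive constant over DAGs of a fixed node set and is omitted.  Natural
logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import Dag, ExperimentDataset

__all__ = [
    "ScoreConfig",
    "LocalScoreKey",
    "ScoreCache",
    "local_bdeu",
    "network_score",
    "score_delta",
    "apply_move",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Score hyperparameters.

    iss
        Equivalent sample size: total Dirichlet prior mass spread uniformly
        over each local count table.  Must be positive.  Default 1.
    structure_prior
        Only ``"uniform"`` is supported; the corresponding log-prior term is
        constant across DAGs and dropped.
    """

    iss: float = 1.0
    structure_prior: str = "uniform"

    def __post_init__(self):
        if not self.iss > 0:
            raise ValueError(f"iss must be positive, got {self.iss}")
        if self.structure_prior != "uniform":
            raise ValueError("only the uniform structure prior is supported")


@dataclass(frozen=True)
class LocalScoreKey:
    """Cache key for a local score: (variable, sorted parent set, experiment)."""

    variable: str
    parent_set: tuple[str, ...]
    experiment_id: str

    def __post_init__(self):
        if self.variable in self.parent_set:
            raise ValueError(f"{self.variable!r} cannot be its own parent")


def _local_from_counts(counts: np.ndarray, q: int, r: int, iss: float) -> float:
    """BDeu local score from a (q, r) count table.

    Parent configurations with zero total count contribute exactly zero
    (their lgamma terms cancel), so only occupied rows are touched.
    """
    n_j = counts.sum(axis=1)
    occupied = n_j > 0
    if not occupied.any():
        return 0.0
    a_j = iss / q
    a_jk = iss / (q * r)
    counts = counts[occupied]
    score = float(np.sum(gammaln(a_j) - gammaln(a_j + n_j[occupied])))
    score += float(np.sum(gammaln(a_jk + counts) - gammaln(a_jk)))
    return score


def _local_bdeu_codes(
    codes: np.ndarray,
    mask_col: np.ndarray,
    cards: np.ndarray,
    var: int,
    parents: tuple[int, ...],
    iss: float,
) -> float:
    """Fast path: local score from integer level codes.

    ``parents`` are variable indices sorted ascending; the joint parent
    configuration index is row-major with the last parent varying fastest,
    matching the CPT row convention of the simulator.
    """
    rows = ~mask_col
    if not rows.any():
        return 0.0
    r = int(cards[var])
    v_codes = codes[rows, var].astype(np.int64)
    if parents:
        q = 1
        cfg = np.zeros(v_codes.shape[0], dtype=np.int64)
        for p in parents:
            cfg = cfg * int(cards[p]) + codes[rows, p]
            q *= int(cards[p])
    else:
        q = 1
        cfg = np.zeros(v_codes.shape[0], dtype=np.int64)
    flat = cfg * r + v_codes
    counts = np.bincount(flat, minlength=q * r).reshape(q, r)
    return _local_from_counts(counts, q, r, iss)


class ScoreCache:
    """Memoized local scores for one (dataset, score config) pair.

    Shared across all Tabu restarts on the same experiment, where the search
    revisits the same (variable, parent set) pairs constantly.
    """

    __slots__ = ("data", "cfg", "_cards", "_store")

    def __init__(self, data: ExperimentDataset, cfg: ScoreConfig):
        self.data = data
        self.cfg = cfg
        self._cards = data.domain.cardinalities()
        self._store: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, var: int, parents: tuple[int, ...]) -> float:
        key = (var, parents)
        score = self._store.get(key)
        if score is None:
            score = _local_bdeu_codes(
                self.data.codes,
                self.data.mask[:, var],
                self._cards,
                var,
                parents,
                self.cfg.iss,
            )
            self._store[key] = score
        return score

    def local_by_name(self, variable: str, parent_set) -> float:
        dom = self.data.domain
        var = dom.index(variable)
        parents = tuple(sorted(dom.index(p) for p in parent_set))
        if var in parents:
            raise ValueError(f"{variable!r} cannot be its own parent")
        return self.local(var, parents)

    def __len__(self) -> int:
        return len(self._store)


def local_bdeu(
    variable: str,
    parent_set,
    data: ExperimentDataset,
    cfg: ScoreConfig = ScoreConfig(),
) -> float:
    """Masked BDeu local score of ``variable`` given ``parent_set``.

    Counts are accumulated only over samples where the variable itself is
    unmasked; parent values in samples where *other* variables are masked
    still condition normally.  Returns 0.0 when the variable is masked in
    every sample (empty product).
    """
    return ScoreCache(data, cfg).local_by_name(variable, parent_set)


def network_score(
    dag: Dag,
    data: ExperimentDataset,
    cfg: ScoreConfig = ScoreConfig(),
    cache: ScoreCache | None = None,
) -> float:
    """Decomposable network score: sum of masked BDeu local scores."""
    if set(dag.nodes) != set(data.variables):
        diff = set(dag.nodes) ^ set(data.variables)
        raise ValueError(f"node sets differ between DAG and data: {sorted(diff)}")
    if cache is None:
        cache = ScoreCache(data, cfg)
    total = 0.0
    for v in dag.nodes:
        total += cache.local_by_name(v, dag.parents(v))
    return total


def apply_move(dag: Dag, move: tuple[str, str, str]) -> Dag:
    """Apply an (kind, u, v) arc move, validating legality.

    ``kind`` is one of ``"add"``, ``"delete"``, ``"reverse"``.
    """
    kind, u, v = move
    if kind == "add":
        return dag.with_edge(u, v)
    if kind == "delete":
        return dag.without_edge(u, v)
    if kind == "reverse":
        return dag.with_reversed(u, v)
    raise ValueError(f"unknown move kind {kind!r}")


def score_delta(
    dag: Dag,
    move: tuple[str, str, str],
    data: ExperimentDataset,
    cfg: ScoreConfig = ScoreConfig(),
    cache: ScoreCache | None = None,
) -> float:
    """Score change of a legal arc move, recomputing only affected locals.

    Only the child's local score changes for add/delete; reverse touches
    both endpoints.  Results are memoized through the cache.
    """
    if cache is None:
        cache = ScoreCache(data, cfg)
    kind, u, v = move
    new = apply_move(dag, move)  # raises on illegal moves
    delta = cache.local_by_name(v, new.parents(v)) - cache.local_by_name(
        v, dag.parents(v)
    )
    if kind == "reverse":
        delta += cache.local_by_name(u, new.parents(u)) - cache.local_by_name(
            u, dag.parents(u)
        )
    return delta
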