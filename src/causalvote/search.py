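"""Random connected start DAGs and Tabu search over arc moves.

Each experiment is analysed by an ensemble of Tabu runs started from random
connected DAGs; the ensemble's disagreement is what later becomes the arc
probability table.  The search space is the set of DAGs over the
experiment's variables minus any blacklisted arcs (arcs into declared
intervention targets are forbidden outright, in addition to being masked
out of the score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable

import numpy as np

from .core import CycleError, Dag, ExperimentDataset
from .scoring import ScoreCache, ScoreConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TabuConfig",
    "Blacklist",
    "create_random_connected_dag",
    "tabu_search",
    "learn_ensemble",
]

_KINDS = ("add", "delete", "reverse")


@dataclass(frozen=True)
class TabuConfig:
    """Search hyperparameters.

    ensemble_size
        Number of random restarts per experiment (the ensemble size n).
        100 restarts is adequate for networks of the sizes studied here.
    tabu_list_length
        How many recently undone moves stay forbidden.
    max_stagnation
        Steps without improving the best-so-far score before stopping;
        ``None`` means ``max(100, 10 * n_nodes)``.
    base_seed
        Restart m uses seed ``base_seed + m`` (1-based) for its start DAG.
    """

    tabu_list_length: int = 10
    max_stagnation: int | None = None
    ensemble_size: int = 100
    base_seed: int = 0

    def __post_init__(self):
        if self.tabu_list_length <= 0 or self.ensemble_size <= 0:
            raise ValueError("tabu_list_length and ensemble_size must be positive")
        if self.max_stagnation is not None and self.max_stagnation <= 0:
            raise ValueError("max_stagnation must be positive")

    def stagnation_limit(self, n_nodes: int) -> int:
        if self.max_stagnation is not None:
            return self.max_stagnation
        return max(100, 10 * n_nodes)


@dataclass(frozen=True)
class Blacklist:
    """A set of forbidden directed arcs."""

    arcs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        arcs = frozenset((str(u), str(v)) for u, v in self.arcs)
        for u, v in arcs:
            if u == v:
                raise ValueError(f"blacklist cannot contain self-loop {u!r}")
        object.__setattr__(self, "arcs", arcs)

    @classmethod
    def into_targets(cls, nodes: Iterable[str], targets: Iterable[str]) -> "Blacklist":
        """Forbid every arc incident *into* each target."""
        nodes = list(nodes)
        return cls(
            frozenset((u, t) for t in targets for u in nodes if u != t)
        )

    def __contains__(self, arc: tuple[str, str]) -> bool:
        return arc in self.arcs

    def matrix(self, nodes: tuple[str, ...]) -> np.ndarray:
        idx = {n: i for i, n in enumerate(nodes)}
        m = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for u, v in self.arcs:
            if u in idx and v in idx:
                m[idx[u], idx[v]] = True
        return m


def create_random_connected_dag(nodes, seed: int) -> Dag:
    """Random weakly connected DAG: permutation + spanning tree + extra arcs.

    A random permutation fixes an ancestral order; a random spanning tree is
    oriented forward along it (guaranteeing weak connectivity and
    acyclicity); each remaining forward pair is added independently with
    probability ``min(1, 2/(n-1))`` so the expected extra degree is about 2.
    Deterministic given the seed.
    """
    nodes = tuple(nodes)
    if not nodes:
        raise ValueError("need at least one node")
    if len(nodes) == 1:
        return Dag(nodes)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(nodes))
    edges: set[tuple[str, str]] = set()
    # spanning tree: attach each node (in permuted order) to a random earlier one
    for pos in range(1, len(nodes)):
        anchor = int(rng.integers(0, pos))
        edges.add((nodes[order[anchor]], nodes[order[pos]]))
    p = min(1.0, 2.0 / (len(nodes) - 1))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            pair = (nodes[order[i]], nodes[order[j]])
            if pair not in edges and rng.random() < p:
                edges.add(pair)
    return Dag(nodes, edges)


class _TabuEngine:
    """Index-based Tabu search state for one dataset.

    Works on integer node indices with a shared :class:`ScoreCache`; move
    deltas are stored in three (v, v) arrays and only entries whose child's
    parent set changed are recomputed after a step.
    """

    def __init__(self, nodes: tuple[str, ...], cache: ScoreCache, black: np.ndarray):
        self.nodes = nodes
        self.v = len(nodes)
        self.cache = cache
        self.black = black

    # -- graph state -------------------------------------------------------
    def load(self, dag: Dag) -> None:
        v = self.v
        self.adj = np.array(dag.adjacency(), dtype=bool)
        self.parents = [
            tuple(sorted(int(i) for i in np.nonzero(self.adj[:, j])[0]))
            for j in range(v)
        ]
        self.locals = np.array(
            [self.cache.local(j, self.parents[j]) for j in range(v)]
        )
        self.score = float(self.locals.sum())

    def dag(self) -> Dag:
        edges = [
            (self.nodes[i], self.nodes[j]) for i, j in zip(*np.nonzero(self.adj))
        ]
        return Dag(self.nodes, edges)

    def _reach_from(self, start: int, skip_edge: tuple[int, int] | None = None):
        """Set of nodes reachable from ``start`` (excluding start unless cyclic)."""
        seen = np.zeros(self.v, dtype=bool)
        stack = [start]
        while stack:
            i = stack.pop()
            for j in np.nonzero(self.adj[i])[0]:
                j = int(j)
                if skip_edge is not None and (i, j) == skip_edge:
                    continue
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        return seen

    def _closure(self) -> np.ndarray:
        """reach[i, j] true iff a directed path i -> ... -> j exists (i != j)."""
        reach = np.zeros((self.v, self.v), dtype=bool)
        for i in range(self.v):
            reach[i] = self._reach_from(i)
        return reach

    # -- deltas ------------------------------------------------------------
    def _refresh_deltas(self, changed) -> None:
        cache = self.cache
        for t in changed:
            base = self.locals[t]
            pset = set(self.parents[t])
            for u in range(self.v):
                if u == t:
                    continue
                if u in pset:
                    without = tuple(p for p in self.parents[t] if p != u)
                    self.d_del[u, t] = cache.local(t, without) - base
                    self.d_add[u, t] = np.nan
                else:
                    with_u = tuple(sorted(self.parents[t] + (u,)))
                    self.d_add[u, t] = cache.local(t, with_u) - base
                    self.d_del[u, t] = np.nan

    def _init_deltas(self) -> None:
        v = self.v
        self.d_add = np.full((v, v), np.nan)
        self.d_del = np.full((v, v), np.nan)
        self._refresh_deltas(range(v))

    # -- search ------------------------------------------------------------
    def search(self, start: Dag, tcfg: TabuConfig) -> tuple[Dag, float, int]:
        self.load(start)
        self._init_deltas()
        v = self.v
        best_adj = self.adj.copy()
        best_score = self.score
        tabu: list[tuple[str, int, int]] = []
        stagnation = 0
        limit = tcfg.stagnation_limit(v)
        steps = 0

        while stagnation < limit:
            reach = self._closure()
            # candidate scores stacked as (kind, u, v); -inf marks illegal/tabu
            cand = np.full((3, v, v), -np.inf)
            legal_add = (
                ~self.adj
                & ~self.adj.T
                & ~reach.T  # path v -> u forbids add(u, v)
                & ~self.black
                & ~np.eye(v, dtype=bool)
            )
            cand[0][legal_add] = self.d_add[legal_add]
            cand[1][self.adj] = self.d_del[self.adj]
            # reverse u->v legal iff edge exists, v->u not blacklisted and no
            # second path u -> ... -> v survives the deletion
            rev_cand = ~self.black.T & self.adj
            for u, w in zip(*np.nonzero(rev_cand)):
                u, w = int(u), int(w)
                if self._reach_from(u, skip_edge=(u, w))[w]:
                    continue
                cand[2, u, w] = self.d_del[u, w] + self.d_add_after_delete(u, w)
            for kind, u, w in tabu:
                cand[_KINDS.index(kind), u, w] = -np.inf

            flat = int(np.argmax(cand))
            if not np.isfinite(cand.flat[flat]):
                break  # no legal non-tabu move at all
            kind_i, u, w = np.unravel_index(flat, cand.shape)
            kind = _KINDS[kind_i]
            self._apply(kind, int(u), int(w))
            steps += 1
            tabu.append(_INVERSE[kind]((int(u), int(w))))
            if len(tabu) > tcfg.tabu_list_length:
                tabu.pop(0)
            if self.score > best_score + 1e-12:
                best_score = self.score
                best_adj = self.adj.copy()
                stagnation = 0
            else:
                stagnation += 1

        best = Dag(
            self.nodes,
            [(self.nodes[i], self.nodes[j]) for i, j in zip(*np.nonzero(best_adj))],
        )
        return best, best_score, steps

    def d_add_after_delete(self, u: int, w: int) -> float:
        """Delta of add(w, u) evaluated on the graph minus edge (u, w)."""
        with_w = tuple(sorted(self.parents[u] + (w,)))
        return self.cache.local(u, with_w) - self.locals[u]

    def _apply(self, kind: str, u: int, w: int) -> None:
        if kind == "add":
            self.adj[u, w] = True
            self._set_parents(w, tuple(sorted(self.parents[w] + (u,))))
            changed = (w,)
        elif kind == "delete":
            self.adj[u, w] = False
            self._set_parents(w, tuple(p for p in self.parents[w] if p != u))
            changed = (w,)
        else:  # reverse
            self.adj[u, w] = False
            self.adj[w, u] = True
            self._set_parents(w, tuple(p for p in self.parents[w] if p != u))
            self._set_parents(u, tuple(sorted(self.parents[u] + (w,))))
            changed = (u, w)
        self._refresh_deltas(changed)

    def _set_parents(self, t: int, parents: tuple[int, ...]) -> None:
        self.parents[t] = parents
        new_local = self.cache.local(t, parents)
        self.score += new_local - self.locals[t]
        self.locals[t] = new_local


_INVERSE = {
    "add": lambda uv: ("delete", uv[0], uv[1]),
    "delete": lambda uv: ("add", uv[0], uv[1]),
    "reverse": lambda uv: ("reverse", uv[1], uv[0]),
}


def _strip_blacklisted(dag: Dag, blacklist: Blacklist) -> Dag:
    edges = [e for e in dag.edges if e not in blacklist]
    if len(edges) == len(dag.edges):
        return dag
    return Dag(dag.nodes, edges)


def tabu_search(
    start: Dag,
    data: ExperimentDataset,
    blacklist: Blacklist = Blacklist(),
    cfg: ScoreConfig = ScoreConfig(),
    tcfg: TabuConfig = TabuConfig(),
    seed: int | None = None,
    cache: ScoreCache | None = None,
) -> Dag:
    """Tabu-search optimization of the masked BDeu score from one start DAG.

    Hill-climbs over add/delete/reverse moves; ties broken lexicographically
    by (kind, u, v) in node-list order; when no improving move exists, the
    best non-tabu worsening move is taken; the tabu list forbids undoing the
    last ``tabu_list_length`` moves; stops after ``max_stagnation`` steps
    without improving the best-so-far score and returns the best DAG
    visited.  Deterministic (``seed`` is accepted for interface symmetry but
    the search itself draws no random numbers).
    """
    del seed
    for arc in start.edges:
        if arc in blacklist:
            raise ValueError(f"start DAG contains blacklisted arc {arc}")
    if set(start.nodes) != set(data.variables):
        raise ValueError("start DAG nodes must match data variables")
    nodes = data.variables
    if tuple(start.nodes) != nodes:
        start = Dag(nodes, start.edges)
    if cache is None:
        cache = ScoreCache(data, cfg)
    engine = _TabuEngine(nodes, cache, blacklist.matrix(nodes))
    best, best_score, steps = engine.search(start, tcfg)
    logger.debug(
        "tabu finished: %d steps, score %.6f, %d arcs", steps, best_score, len(best.edges)
    )
    return best


def learn_ensemble(
    data: ExperimentDataset,
    cfg: ScoreConfig = ScoreConfig(),
    tcfg: TabuConfig = TabuConfig(),
) -> list[Dag]:
    """The per-experiment ensemble: n random restarts of Tabu search.

    The blacklist forbids every arc into a declared intervention target;
    random start DAGs have blacklisted arcs stripped (they are not
    re-connected afterwards).  Restart m uses start-DAG seed
    ``base_seed + m`` for m = 1..n.  Bitwise reproducible.
    """
    nodes = data.variables
    blacklist = Blacklist.into_targets(nodes, data.declared_targets)
    cache = ScoreCache(data, cfg)
    ensemble: list[Dag] = []
    for m in range(1, tcfg.ensemble_size + 1):
        start = create_random_connected_dag(nodes, seed=tcfg.base_seed + m)
        start = _strip_blacklisted(start, blacklist)
        result = tabu_search(
            start, data, blacklist=blacklist, cfg=cfg, tcfg=tcfg, cache=cache
        )
        ensemble.append(result)
        logger.info(
            "experiment %s restart %d/%d: %d arcs",
            data.experiment_id, m, tcfg.ensemble_size, len(result.edges),
        )
    return ensemble
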