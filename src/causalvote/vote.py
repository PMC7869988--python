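"""Arc-frequency voting and consensus-network construction.

Every experiment contributes an arc probability table: the empirical
frequency of each directed arc across that experiment's ensemble of
optimized DAGs (an arc present in 90 of 100 DAGs gets probability 0.90).
An arc is *invalid* in an experiment whose declared intervention targets
include the arc's head — the arc simply cannot be observed there, because
all incoming arcs of a declared target are removed from the search.
Averaging runs over valid experiments only; the consensus DAG keeps the
arcs whose averaged probability exceeds the threshold, inserted in
descending probability with cycle-making arcs skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Dag, ExperimentSuite
from .scoring import ScoreConfig
from .search import TabuConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ArcProbabilityTable",
    "VoteConfig",
    "ConsensusNetwork",
    "arc_frequencies",
    "average_networks",
    "threshold_dag",
    "learn_and_vote",
    "pooled_learn",
]


class ArcProbabilityTable:
    """Empirical arc probabilities over all ordered node pairs.

    ``prob[u, v]`` (indexed in node order) is the probability of the
    directed arc u -> v; ``valid[u, v]`` is false when v was a declared
    intervention target of the experiment the table came from.  The derived
    *strength* of an unordered pair is ``prob(u->v) + prob(v->u)`` and the
    *direction* of u -> v is its share of the strength.
    """

    __slots__ = ("nodes", "prob", "valid", "never_observable", "_index")

    def __init__(
        self,
        nodes: Sequence[str],
        prob: np.ndarray,
        valid: np.ndarray | None = None,
        never_observable: frozenset = frozenset(),
    ):
        self.nodes = tuple(nodes)
        v = len(self.nodes)
        prob = np.array(prob, dtype=float)
        if prob.shape != (v, v):
            raise ValueError("prob must be a (v, v) matrix")
        if (prob < 0).any() or (prob > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        np.fill_diagonal(prob, 0.0)
        self.prob = prob
        if valid is None:
            valid = np.ones((v, v), dtype=bool)
        else:
            valid = np.array(valid, dtype=bool)
            if valid.shape != (v, v):
                raise ValueError("valid must be a (v, v) matrix")
        np.fill_diagonal(valid, False)
        self.valid = valid
        self.never_observable = frozenset(never_observable)
        self._index = {n: i for i, n in enumerate(self.nodes)}
        self.prob.setflags(write=False)
        self.valid.setflags(write=False)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ValueError(f"unknown node {name!r}") from None

    def probability(self, u: str, v: str) -> float:
        return float(self.prob[self.index(u), self.index(v)])

    def is_valid(self, u: str, v: str) -> bool:
        return bool(self.valid[self.index(u), self.index(v)])

    def strength(self, u: str, v: str) -> float:
        i, j = self.index(u), self.index(v)
        return float(self.prob[i, j] + self.prob[j, i])

    def direction(self, u: str, v: str) -> float:
        """Share of the pair's strength carried by u -> v (nan when strength 0)."""
        s = self.strength(u, v)
        if s == 0.0:
            return float("nan")
        return self.probability(u, v) / s

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.nodes):
            for j, v in enumerate(self.nodes):
                if i == j:
                    continue
                rows.append(
                    {
                        "from": u,
                        "to": v,
                        "prob": self.prob[i, j],
                        "valid": bool(self.valid[i, j]),
                        "strength": self.prob[i, j] + self.prob[j, i],
                        "direction": self.direction(u, v),
                    }
                )
        return pd.DataFrame(rows, columns=["from", "to", "prob", "valid", "strength", "direction"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, nodes: Sequence[str] | None = None) -> "ArcProbabilityTable":
        if nodes is None:
            seen: dict[str, None] = {}
            for col in ("from", "to"):
                for n in frame[col].astype(str):
                    seen.setdefault(n)
            nodes = tuple(seen)
        nodes = tuple(nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        v = len(nodes)
        prob = np.zeros((v, v))
        valid = np.ones((v, v), dtype=bool)
        for _, row in frame.iterrows():
            i, j = idx[str(row["from"])], idx[str(row["to"])]
            prob[i, j] = float(row["prob"])
            if "valid" in frame.columns:
                valid[i, j] = bool(row["valid"])
        return cls(nodes, prob, valid)


@dataclass(frozen=True)
class VoteConfig:
    """Consensus construction parameters.

    threshold
        An arc enters the consensus DAG only when its averaged probability
        is *strictly* greater than this (default 0.5, where the method
        performs best).
    mode
        ``"average"`` averages raw arc frequencies over valid experiments;
        ``"majority"`` first binarizes each experiment's vote at 0.5 and
        averages the 0/1 votes instead.
    """

    threshold: float = 0.5
    mode: str = "average"

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.mode not in ("average", "majority"):
            raise ValueError(f"unknown vote mode {self.mode!r}")


@dataclass
class ConsensusNetwork:
    """The final consensus DAG with all voting intermediates retained."""

    dag: Dag
    averaged_table: ArcProbabilityTable
    per_experiment_tables: list[ArcProbabilityTable] = field(default_factory=list)
    skipped_arcs: list[tuple[str, str, float, str]] = field(default_factory=list)
    ensembles: list[list[Dag]] | None = None


def arc_frequencies(
    ensemble: Sequence[Dag], declared_targets: Iterable[str] = ()
) -> ArcProbabilityTable:
    """Directed empirical arc frequencies across an ensemble of DAGs."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    nodes = ensemble[0].nodes
    for d in ensemble[1:]:
        if d.nodes != nodes:
            raise ValueError("ensemble DAGs have heterogeneous node sets")
    counts = np.zeros((len(nodes), len(nodes)))
    for d in ensemble:
        counts += d.adjacency()
    prob = counts / len(ensemble)
    valid = np.ones((len(nodes), len(nodes)), dtype=bool)
    idx = {n: i for i, n in enumerate(nodes)}
    for t in declared_targets:
        if t not in idx:
            raise ValueError(f"declared target {t!r} is not a node")
        valid[:, idx[t]] = False
    return ArcProbabilityTable(nodes, prob, valid)


def average_networks(
    tables: Sequence[ArcProbabilityTable], mode: str = "average"
) -> ArcProbabilityTable:
    """Validity-aware arithmetic mean of per-experiment arc tables.

    Each ordered pair is averaged over the experiments in which it is valid
    (head not intervened).  Pairs valid in no experiment get probability 0
    and are flagged *never-observable*.  In ``"majority"`` mode each
    experiment contributes a 0/1 vote (its probability > 0.5) instead of
    its raw frequency.  The output's valid flags are all true.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one table")
    nodes = tables[0].nodes
    for t in tables[1:]:
        if t.nodes != nodes:
            raise ValueError("tables have mismatching node sets")
    v = len(nodes)
    num = np.zeros((v, v))
    den = np.zeros((v, v))
    for t in tables:
        contrib = (t.prob > 0.5).astype(float) if mode == "majority" else t.prob
        num += np.where(t.valid, contrib, 0.0)
        den += t.valid
    with np.errstate(invalid="ignore"):
        avg = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    never = frozenset(
        (nodes[i], nodes[j])
        for i in range(v)
        for j in range(v)
        if i != j and den[i, j] == 0
    )
    if never:
        logger.warning("%d ordered pairs are never observable; probability set to 0", len(never))
    return ArcProbabilityTable(nodes, avg, never_observable=never)


def _threshold(
    avg: ArcProbabilityTable, vcfg: VoteConfig
) -> tuple[Dag, list[tuple[str, str, float, str]]]:
    nodes = avg.nodes
    v = len(nodes)
    candidates: list[tuple[float, int, int]] = []
    skipped: list[tuple[str, str, float, str]] = []
    for i in range(v):
        for j in range(i + 1, v):
            p_ij, p_ji = avg.prob[i, j], avg.prob[j, i]
            fwd = p_ij > vcfg.threshold
            bwd = p_ji > vcfg.threshold
            if fwd and bwd:
                if p_ij == p_ji:
                    logger.warning(
                        "exact orientation tie for pair (%s, %s) at p=%.3f; dropping both",
                        nodes[i], nodes[j], p_ij,
                    )
                    skipped.append((nodes[i], nodes[j], p_ij, "orientation-tie"))
                    skipped.append((nodes[j], nodes[i], p_ji, "orientation-tie"))
                    continue
                if p_ij > p_ji:
                    candidates.append((p_ij, i, j))
                    skipped.append((nodes[j], nodes[i], p_ji, "weaker-orientation"))
                else:
                    candidates.append((p_ji, j, i))
                    skipped.append((nodes[i], nodes[j], p_ij, "weaker-orientation"))
            elif fwd:
                candidates.append((p_ij, i, j))
            elif bwd:
                candidates.append((p_ji, j, i))
    # descending probability; ties by lexicographic pair in node order
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    dag = Dag(nodes)
    for p, i, j in candidates:
        try:
            dag = dag.with_edge(nodes[i], nodes[j])
        except Exception:
            logger.warning(
                "skipping arc %s -> %s (p=%.3f): would create a cycle",
                nodes[i], nodes[j], p,
            )
            skipped.append((nodes[i], nodes[j], p, "cycle"))
    return dag, skipped


def threshold_dag(avg: ArcProbabilityTable, vcfg: VoteConfig = VoteConfig()) -> Dag:
    """Threshold an averaged table into an acyclic consensus DAG.

    Candidate arcs have probability strictly above the threshold; when both
    orientations of a pair qualify only the stronger is kept (an exact tie
    drops both); candidates are inserted in descending probability (ties by
    node order) and any arc that would close a cycle is skipped and logged.
    """
    return _threshold(avg, vcfg)[0]


def learn_and_vote(
    suite: ExperimentSuite,
    cfg: ScoreConfig = ScoreConfig(),
    tcfg: TabuConfig = TabuConfig(),
    vcfg: VoteConfig = VoteConfig(),
    keep_ensembles: bool = False,
) -> ConsensusNetwork:
    """Full voting pipeline over a multi-experiment suite.

    Thin functional wrapper around :class:`causalvote.estimators.LearnAndVote`.
    """
    from .estimators import LearnAndVote

    est = LearnAndVote.from_configs(cfg, tcfg, vcfg, keep_ensembles=keep_ensembles)
    return est.fit(suite).consensus_


def pooled_learn(
    suite: ExperimentSuite,
    cfg: ScoreConfig = ScoreConfig(),
    tcfg: TabuConfig = TabuConfig(),
    vcfg: VoteConfig = VoteConfig(),
    keep_ensembles: bool = False,
) -> ConsensusNetwork:
    """Pooled-data baseline: concatenate all experiments, then learn once.

    Thin functional wrapper around :class:`causalvote.estimators.PooledLearner`.
    """
    from .estimators import PooledLearner

    est = PooledLearner.from_configs(cfg, tcfg, vcfg, keep_ensembles=keep_ensembles)
    return est.fit(suite).consensus_
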