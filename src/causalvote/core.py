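"""Shared graph and dataset types.

Conventions used throughout the package:

* Variable names are case-sensitive strings; the node-list order given at
  construction time is the canonical tie-breaking order everywhere
  (sampling, move enumeration, reporting).
* Categorical levels are strings, never integers, so that datasets and
  domains cannot be silently coerced into each other.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CycleError",
    "Dag",
    "CategoricalDomain",
    "ExperimentDataset",
    "ExperimentSuite",
    "has_path",
    "topological_order",
    "read_dag",
    "write_dag",
    "dag_to_dot",
]


class CycleError(ValueError):
    """Raised when an edge set contains, or a mutation would create, a cycle."""


class Dag:
    """An immutable directed acyclic graph over named nodes.

    Parameters
    ----------
    nodes
        Ordered variable names.  The order is preserved and used as the
        canonical tie-breaking order.
    edges
        Iterable of ``(parent, child)`` pairs.

    Raises
    ------
    CycleError
        If the edge set contains a directed cycle (one cycle is named).
    ValueError
        On self-loops, duplicate nodes or unknown node names.
    """

    __slots__ = ("_nodes", "_index", "_edges", "_adj")

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        nodes = tuple(str(n) for n in nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        index = {n: i for i, n in enumerate(nodes)}
        v = len(nodes)
        adj = np.zeros((v, v), dtype=bool)
        for u, w in edges:
            for name in (u, w):
                if name not in index:
                    raise ValueError(f"unknown node {name!r}")
            if u == w:
                raise ValueError(f"self-loop on {u!r}")
            adj[index[u], index[w]] = True
        self._nodes = nodes
        self._index = index
        self._adj = adj
        self._adj.setflags(write=False)
        self._edges = frozenset(
            (nodes[i], nodes[j]) for i, j in zip(*np.nonzero(adj))
        )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = self.to_networkx()
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise CycleError(f"edge set contains a cycle: {path}")

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ValueError(f"unknown node {name!r}") from None

    def adjacency(self) -> np.ndarray:
        """Boolean parent->child adjacency matrix in node order (read-only)."""
        return self._adj

    def has_edge(self, u: str, v: str) -> bool:
        return self._adj[self.index(u), self.index(v)]

    def parents(self, v: str) -> tuple[str, ...]:
        j = self.index(v)
        return tuple(self._nodes[i] for i in np.nonzero(self._adj[:, j])[0])

    def children(self, u: str) -> tuple[str, ...]:
        i = self.index(u)
        return tuple(self._nodes[j] for j in np.nonzero(self._adj[i])[0])

    def leaves(self) -> tuple[str, ...]:
        return tuple(n for n in self._nodes if not self.children(n))

    # -- mutation (returns new graphs; acyclicity re-checked) --------------
    def with_edge(self, u: str, v: str) -> "Dag":
        if self.has_edge(u, v):
            raise ValueError(f"edge {u!r}->{v!r} already present")
        if has_path(self, v, u):
            raise CycleError(f"adding {u!r}->{v!r} would create a cycle")
        return Dag(self._nodes, self._edges | {(u, v)})

    def without_edge(self, u: str, v: str) -> "Dag":
        if not self.has_edge(u, v):
            raise ValueError(f"edge {u!r}->{v!r} not present")
        return Dag(self._nodes, self._edges - {(u, v)})

    def with_reversed(self, u: str, v: str) -> "Dag":
        return self.without_edge(u, v).with_edge(v, u)

    # -- conversions -------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    # -- dunder ------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Dag)
            and self._nodes == other._nodes
            and self._edges == other._edges
        )

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dag(nodes={list(self._nodes)}, edges={sorted(self._edges)})"


def has_path(dag: Dag, src: str, dst: str) -> bool:
    """True iff a directed path ``src -> ... -> dst`` exists (length 0 counts)."""
    s, t = dag.index(src), dag.index(dst)
    if s == t:
        return True
    adj = dag.adjacency()
    seen = np.zeros(dag.n_nodes, dtype=bool)
    stack = [s]
    seen[s] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i])[0]:
            if j == t:
                return True
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return False


def topological_order(dag: Dag) -> list[str]:
    """Ancestral node order; ties broken by node-list order (deterministic)."""
    return list(
        nx.lexicographical_topological_sort(dag.to_networkx(), key=dag.index)
    )


# ---------------------------------------------------------------------------
# DAG file format: "# nodes: a,b,c" header + one "parent<TAB>child" per line.
# ---------------------------------------------------------------------------

def write_dag(dag: Dag, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# nodes: " + ",".join(dag.nodes) + "\n")
        for u, v in sorted(dag.edges, key=lambda e: (dag.index(e[0]), dag.index(e[1]))):
            fh.write(f"{u}\t{v}\n")


def read_dag(path) -> Dag:
    nodes: tuple[str, ...] | None = None
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("nodes:"):
                    names = body[len("nodes:"):].strip()
                    nodes = tuple(n.strip() for n in names.split(",") if n.strip())
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'parent<TAB>child'")
            edges.append((parts[0], parts[1]))
    if nodes is None:
        seen: dict[str, None] = {}
        for u, v in edges:
            seen.setdefault(u)
            seen.setdefault(v)
        nodes = tuple(seen)
    return Dag(nodes, edges)


def enumerate_dags(nodes: Sequence[str]):
    """Yield every DAG over ``nodes`` (exhaustive; use only for tiny v).

    There are 25 DAGs on 3 labelled nodes, 543 on 4.
    """
    from itertools import combinations, product

    nodes = tuple(nodes)
    pairs = list(combinations(range(len(nodes)), 2))
    # each unordered pair is absent, forward, or backward
    for states in product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (i, j), s in zip(pairs, states):
            if s == 1:
                edges.append((nodes[i], nodes[j]))
            elif s == 2:
                edges.append((nodes[j], nodes[i]))
        try:
            yield Dag(nodes, edges)
        except CycleError:
            continue


def dag_to_dot(dag: Dag, name: str = "G") -> str:
    lines = [f"digraph {name} {{"]
    for n in dag.nodes:
        lines.append(f'  "{n}";')
    for u, v in sorted(dag.edges, key=lambda e: (dag.index(e[0]), dag.index(e[1]))):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Categorical domains and datasets
# ---------------------------------------------------------------------------

class CategoricalDomain:
    """Per-variable ordered level labels.

    The level order is fixed and defines count-vector indexing in the score
    and the row indexing of conditional probability tables.  Every variable
    must have at least two levels.
    """

    __slots__ = ("_levels", "_variables", "_index")

    def __init__(self, levels: Mapping[str, Sequence[str]]):
        self._levels: dict[str, tuple[str, ...]] = {}
        for var, lv in levels.items():
            lv = tuple(str(x) for x in lv)
            if len(set(lv)) != len(lv):
                raise ValueError(f"duplicate levels for variable {var!r}")
            if len(lv) < 2:
                raise ValueError(f"variable {var!r} needs >= 2 levels, got {len(lv)}")
            self._levels[str(var)] = lv
        self._variables = tuple(self._levels)
        self._index = {v: i for i, v in enumerate(self._variables)}

    @property
    def variables(self) -> tuple[str, ...]:
        return self._variables

    def index(self, var: str) -> int:
        try:
            return self._index[var]
        except KeyError:
            raise ValueError(f"unknown variable {var!r}") from None

    def levels(self, var: str) -> tuple[str, ...]:
        return self._levels[self._variables[self.index(var)]]

    def cardinality(self, var: str) -> int:
        return len(self.levels(var))

    def cardinalities(self) -> np.ndarray:
        return np.array([len(self._levels[v]) for v in self._variables], dtype=np.int64)

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        """Encode a label table into integer level codes (samples x variables).

        Raises a ``ValueError`` naming the first offending sample and variable
        when an unknown level is encountered.
        """
        missing = [v for v in self._variables if v not in table.columns]
        if missing:
            raise ValueError(f"dataset is missing variables {missing}")
        n = len(table)
        codes = np.empty((n, len(self._variables)), dtype=np.int16)
        for j, var in enumerate(self._variables):
            lookup = {lv: k for k, lv in enumerate(self._levels[var])}
            col = table[var].astype(str).to_numpy()
            for i, cell in enumerate(col):
                try:
                    codes[i, j] = lookup[cell]
                except KeyError:
                    raise ValueError(
                        f"unknown level {cell!r} of variable {var!r} in sample {i}"
                    ) from None
        return codes

    def decode(self, codes: np.ndarray) -> pd.DataFrame:
        data = {
            var: [self._levels[var][c] for c in codes[:, j]]
            for j, var in enumerate(self._variables)
        }
        return pd.DataFrame(data, columns=list(self._variables))

    @classmethod
    def infer(cls, tables: Iterable[pd.DataFrame]) -> "CategoricalDomain":
        """Union of observed levels across all tables, sorted lexicographically."""
        observed: dict[str, set[str]] = {}
        columns: list[str] = []
        for tab in tables:
            for col in tab.columns:
                if col not in observed:
                    observed[col] = set()
                    columns.append(col)
                observed[col].update(str(x) for x in tab[col])
        return cls({c: tuple(sorted(observed[c])) for c in columns})

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CategoricalDomain) and self._levels == other._levels

    def __hash__(self) -> int:
        return hash(tuple((v, lv) for v, lv in self._levels.items()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"CategoricalDomain({self._levels!r})"


class ExperimentDataset:
    """One experiment's categorical sample table plus its intervention mask.

    ``mask[m, v]`` is true when variable ``v`` was externally set in sample
    ``m`` and must therefore be excluded from that variable's likelihood
    contribution.  ``declared_targets`` are the experiment-level intervention
    targets known to the learner; their mask columns are forced to true.
    The mask may mark additional per-sample entries (used when experiments
    are concatenated for the pooled baseline).
    """

    __slots__ = ("experiment_id", "domain", "codes", "mask", "declared_targets")

    def __init__(
        self,
        experiment_id: str,
        table: pd.DataFrame | np.ndarray,
        domain: CategoricalDomain,
        declared_targets: Iterable[str] = (),
        mask: np.ndarray | None = None,
    ):
        self.experiment_id = str(experiment_id)
        self.domain = domain
        if isinstance(table, pd.DataFrame):
            if len(table) == 0:
                raise ValueError(f"experiment {experiment_id!r}: empty dataset")
            codes = domain.encode(table)
        else:
            codes = np.asarray(table, dtype=np.int16)
            if codes.ndim != 2 or codes.shape[1] != len(domain.variables):
                raise ValueError("codes must be a samples x variables array")
            if codes.shape[0] == 0:
                raise ValueError(f"experiment {experiment_id!r}: empty dataset")
            cards = domain.cardinalities()
            if (codes < 0).any() or (codes >= cards[None, :]).any():
                i, j = np.argwhere((codes < 0) | (codes >= cards[None, :]))[0]
                raise ValueError(
                    f"invalid level code for variable {domain.variables[j]!r} "
                    f"in sample {i}"
                )
        self.codes = codes
        self.codes.setflags(write=False)
        targets = frozenset(str(t) for t in declared_targets)
        for t in targets:
            domain.index(t)  # raises on unknown variable
        self.declared_targets = targets
        if mask is None:
            mask = np.zeros(codes.shape, dtype=bool)
        else:
            mask = np.array(mask, dtype=bool)
            if mask.shape != codes.shape:
                raise ValueError("mask shape must match table shape")
        for t in targets:
            mask[:, domain.index(t)] = True
        self.mask = mask
        self.mask.setflags(write=False)

    @property
    def variables(self) -> tuple[str, ...]:
        return self.domain.variables

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def table(self) -> pd.DataFrame:
        """Label-valued view of the sample table."""
        return self.domain.decode(self.codes)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExperimentDataset({self.experiment_id!r}, n={self.n_samples}, "
            f"targets={sorted(self.declared_targets)})"
        )


class ExperimentSuite:
    """An ordered collection of experiments over one shared domain."""

    __slots__ = ("experiments", "domain")

    def __init__(self, experiments: Sequence[ExperimentDataset]):
        experiments = list(experiments)
        if not experiments:
            raise ValueError("suite needs at least one experiment")
        domain = experiments[0].domain
        for e in experiments[1:]:
            if e.domain != domain:
                raise ValueError(
                    f"experiment {e.experiment_id!r} has a different domain"
                )
        ids = [e.experiment_id for e in experiments]
        if len(set(ids)) != len(ids):
            raise ValueError("experiment ids must be unique")
        sizes = {e.n_samples for e in experiments}
        if len(sizes) > 1:
            logger.warning(
                "unequal sample sizes across experiments (%s); averaging will be "
                "biased towards larger experiments",
                sorted(sizes),
            )
        self.experiments = experiments
        self.domain = domain

    @property
    def k(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self) -> int:
        return len(self.experiments)

    def __getitem__(self, i: int) -> ExperimentDataset:
        return self.experiments[i]

    def concatenate(self, experiment_id: str = "pooled") -> ExperimentDataset:
        """Row-wise concatenation of all experiments into one dataset.

        The per-sample mask is inherited row-wise; the declared targets of
        the pooled dataset are the variables that are masked in *every*
        sample (only those remain unscorable throughout).
        """
        codes = np.vstack([e.codes for e in self.experiments])
        mask = np.vstack([e.mask for e in self.experiments])
        always = mask.all(axis=0)
        targets = [v for j, v in enumerate(self.domain.variables) if always[j]]
        return ExperimentDataset(
            experiment_id, codes, self.domain, declared_targets=targets, mask=mask
        )
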