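"""Synthetic-data engine: discrete Bayesian networks, mutilation, suites.

The generator emulates the experimental protocol the learner is designed
for: forward sampling from a discrete ground-truth network (1,000 samples
per experiment by default), perfect interventions that clamp a target to a
fixed level (point-mass CPT, incoming arcs removed), and *fat-hand*
interventions that additionally clamp one or more children of the declared
target without telling the learner.  Suites default to the 2 observational
: 7 interventional shape with equal sample sizes, and intervention targets
are drawn from non-leaf nodes only (leaves cascade no causal information).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CategoricalDomain, Dag, ExperimentDataset, ExperimentSuite, topological_order

__all__ = [
    "DiscreteBayesNet",
    "InterventionPlan",
    "forward_sample",
    "mutilate",
    "generate_suite",
    "pooling_trap_fixture",
    "pooling_trap_net",
    "discretize",
    "chain_net",
    "fork_net",
    "collider_net",
    "asia_like_net",
    "bn_to_json",
    "bn_from_json",
]


class DiscreteBayesNet:
    """A DAG plus one conditional probability table per node.

    Each CPT is a ``(q, r)`` array: one row per joint parent configuration
    (parents in node-index order, last parent varying fastest — the same
    convention the score's count tables use) and one column per level.
    Rows must sum to 1 within 1e-9.
    """

    __slots__ = ("dag", "domain", "cpts")

    def __init__(
        self,
        dag: Dag,
        domain: CategoricalDomain,
        cpts: Mapping[str, np.ndarray],
    ):
        if tuple(dag.nodes) != tuple(domain.variables):
            raise ValueError("dag nodes and domain variables must match in order")
        self.dag = dag
        self.domain = domain
        checked: dict[str, np.ndarray] = {}
        for node in dag.nodes:
            if node not in cpts:
                raise ValueError(f"missing CPT for node {node!r}")
            table = np.asarray(cpts[node], dtype=float)
            r = domain.cardinality(node)
            q = 1
            for p in self._ordered_parents(node):
                q *= domain.cardinality(p)
            if table.shape != (q, r):
                raise ValueError(
                    f"CPT for node {node!r} must have shape ({q}, {r}), got {table.shape}"
                )
            sums = table.sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > 1e-9)[0]
            if bad.size:
                raise ValueError(
                    f"CPT row {int(bad[0])} of node {node!r} sums to {sums[bad[0]]!r}, not 1"
                )
            if (table < 0).any():
                raise ValueError(f"CPT of node {node!r} has negative entries")
            checked[node] = table
        self.cpts = checked

    def _ordered_parents(self, node: str) -> tuple[str, ...]:
        """Parents sorted by node index (defines CPT row indexing)."""
        return tuple(
            sorted(self.dag.parents(node), key=self.dag.index)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"DiscreteBayesNet({self.dag!r})"


@dataclass(frozen=True)
class InterventionPlan:
    """One experiment's intervention: a declared target plus hidden off-targets.

    ``fat_hand`` maps child nodes of the primary target to the levels they
    are secretly clamped to; the learner is told about ``primary_target``
    only.
    """

    primary_target: str
    clamp_value: str
    fat_hand: Mapping[str, str] = field(default_factory=dict)

    def all_clamped(self) -> dict[str, str]:
        clamped = {self.primary_target: self.clamp_value}
        for node, level in self.fat_hand.items():
            if node in clamped:
                raise ValueError(f"node {node!r} clamped twice")
            clamped[node] = level
        return clamped


def forward_sample(
    bn: DiscreteBayesNet,
    n: int,
    seed: int,
    experiment_id: str = "obs",
    declared_targets: Sequence[str] = (),
) -> ExperimentDataset:
    """Draw ``n`` joint samples in topological order (mask all false unless
    declared targets are given)."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    dom = bn.domain
    cards = dom.cardinalities()
    codes = np.zeros((n, len(dom.variables)), dtype=np.int16)
    for node in topological_order(bn.dag):
        j = dom.index(node)
        parents = bn._ordered_parents(node)
        cfg = np.zeros(n, dtype=np.int64)
        for p in parents:
            cfg = cfg * int(cards[dom.index(p)]) + codes[:, dom.index(p)]
        cum = np.cumsum(bn.cpts[node], axis=1)
        u = rng.random(n)
        codes[:, j] = (u[:, None] > cum[cfg]).sum(axis=1)
    return ExperimentDataset(
        experiment_id, codes, dom, declared_targets=declared_targets
    )


def mutilate(bn: DiscreteBayesNet, plan: InterventionPlan) -> DiscreteBayesNet:
    """Return a copy of ``bn`` with the plan's nodes clamped.

    Clamped nodes lose their incoming arcs and get a point-mass CPT on the
    clamp level; arcs *out of* clamped nodes survive, so children still
    condition on the clamped value.  The original network is untouched.
    """
    clamped = plan.all_clamped()
    dom = bn.domain
    for child in plan.fat_hand:
        if child not in bn.dag.children(plan.primary_target):
            raise ValueError(
                f"fat-hand node {child!r} is not a child of {plan.primary_target!r}"
            )
    for node, level in clamped.items():
        if level not in dom.levels(node):
            raise ValueError(f"{level!r} is not a level of {node!r}")
    edges = [e for e in bn.dag.edges if e[1] not in clamped]
    dag = Dag(bn.dag.nodes, edges)
    cpts = dict(bn.cpts)
    for node, level in clamped.items():
        row = np.zeros((1, dom.cardinality(node)))
        row[0, dom.levels(node).index(level)] = 1.0
        cpts[node] = row
    return DiscreteBayesNet(dag, dom, cpts)


def generate_suite(
    bn: DiscreteBayesNet,
    k_obs: int = 2,
    k_int: int = 7,
    n_per_exp: int = 1000,
    fat_hand_rate: float = 1.0,
    seed: int = 0,
    n_fat_children: int = 1,
) -> tuple[ExperimentSuite, Dag, list[InterventionPlan | None]]:
    """Generate a multi-experiment suite from one ground-truth network.

    ``k_obs`` observational experiments are followed by ``k_int``
    interventional ones.  Each intervention draws its primary target
    uniformly from the non-leaf nodes (without replacement until exhausted,
    then with replacement), clamps it to a uniformly drawn level and, with
    probability ``fat_hand_rate``, also clamps ``n_fat_children`` uniformly
    chosen children to uniformly drawn levels.  Only primary targets are
    declared to the learner; fat-hand children appear in the returned
    hidden plans but never in ``declared_targets`` or the mask.

    Returns ``(suite, ground_truth_dag, plans)`` with one plan entry per
    experiment (``None`` for observational ones).
    """
    if k_obs < 0 or k_int < 0 or k_obs + k_int < 1:
        raise ValueError("need a positive number of experiments")
    if not 0.0 <= fat_hand_rate <= 1.0:
        raise ValueError("fat_hand_rate must lie in [0, 1]")
    non_leaf = [n for n in bn.dag.nodes if bn.dag.children(n)]
    if k_int >= 1 and not non_leaf:
        raise ValueError("network has no non-leaf node to intervene on")
    rng = np.random.default_rng(seed)
    dom = bn.domain
    experiments: list[ExperimentDataset] = []
    plans: list[InterventionPlan | None] = []
    for i in range(k_obs):
        experiments.append(
            forward_sample(
                bn, n_per_exp, seed=int(rng.integers(2**31)), experiment_id=f"obs{i + 1}"
            )
        )
        plans.append(None)
    pool: list[str] = []
    for i in range(k_int):
        if not pool:
            pool = list(non_leaf)
        target = pool.pop(int(rng.integers(len(pool))))
        clamp = dom.levels(target)[int(rng.integers(dom.cardinality(target)))]
        fat: dict[str, str] = {}
        if rng.random() < fat_hand_rate:
            children = [c for c in bn.dag.children(target)]
            take = min(n_fat_children, len(children))
            for idx in rng.choice(len(children), size=take, replace=False):
                child = children[int(idx)]
                fat[child] = dom.levels(child)[int(rng.integers(dom.cardinality(child)))]
        plan = InterventionPlan(target, clamp, fat)
        mutilated = mutilate(bn, plan)
        experiments.append(
            forward_sample(
                mutilated,
                n_per_exp,
                seed=int(rng.integers(2**31)),
                experiment_id=f"int{i + 1}",
                declared_targets=[target],
            )
        )
        plans.append(plan)
    return ExperimentSuite(experiments), bn.dag, plans


# ---------------------------------------------------------------------------
# Fixture networks (CPT values are this package's own, chosen to give
# moderate, learnable effects at the default 1,000 samples per experiment)
# ---------------------------------------------------------------------------

def _binary_domain(nodes: Sequence[str]) -> CategoricalDomain:
    return CategoricalDomain({n: ("0", "1") for n in nodes})


def chain_net(p_follow: float = 0.9) -> DiscreteBayesNet:
    """X -> Y -> Z where each child copies its parent with prob ``p_follow``."""
    nodes = ("X", "Y", "Z")
    dag = Dag(nodes, [("X", "Y"), ("Y", "Z")])
    follow = np.array([[p_follow, 1 - p_follow], [1 - p_follow, p_follow]])
    cpts = {"X": np.array([[0.5, 0.5]]), "Y": follow, "Z": follow}
    return DiscreteBayesNet(dag, _binary_domain(nodes), cpts)


def fork_net(p_follow: float = 0.9) -> DiscreteBayesNet:
    """Y <- X -> Z: one cause with two noisy copies."""
    nodes = ("X", "Y", "Z")
    dag = Dag(nodes, [("X", "Y"), ("X", "Z")])
    follow = np.array([[p_follow, 1 - p_follow], [1 - p_follow, p_follow]])
    cpts = {"X": np.array([[0.5, 0.5]]), "Y": follow, "Z": follow}
    return DiscreteBayesNet(dag, _binary_domain(nodes), cpts)


def collider_net() -> DiscreteBayesNet:
    """X -> Z <- Y with independent fair-coin parents."""
    nodes = ("X", "Y", "Z")
    dag = Dag(nodes, [("X", "Z"), ("Y", "Z")])
    cpts = {
        "X": np.array([[0.5, 0.5]]),
        "Y": np.array([[0.5, 0.5]]),
        # rows: (X,Y) = (0,0), (0,1), (1,0), (1,1)
        "Z": np.array([[0.95, 0.05], [0.2, 0.8], [0.2, 0.8], [0.05, 0.95]]),
    }
    return DiscreteBayesNet(dag, _binary_domain(nodes), cpts)


def pooling_trap_net() -> DiscreteBayesNet:
    """Ground truth for the pooling-error scenario: Vi -> Vk <- Vj.

    Vi and Vj are marginally independent fair coins; Vk responds strongly
    to each parent.
    """
    nodes = ("Vi", "Vj", "Vk")
    dag = Dag(nodes, [("Vi", "Vk"), ("Vj", "Vk")])
    cpts = {
        "Vi": np.array([[0.5, 0.5]]),
        "Vj": np.array([[0.5, 0.5]]),
        # rows: (Vi,Vj) = (0,0), (0,1), (1,0), (1,1)
        "Vk": np.array([[0.95, 0.05], [0.2, 0.8], [0.2, 0.8], [0.05, 0.95]]),
    }
    return DiscreteBayesNet(dag, _binary_domain(nodes), cpts)


def asia_like_net() -> DiscreteBayesNet:
    """An 8-node lung-disease-style network with this package's own CPTs.

    Structure: visit -> tub; smoke -> lung, bronc; tub, lung -> either;
    either -> xray; either, bronc -> dysp.  Leaves are xray and dysp.  The
    classic deterministic or-gate is replaced by a noisy one (deterministic
    nodes are degenerate for Dirichlet-multinomial scoring) and marginals
    are kept away from extremes so effects are learnable at n=1000.
    """
    nodes = ("visit", "tub", "smoke", "lung", "bronc", "either", "xray", "dysp")
    dag = Dag(
        nodes,
        [
            ("visit", "tub"),
            ("smoke", "lung"),
            ("smoke", "bronc"),
            ("tub", "either"),
            ("lung", "either"),
            ("either", "xray"),
            ("either", "dysp"),
            ("bronc", "dysp"),
        ],
    )
    cpts = {
        "visit": np.array([[0.7, 0.3]]),
        "tub": np.array([[0.92, 0.08], [0.6, 0.4]]),
        "smoke": np.array([[0.5, 0.5]]),
        "lung": np.array([[0.95, 0.05], [0.65, 0.35]]),
        "bronc": np.array([[0.75, 0.25], [0.4, 0.6]]),
        # rows: (tub, lung) = (0,0), (0,1), (1,0), (1,1)
        "either": np.array([[0.98, 0.02], [0.1, 0.9], [0.1, 0.9], [0.02, 0.98]]),
        "xray": np.array([[0.92, 0.08], [0.05, 0.95]]),
        # rows: (bronc, either) = (0,0), (0,1), (1,0), (1,1)
        "dysp": np.array([[0.9, 0.1], [0.25, 0.75], [0.3, 0.7], [0.05, 0.95]]),
    }
    return DiscreteBayesNet(dag, _binary_domain(nodes), cpts)


def pooling_trap_fixture(seed: int = 0) -> tuple[ExperimentSuite, Dag]:
    """Three-experiment scenario reproducing the two pooling error modes.

    Ground truth: the collider Vi -> Vk <- Vj with Vi and Vj independent.

    * experiment ``obs``: plain observational samples;
    * experiment ``intA``: an uncertain intervention clamps Vi *and* Vj to
      perfectly correlated random values (Vi is drawn fair, Vj is set equal
      to it); only Vi is declared — Vj is the hidden off-target;
    * experiment ``intB``: a declared perfect intervention clamps Vk.

    1,000 samples per experiment.  Pooling these experiments makes Vi and
    Vj look dependent (they agree in every intA sample) while the voting
    route confines the artifact to intA's table.
    """
    rng = np.random.default_rng(seed)
    truth = pooling_trap_net()
    dom = truth.domain
    obs = forward_sample(
        truth, 1000, seed=int(rng.integers(2**31)), experiment_id="obs"
    )
    # experiment A: correlated clamp of (Vi, Vj), modelled as a mutilated
    # generative network where Vj deterministically copies the forced Vi
    nodes = truth.dag.nodes
    dag_a = Dag(nodes, [("Vi", "Vj"), ("Vi", "Vk"), ("Vj", "Vk")])
    cpts_a = {
        "Vi": np.array([[0.5, 0.5]]),
        "Vj": np.array([[1.0, 0.0], [0.0, 1.0]]),
        "Vk": truth.cpts["Vk"],
    }
    net_a = DiscreteBayesNet(dag_a, dom, cpts_a)
    exp_a = forward_sample(
        net_a,
        1000,
        seed=int(rng.integers(2**31)),
        experiment_id="intA",
        declared_targets=["Vi"],
    )
    net_b = mutilate(truth, InterventionPlan("Vk", "1"))
    exp_b = forward_sample(
        net_b,
        1000,
        seed=int(rng.integers(2**31)),
        experiment_id="intB",
        declared_targets=["Vk"],
    )
    return ExperimentSuite([obs, exp_a, exp_b]), truth.dag


def discretize(
    table: pd.DataFrame,
    bins: int = 2,
    experiment_id: str = "discretized",
    declared_targets: Sequence[str] = (),
) -> tuple[ExperimentDataset, dict[str, np.ndarray]]:
    """Equal-frequency (quantile) binning of a continuous table.

    Each column is split at its empirical quantiles into ``bins`` levels
    labelled ``"b0" .. "b{k-1}"``; the realized bin edges are returned for
    reproducibility.  Rank statistics drive the binning, so any strictly
    monotone transform of a column yields the identical discretization.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    frames = {}
    edges: dict[str, np.ndarray] = {}
    for col in table.columns:
        x = pd.to_numeric(table[col]).to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError(f"column {col!r} is constant: single-level variable")
        interior = np.quantile(x, [k / bins for k in range(1, bins)])
        # assign by average rank so ties always share a bin and any strictly
        # monotone transform yields the identical discretization
        from scipy.stats import rankdata

        ranks = rankdata(x, method="average")
        binned = np.clip(
            np.floor((ranks - 0.5) * bins / len(x)).astype(int), 0, bins - 1
        )
        if len(np.unique(binned)) < 2:
            raise ValueError(f"column {col!r} collapses to a single bin")
        frames[col] = [f"b{int(b)}" for b in binned]
        edges[col] = np.concatenate(([x.min()], interior, [x.max()]))
    labelled = pd.DataFrame(frames, columns=list(table.columns))
    domain = CategoricalDomain(
        {c: tuple(sorted(set(frames[c]))) for c in table.columns}
    )
    dataset = ExperimentDataset(
        experiment_id, labelled, domain, declared_targets=declared_targets
    )
    return dataset, edges


# ---------------------------------------------------------------------------
# JSON interchange for generative networks
# ---------------------------------------------------------------------------

def bn_to_json(bn: DiscreteBayesNet) -> str:
    payload = {
        "nodes": list(bn.dag.nodes),
        "levels": {n: list(bn.domain.levels(n)) for n in bn.dag.nodes},
        "edges": sorted(
            ([u, v] for u, v in bn.dag.edges),
            key=lambda e: (bn.dag.index(e[0]), bn.dag.index(e[1])),
        ),
        "cpts": {n: bn.cpts[n].tolist() for n in bn.dag.nodes},
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def bn_from_json(text: str) -> DiscreteBayesNet:
    payload = json.loads(text)
    nodes = payload["nodes"]
    dag = Dag(nodes, [tuple(e) for e in payload["edges"]])
    domain = CategoricalDomain({n: tuple(payload["levels"][n]) for n in nodes})
    cpts = {n: np.asarray(payload["cpts"][n], dtype=float) for n in nodes}
    return DiscreteBayesNet(dag, domain, cpts)


_NAMED_NETS = {
    "chain": chain_net,
    "fork": fork_net,
    "collider": collider_net,
    "pooling-trap": pooling_trap_net,
    "asia-like": asia_like_net,
}


def named_net(name: str) -> DiscreteBayesNet:
    """Look up one of the shipped fixture networks by name."""
    try:
        return _NAMED_NETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown network {name!r}; available: {sorted(_NAMED_NETS)}"
        ) from None
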