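"""Structure-recovery metrics and method-comparison sweeps.

A directed arc of the ground-truth network is a *positive*; metrics come
from the directed-arc confusion counts.  Accuracy is deliberately not
computed: sparse networks make the negative class overwhelm it.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core import Dag
from .scoring import ScoreConfig
from .search import TabuConfig
from .simulate import DiscreteBayesNet, generate_suite
from .vote import ArcProbabilityTable, VoteConfig, learn_and_vote, pooled_learn, threshold_dag

__all__ = [
    "EvaluationReport",
    "RocPoint",
    "confusion",
    "roc_curve",
    "roc_auc",
    "sweep_runs",
    "sample_size_sweep",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Directed-arc confusion counts with precision/recall/F1."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def confusion(predicted: Dag, truth: Dag, reversal: str = "strict") -> EvaluationReport:
    """Directed-arc confusion of a predicted DAG against the ground truth.

    Under the default ``"strict"`` convention a reversed arc costs one
    false positive *and* one false negative; ``"lenient"`` counts a
    reversed arc as a single error (one false positive, with the true arc
    no longer counted as missed).
    """
    if set(predicted.nodes) != set(truth.nodes):
        diff = set(predicted.nodes) ^ set(truth.nodes)
        raise ValueError(f"node sets differ: {sorted(diff)}")
    if reversal not in ("strict", "lenient"):
        raise ValueError(f"unknown reversal convention {reversal!r}")
    pred, true = predicted.edges, truth.edges
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    if reversal == "lenient":
        reversed_arcs = {(v, u) for u, v in pred - true} & (true - pred)
        fn -= len(reversed_arcs)
    return EvaluationReport(tp=tp, fp=fp, fn=fn)


@dataclass(frozen=True)
class RocPoint:
    """One operating point of the consensus threshold."""

    threshold: float
    sensitivity: float
    fpr: float


def roc_curve(
    avg: ArcProbabilityTable,
    truth: Dag,
    thresholds: Sequence[float] | None = None,
) -> list[RocPoint]:
    """Sensitivity vs. false-positive rate over a threshold grid.

    Each point thresholds the *same* fitted averaged table (so the arc sets
    nest and both coordinates are non-increasing in the threshold).  FPR
    uses all ``v(v-1)`` ordered pairs minus the true arcs as negatives.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    v = len(truth.nodes)
    negatives = v * (v - 1) - len(truth.edges)
    points = []
    for t in thresholds:
        t = float(t)
        if t <= 0.0:
            t_eff = 1e-12  # strict inequality; probability-0 arcs never enter
        elif t >= 1.0:
            points.append(RocPoint(t, 0.0, 0.0))  # exclusive: empty prediction
            continue
        else:
            t_eff = t
        pred = threshold_dag(avg, VoteConfig(threshold=t_eff))
        rep = confusion(pred, truth)
        fpr = rep.fp / negatives if negatives else 0.0
        points.append(RocPoint(t, rep.recall, fpr))
    return points


def roc_auc(points: Sequence[RocPoint]) -> float:
    """Trapezoidal area under the sensitivity-vs-FPR curve.

    The conventional (0, 0) and (1, 1) anchor points are appended before
    integration.
    """
    xy = sorted({(p.fpr, p.sensitivity) for p in points} | {(0.0, 0.0), (1.0, 1.0)})
    xs = np.array([p[0] for p in xy])
    ys = np.array([p[1] for p in xy])
    return float(np.trapezoid(ys, xs))


def sweep_runs(
    bn: DiscreteBayesNet,
    sizes: Sequence[int],
    seeds: Sequence[int],
    k_obs: int = 2,
    k_int: int = 7,
    fat_hand_rate: float = 1.0,
    cfg: ScoreConfig = ScoreConfig(),
    tcfg: TabuConfig = TabuConfig(),
    vcfg: VoteConfig = VoteConfig(),
    reversal: str = "strict",
) -> pd.DataFrame:
    """Per-(size, seed, method) structure-recovery results.

    For every sample size and seed a fresh suite is generated from ``bn``
    and both the voting pipeline and the pooled baseline are run and
    evaluated against the ground truth.  Returns one tidy row per run with
    columns ``size, seed, method, tp, fp, fn, precision, recall, f1``.
    """
    records = []
    for size in sizes:
        for seed in seeds:
            suite, truth, _ = generate_suite(
                bn,
                k_obs=k_obs,
                k_int=k_int,
                n_per_exp=int(size),
                fat_hand_rate=fat_hand_rate,
                seed=int(seed),
            )
            for method, runner in (("vote", learn_and_vote), ("pooled", pooled_learn)):
                consensus = runner(suite, cfg=cfg, tcfg=tcfg, vcfg=vcfg)
                rep = confusion(consensus.dag, truth, reversal=reversal)
                records.append(
                    {"size": int(size), "seed": int(seed), "method": method}
                    | rep.to_dict()
                )
    return pd.DataFrame.from_records(records)


def sample_size_sweep(
    bn: DiscreteBayesNet,
    sizes: Sequence[int],
    seeds: Sequence[int],
    **kwargs,
) -> pd.DataFrame:
    """Mean +/- sd of F1 per (size, method) cell for voting vs. pooling."""
    runs = sweep_runs(bn, sizes, seeds, **kwargs)
    out = (
        runs.groupby(["size", "method"], as_index=False)
        .agg(mean_f1=("f1", "mean"), sd_f1=("f1", "std"), n_seeds=("seed", "nunique"))
        .sort_values(["size", "method"], ignore_index=True)
    )
    out["sd_f1"] = out["sd_f1"].fillna(0.0)
    return out
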