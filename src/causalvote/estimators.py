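"""Estimator-style front ends for the two learning pipelines.

Both classes follow scikit-learn conventions: hyperparameters are
constructor arguments mirrored by ``get_params``/``set_params``, ``fit``
takes the data (an :class:`~causalvote.core.ExperimentSuite`, a single
:class:`~causalvote.core.ExperimentDataset`, or a list of datasets) and all
fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .core import ExperimentDataset, ExperimentSuite
from .scoring import ScoreConfig
from .search import TabuConfig, learn_ensemble
from .vote import (
    ArcProbabilityTable,
    ConsensusNetwork,
    VoteConfig,
    _threshold,
    arc_frequencies,
    average_networks,
)

__all__ = ["LearnAndVote", "PooledLearner"]


def _as_suite(X) -> ExperimentSuite:
    if isinstance(X, ExperimentSuite):
        return X
    if isinstance(X, ExperimentDataset):
        return ExperimentSuite([X])
    return ExperimentSuite(list(X))


class _VotingBase(BaseEstimator):
    """Shared hyperparameter surface of the voting and pooled pipelines."""

    def __init__(
        self,
        iss: float = 1.0,
        ensemble_size: int = 100,
        tabu_list_length: int = 10,
        max_stagnation: int | None = None,
        threshold: float = 0.5,
        mode: str = "average",
        random_state: int = 0,
        keep_ensembles: bool = False,
    ):
        self.iss = iss
        self.ensemble_size = ensemble_size
        self.tabu_list_length = tabu_list_length
        self.max_stagnation = max_stagnation
        self.threshold = threshold
        self.mode = mode
        self.random_state = random_state
        self.keep_ensembles = keep_ensembles

    @classmethod
    def from_configs(
        cls,
        cfg: ScoreConfig = ScoreConfig(),
        tcfg: TabuConfig = TabuConfig(),
        vcfg: VoteConfig = VoteConfig(),
        keep_ensembles: bool = False,
    ):
        return cls(
            iss=cfg.iss,
            ensemble_size=tcfg.ensemble_size,
            tabu_list_length=tcfg.tabu_list_length,
            max_stagnation=tcfg.max_stagnation,
            threshold=vcfg.threshold,
            mode=vcfg.mode,
            random_state=tcfg.base_seed,
            keep_ensembles=keep_ensembles,
        )

    def _configs(self) -> tuple[ScoreConfig, TabuConfig, VoteConfig]:
        return (
            ScoreConfig(iss=self.iss),
            TabuConfig(
                tabu_list_length=self.tabu_list_length,
                max_stagnation=self.max_stagnation,
                ensemble_size=self.ensemble_size,
                base_seed=self.random_state,
            ),
            VoteConfig(threshold=self.threshold, mode=self.mode),
        )

    # -- common fitted-state plumbing -------------------------------------
    def _finish(self, consensus: ConsensusNetwork) -> "_VotingBase":
        self.consensus_ = consensus
        self.dag_ = consensus.dag
        self.arc_table_ = consensus.averaged_table
        self.nodes_ = consensus.dag.nodes
        self.n_features_in_ = len(self.nodes_)
        return self

    def predict(self, X=None):
        """Return the fitted consensus DAG (the data argument is ignored)."""
        if not hasattr(self, "dag_"):
            raise RuntimeError("estimator is not fitted")
        return self.dag_


class LearnAndVote(_VotingBase):
    """Consensus causal-network learner for multi-experiment data.

    Each experiment is analysed separately: an ensemble of
    ``ensemble_size`` Tabu searches from random connected start DAGs under
    the intervention-masked BDeu score yields a directed arc-frequency
    table; tables are averaged over the experiments in which each arc is
    valid (head not intervened) and the averaged probabilities above
    ``threshold`` form the consensus DAG.

    Fitted attributes: ``dag_`` (consensus :class:`~causalvote.core.Dag`),
    ``arc_table_`` (averaged :class:`~causalvote.vote.ArcProbabilityTable`),
    ``per_experiment_tables_`` and ``consensus_`` (all intermediates).
    """

    def fit(self, X, y=None):
        del y
        suite = _as_suite(X)
        cfg, tcfg, vcfg = self._configs()
        tables: list[ArcProbabilityTable] = []
        ensembles: list = []
        for data in suite:
            ensemble = learn_ensemble(data, cfg=cfg, tcfg=tcfg)
            tables.append(arc_frequencies(ensemble, data.declared_targets))
            if self.keep_ensembles:
                ensembles.append(ensemble)
        avg = average_networks(tables, mode=vcfg.mode)
        dag, skipped = _threshold(avg, vcfg)
        consensus = ConsensusNetwork(
            dag=dag,
            averaged_table=avg,
            per_experiment_tables=tables,
            skipped_arcs=skipped,
            ensembles=ensembles if self.keep_ensembles else None,
        )
        self.per_experiment_tables_ = tables
        return self._finish(consensus)


class PooledLearner(_VotingBase):
    """Pooled-data baseline: one learner over the concatenated experiments.

    All experiments are stacked row-wise into a single dataset whose
    intervention mask is inherited per sample; arcs into variables that are
    intervened in *every* sample are blacklisted.  A single Tabu ensemble
    is then thresholded directly — there is no cross-experiment averaging
    step.  This is the classical pooling strategy the voting method is
    designed to improve upon.
    """

    def fit(self, X, y=None):
        del y
        suite = _as_suite(X)
        cfg, tcfg, vcfg = self._configs()
        pooled = suite.concatenate()
        ensemble = learn_ensemble(pooled, cfg=cfg, tcfg=tcfg)
        table = arc_frequencies(ensemble, pooled.declared_targets)
        # a single experiment: averaging is the identity on valid pairs
        avg = average_networks([table], mode=vcfg.mode)
        dag, skipped = _threshold(avg, vcfg)
        consensus = ConsensusNetwork(
            dag=dag,
            averaged_table=avg,
            per_experiment_tables=[table],
            skipped_arcs=skipped,
            ensembles=[ensemble] if self.keep_ensembles else None,
        )
        self.per_experiment_tables_ = [table]
        return self._finish(consensus)
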