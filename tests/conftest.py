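import numpy as np
import pandas as pd
import pytest

from causalvote import CategoricalDomain, Dag, ExperimentDataset


@pytest.fixture
def binary_domain():
    return CategoricalDomain({v: ("0", "1") for v in ("X", "Y", "Z")})


@pytest.fixture
def chain_dag():
    return Dag(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")])


def random_three_var_dataset(seed: int, n: int = 60) -> ExperimentDataset:
    """A dataset sampled from a random 3-node net with Dirichlet-random CPTs."""
    from causalvote import enumerate_dags
    from causalvote.simulate import DiscreteBayesNet, forward_sample

    rng = np.random.default_rng(seed)
    nodes = ("X", "Y", "Z")
    domain = CategoricalDomain({v: ("0", "1") for v in nodes})
    dags = list(enumerate_dags(nodes))
    dag = dags[int(rng.integers(len(dags)))]
    cpts = {}
    for node in nodes:
        q = 2 ** len(dag.parents(node))
        cpts[node] = rng.dirichlet([1.0, 1.0], size=q)
    bn = DiscreteBayesNet(dag, domain, cpts)
    return forward_sample(bn, n, seed=int(rng.integers(2**31)))


def make_dataset(
    columns: dict, declared_targets=(), mask=None, experiment_id="e"
) -> ExperimentDataset:
    """Shorthand: build a dataset from label columns, inferring the domain."""
    table = pd.DataFrame({k: [str(x) for x in v] for k, v in columns.items()})
    domain = CategoricalDomain.infer([table])
    return ExperimentDataset(
        experiment_id, table, domain, declared_targets=declared_targets, mask=mask
    )
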