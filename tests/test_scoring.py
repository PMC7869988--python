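"""Masked BDeu score: frozen closed-form values, brute-force oracle, invariants."""

import math
from itertools import product

import numpy as np
import pytest

from causalvote import (
    Dag,
    ScoreConfig,
    enumerate_dags,
    local_bdeu,
    network_score,
    score_delta,
)
from causalvote.scoring import ScoreCache, apply_move

from conftest import make_dataset, random_three_var_dataset


def oracle_local(variable, parent_set, data, iss=1.0):
    """Independent Dirichlet-multinomial enumeration, recomputing every count
    table from the label-valued table with plain dicts and math.lgamma."""
    dom = data.domain
    table = data.table
    r = dom.cardinality(variable)
    parent_levels = [dom.levels(p) for p in parent_set]
    q = 1
    for lv in parent_levels:
        q *= len(lv)
    a_j = iss / q
    a_jk = iss / (q * r)
    vi = dom.index(variable)
    counts: dict[tuple, dict[str, int]] = {}
    for m in range(data.n_samples):
        if data.mask[m, vi]:
            continue
        cfg = tuple(table.iloc[m][p] for p in parent_set)
        cell = counts.setdefault(cfg, {})
        val = table.iloc[m][variable]
        cell[val] = cell.get(val, 0) + 1
    score = 0.0
    for cfg in product(*parent_levels) if parent_set else [()]:
        cell = counts.get(tuple(cfg), {})
        n_j = sum(cell.values())
        if n_j == 0:
            continue
        score += math.lgamma(a_j) - math.lgamma(a_j + n_j)
        for level in dom.levels(variable):
            n_jk = cell.get(level, 0)
            score += math.lgamma(a_jk + n_jk) - math.lgamma(a_jk)
    return score


class TestFrozenValues:
    def test_empty_parents_beta_binomial(self):
        # three binary observations (0,0,1): marginal likelihood 1/16
        data = make_dataset({"X": ["0", "0", "1"]})
        assert local_bdeu("X", (), data) == pytest.approx(math.log(1 / 16), abs=1e-12)

    def test_masked_sample_drops_from_counts(self):
        mask = np.array([[False], [False], [True]])
        data = make_dataset({"X": ["0", "0", "1"]}, mask=mask)
        # sequential predictive 0.5 * 0.75 under a Beta(1/2, 1/2) prior
        assert local_bdeu("X", (), data) == pytest.approx(math.log(0.375), abs=1e-12)

    def test_fully_masked_variable_scores_zero(self):
        data = make_dataset({"X": ["0", "1", "1"]}, declared_targets=["X"])
        assert local_bdeu("X", (), data) == 0.0


class TestOracleAgreement:
    def test_local_matches_brute_force_on_100_random_datasets(self):
        for seed in range(100):
            data = random_three_var_dataset(seed, n=40)
            rng = np.random.default_rng(10_000 + seed)
            var = data.variables[int(rng.integers(3))]
            others = [v for v in data.variables if v != var]
            parent_set = tuple(
                p for p in others if rng.random() < 0.5
            )
            got = local_bdeu(var, parent_set, data)
            want = oracle_local(var, parent_set, data)
            assert got == pytest.approx(want, abs=1e-9), (seed, var, parent_set)

    def test_network_score_matches_summed_oracle(self):
        data = random_three_var_dataset(7, n=50)
        dag = Dag(data.variables, [("X", "Y"), ("X", "Z"), ("Y", "Z")])
        want = sum(oracle_local(v, dag.parents(v), data) for v in dag.nodes)
        assert network_score(dag, data) == pytest.approx(want, abs=1e-9)

    def test_oracle_agreement_with_masked_samples(self):
        rng = np.random.default_rng(42)
        mask = rng.random((40, 3)) < 0.3
        data = make_dataset(
            {
                "X": rng.integers(2, size=40),
                "Y": rng.integers(2, size=40),
                "Z": rng.integers(2, size=40),
            },
            mask=mask,
        )
        for var, parents in [("X", ("Y",)), ("Y", ("X", "Z")), ("Z", ())]:
            assert local_bdeu(var, parents, data) == pytest.approx(
                oracle_local(var, parents, data), abs=1e-9
            )


class TestMaskSemantics:
    def test_mask_locality_both_directions(self):
        # altering a masked value leaves that variable's score unchanged but
        # may change its child's score
        rng = np.random.default_rng(3)
        x = rng.integers(2, size=30)
        y = (x ^ (rng.random(30) < 0.2)).astype(int)
        mask = np.zeros((30, 2), dtype=bool)
        mask[5, 0] = True
        base = make_dataset({"X": x, "Y": y}, mask=mask)
        flipped_x = x.copy()
        flipped_x[5] ^= 1
        altered = make_dataset({"X": flipped_x, "Y": y}, mask=mask)
        assert local_bdeu("X", (), base) == local_bdeu("X", (), altered)
        assert local_bdeu("Y", ("X",), base) != local_bdeu("Y", ("X",), altered)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.integers(2, size=25)
        y = rng.integers(2, size=25)
        mask = rng.random((25, 2)) < 0.2
        perm = rng.permutation(25)
        a = make_dataset({"X": x, "Y": y}, mask=mask)
        b = make_dataset({"X": x[perm], "Y": y[perm]}, mask=mask[perm])
        for var, parents in [("X", ()), ("Y", ("X",))]:
            assert local_bdeu(var, parents, a) == pytest.approx(
                local_bdeu(var, parents, b), abs=1e-12
            )


def _markov_class_key(dag):
    """Skeleton + v-structures characterize the Markov equivalence class."""
    skeleton = frozenset(frozenset(e) for e in dag.edges)
    v_structs = set()
    for z in dag.nodes:
        pa = dag.parents(z)
        for i, x in enumerate(pa):
            for y in pa[i + 1:]:
                if not (dag.has_edge(x, y) or dag.has_edge(y, x)):
                    v_structs.add((frozenset({x, y}), z))
    return (skeleton, frozenset(v_structs))


class TestScoreEquivalence:
    def test_markov_equivalent_dags_score_equal_on_observational_data(self):
        data = random_three_var_dataset(11, n=80)
        classes: dict = {}
        for dag in enumerate_dags(data.variables):
            classes.setdefault(_markov_class_key(dag), []).append(
                network_score(dag, data)
            )
        assert len(classes) == 11  # 3-node Markov classes
        for scores in classes.values():
            assert max(scores) - min(scores) < 1e-9

    def test_two_node_reversal_scores_equal(self):
        data = make_dataset({"X": ["0", "1", "1", "0", "1"], "Y": ["1", "1", "0", "0", "1"]})
        nodes = data.variables
        fwd = network_score(Dag(nodes, [("X", "Y")]), data)
        bwd = network_score(Dag(nodes, [("Y", "X")]), data)
        assert fwd == pytest.approx(bwd, abs=1e-12)

    def test_additivity(self):
        data = random_three_var_dataset(13, n=60)
        dag = Dag(data.variables, [("X", "Z"), ("Y", "Z")])
        total = sum(local_bdeu(v, dag.parents(v), data) for v in dag.nodes)
        assert network_score(dag, data) == pytest.approx(total, abs=1e-12)


class TestScoreDelta:
    def test_inverse_moves_cancel(self):
        data = random_three_var_dataset(17, n=60)
        dag = Dag(data.variables)
        cache = ScoreCache(data, ScoreConfig())
        d_add = score_delta(dag, ("add", "X", "Y"), data, cache=cache)
        dag2 = apply_move(dag, ("add", "X", "Y"))
        d_del = score_delta(dag2, ("delete", "X", "Y"), data, cache=cache)
        assert d_add + d_del == pytest.approx(0.0, abs=1e-12)

    def test_reverse_equals_delete_plus_add(self):
        data = random_three_var_dataset(19, n=60)
        dag = Dag(data.variables, [("X", "Y")])
        cache = ScoreCache(data, ScoreConfig())
        d_rev = score_delta(dag, ("reverse", "X", "Y"), data, cache=cache)
        d_del = score_delta(dag, ("delete", "X", "Y"), data, cache=cache)
        after = apply_move(dag, ("delete", "X", "Y"))
        d_add = score_delta(after, ("add", "Y", "X"), data, cache=cache)
        assert d_rev == pytest.approx(d_del + d_add, abs=1e-12)

    def test_delta_agrees_with_full_rescore_on_random_moves(self):
        rng = np.random.default_rng(23)
        nodes = ("A", "B", "C", "D")
        checked = 0
        data = None
        while checked < 100:
            if checked % 10 == 0:
                data = _four_var_dataset(int(rng.integers(2**31)))
            dag = _random_dag(nodes, rng)
            move = _random_legal_move(dag, rng)
            if move is None:
                continue
            cache = ScoreCache(data, ScoreConfig())
            delta = score_delta(dag, move, data, cache=cache)
            full = network_score(apply_move(dag, move), data) - network_score(dag, data)
            assert delta == pytest.approx(full, abs=1e-9)
            checked += 1

    def test_illegal_move_rejected(self, chain_dag):
        data = random_three_var_dataset(29, n=30)
        with pytest.raises(Exception):
            score_delta(chain_dag, ("add", "Z", "X"), data)  # would close a cycle


def _four_var_dataset(seed):
    rng = np.random.default_rng(seed)
    return make_dataset(
        {v: rng.integers(2, size=30) for v in ("A", "B", "C", "D")}
    )


def _random_dag(nodes, rng):
    from causalvote import create_random_connected_dag

    return create_random_connected_dag(nodes, seed=int(rng.integers(2**31)))


def _random_legal_move(dag, rng):
    from causalvote import has_path

    kinds = ["add", "delete", "reverse"]
    nodes = dag.nodes
    for _ in range(50):
        kind = kinds[int(rng.integers(3))]
        u = nodes[int(rng.integers(len(nodes)))]
        v = nodes[int(rng.integers(len(nodes)))]
        if u == v:
            continue
        if kind == "add" and not dag.has_edge(u, v) and not dag.has_edge(v, u) and not has_path(dag, v, u):
            return (kind, u, v)
        if kind == "delete" and dag.has_edge(u, v):
            return (kind, u, v)
        if kind == "reverse" and dag.has_edge(u, v):
            try:
                dag.with_reversed(u, v)
            except Exception:
                continue
            return (kind, u, v)
    return None
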