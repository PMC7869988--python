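# causalvote

Consensus causal network learning from multiple observational and
interventional experiments — by voting, not pooling.

## The problem

To learn a causal Bayesian network people routinely concatenate samples
from several experiments into one big table. When interventions are
*uncertain* — a perturbation secretly hits more nodes than the one it was
aimed at — pooling backfires in two characteristic ways: variables that
are causally unrelated but were co-perturbed become dependent in the
pooled mixture (spurious arcs), and rows in which a variable was clamped
dilute or reorient its true incoming arcs (missed arcs). Cell-signaling
experiments, where inhibitors have off-target effects, are the archetype.

`causalvote` keeps experiments separate. For each experiment `j` with
dataset `D_j` it learns an ensemble of DAGs by Tabu search under an
intervention-masked BDeu score

```
S(G : D_j) = Σ_i S_local(V_i, Pa(V_i) : D_j),
S_local   = Σ_j [lnΓ(α_j) − lnΓ(α_j+N_j)] + Σ_jk [lnΓ(α_jk+N_jk) − lnΓ(α_jk)]
```

with counts taken only over samples where `V_i` was not intervened.
Every possible directed arc then gets, per experiment, its empirical
frequency across the ensemble (an arc in 90 of 100 optimized DAGs scores
0.90); frequencies are averaged over the experiments in which the arc's
head was not an intervention target; and the arcs whose averaged
probability exceeds a threshold (default 0.5) form the consensus DAG
`G^f`. A pooled baseline (same score, same search, one concatenated
dataset) is included for comparison, as is a simulator of mutilated
networks with hidden "fat-hand" off-target clamps and an evaluation
harness (precision/recall/F1, threshold curves, sample-size sweeps).

## Worked example

The shipped three-node fixture encodes the pooling trap: ground truth
`Vi → Vk ← Vj`, one observational experiment, one experiment whose
intervention secretly clamps `Vi` *and* `Vj` to identical random values
(only `Vi` declared), and one declared clamp of `Vk`.

```python
from causalvote import TabuConfig, learn_and_vote
from causalvote.simulate import pooling_trap_fixture

suite, truth = pooling_trap_fixture(seed=0)
result = learn_and_vote(suite, tcfg=TabuConfig(ensemble_size=30, base_seed=7))
print("consensus arcs:", sorted(result.dag.edges))
print(result.averaged_table.to_frame().round(3).to_string(index=False))
```

prints

```
consensus arcs: [('Vi', 'Vk'), ('Vj', 'Vk')]
from to  prob  valid  strength  direction
  Vi Vj 0.333   True     0.333        1.0
  Vi Vk 0.667   True     0.667        1.0
  Vj Vi 0.000   True     0.333        0.0
  Vj Vk 0.833   True     0.833        1.0
  Vk Vi 0.000   True     0.667        0.0
  Vk Vj 0.000   True     0.833        0.0
```

Read this as: the ensemble of the co-clamped experiment votes for the
spurious `Vi → Vj` arc with probability 1, but the two experiments in
which the pair behaves normally vote 0, so the average lands at 1/3 —
below threshold — and the consensus recovers exactly the true collider.
Running `PooledLearner` on the same suite instead reports `Vi → Vj` with
probability 1: the false positive the voting step exists to remove.

The same machinery is available as scikit-learn-style estimators
(`LearnAndVote`, `PooledLearner`: constructor hyperparameters,
`fit(suite)`, fitted `dag_` / `arc_table_` attributes) and as a CLI:

```sh
causalvote simulate --net asia-like --k-obs 2 --k-int 7 --n 1000 --seed 1 --out suite/
causalvote learn suite/manifest.yaml --out fit/ --seed 1
causalvote evaluate fit/consensus.tsv suite/truth.tsv
causalvote roc fit/arcs_averaged.csv suite/truth.tsv --out roc.csv
```

`learn --pooled` switches to the pooled baseline, `--mode majority` to
majority voting, and `learn-one`, `score` and `sweep` expose the
single-dataset ensemble, the score itself, and the sample-size
comparison. See `docs/methods.md` for the model, assumptions, parameter
meanings, and limitations.

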