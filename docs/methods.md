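# Methods

## Problem and model

`causalvote` learns the structure of a causal Bayesian network over a fixed
set of categorical variables from **several experiments** — some purely
observational, some with declared interventions — without pooling their
samples into one table. The motivating failure modes of pooling are well
known: an intervention that secretly co-targets two variables makes them
look dependent in the pooled mixture (a false positive), and pooling rows
in which a variable was externally clamped dilutes or reorients its true
incoming arcs (a false negative). Both effects are demonstrated by the
shipped three-node fixture (`pooling_trap_fixture`).

The pipeline has four stages per suite of `k` experiments:

1. **Score.** Candidate DAGs are scored per experiment with an
   intervention-masked BDeu marginal likelihood. For variable `V` with
   level count `r`, parent set inducing `q` parent configurations, and
   equivalent sample size `iss`, the local score is

   ```
   sum_j [ lnΓ(α_j) − lnΓ(α_j + N_j) ] + sum_{j,k} [ lnΓ(α_jk + N_jk) − lnΓ(α_jk) ]
   α_jk = iss / (q·r),   α_j = iss / q
   ```

   where the counts `N` run only over samples in which `V` itself is not
   masked. A masked sample still contributes its values as *parent*
   conditions for other variables. The network score is the sum of local
   scores (decomposable). A uniform structure prior is an additive
   constant and is dropped. Natural logarithms throughout.

2. **Search.** Per experiment, an ensemble of `n` Tabu searches is run
   from `n` random weakly-connected start DAGs. Arcs into declared
   intervention targets are handled belt-and-braces: they are blacklisted
   from the move set *and* carry no score signal (the target is fully
   masked). Moves are add/delete/reverse; the best legal non-tabu move is
   taken each step (lexicographic `(kind, u, v)` tie-break in node-list
   order), worsening moves are allowed when nothing improves, the tabu
   list forbids undoing the last `tabu_list_length` moves, and the search
   stops after `max_stagnation` steps without improving the best-so-far.

3. **Vote.** Each ensemble becomes a table of directed arc frequencies
   (an arc in 90 of 100 optimized DAGs gets probability 0.90). An ordered
   pair `(u, v)` is *invalid* in an experiment that declared `v` as an
   intervention target — the arc is unobservable there by construction —
   and the cross-experiment average runs over valid experiments only.
   Pairs valid nowhere are reported as never-observable with probability
   0 (not missing), so downstream metrics keep a fixed denominator.

4. **Threshold.** Arcs with averaged probability strictly above the
   threshold enter the consensus DAG in descending probability order;
   when both orientations qualify only the stronger survives (an exact
   tie drops both), and any arc that would close a cycle is skipped and
   logged.

The pooled baseline (`PooledLearner`) concatenates all experiments
row-wise (masks inherited per sample, arcs blacklisted only into variables
masked in *every* sample) and runs a single ensemble — the classical
strategy the voting route is designed to improve on. Both pipelines share
every component except the averaging step, so comparisons isolate the
pooling decision itself.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `iss` | 1.0 | total Dirichlet prior mass per local count table; 1 is the common convention of discrete-BN software |
| `ensemble_size` (`n`) | 100 | Tabu restarts per experiment; 100 is adequate at the network sizes treated here |
| `tabu_list_length` | 10 | forbidden-undo memory |
| `max_stagnation` | `max(100, 10·v)` | non-improving steps before stopping |
| `threshold` | 0.5 | consensus cut on averaged arc probability (strict `>`) |
| `mode` | `average` | `majority` binarizes each experiment's vote at 0.5 first — more robust to one extreme experiment, usually sparser |

The equivalent sample size and the structure prior are deliberately plain
configuration knobs: no published value fixes them for this method, so the
defaults follow the surrounding software ecosystem and are overridable
everywhere (`ScoreConfig`, CLI `--iss`).

## The synthetic-data generator

`generate_suite` emulates the experimental protocol the method targets:
forward sampling from a discrete ground-truth network; equal sample sizes
(default 1,000 per experiment); a default suite shape of 2 observational +
7 interventional experiments; interventions clamp a uniformly drawn
non-leaf target to a uniformly drawn level (leaves are avoided because
they cascade no causal signal — a choice only possible because the ground
truth is known); and with probability `fat_hand_rate` one uniformly chosen
child of the target is *also* clamped without being declared. Clamps are
point masses with incoming arcs removed ("mutilation"); soft or
mechanism-change interventions are out of scope. Hidden off-target clamps
are returned as oracle-only plans and never reach the learner's declared
targets or mask.

What the generator does **not** emulate: batch effects and
experiment-specific distribution shifts beyond interventions, measurement
error, missing data, unequal sample sizes (the suite only warns), or
continuous mechanisms (Gaussian data must pass through `discretize`,
a rank-based equal-frequency binner). Passing tests therefore show that
the pipeline behaves correctly under clean, known-mechanism intervention
noise — not that it is robust to everything real cytometry data does.

### The three-node fixture

`pooling_trap_fixture` encodes the two pooling error modes on the collider
`Vi → Vk ← Vj` (independent fair-coin parents,
`P(Vk=1|Vi,Vj) = 0.05/0.8/0.8/0.95`):

* `intA` clamps Vi *and* Vj to perfectly correlated random values
  (Vi drawn fair, Vj set equal), declaring only Vi. A constant joint
  clamp would make the pair degenerate inside the experiment; the random
  correlated clamp is what makes the two variables "perfectly dependent"
  in-experiment while still exposing the artifact only through pooling.
* `intB` clamps Vk, declared.
* one observational experiment.

Pooling the three experiments makes the Vi–Vj dependence statistically
overwhelming (the pooled learner reports the spurious arc on essentially
every seed), while the voting route confines it to `intA`'s table where
it is averaged down to 1/3. The false-independence mode appears as an
orientation flip in the pooled learner (`Vk → Vj` replacing `Vj → Vk`) on
a minority of seeds (about 1 in 5) and never in the voting route; the
effect is directionally consistent but tie-heavy, so a per-seed sign test
at α = 0.05 over 20 seeds does not reach significance (4 discordant pairs,
one-sided p = 0.0625, all discordance favoring voting; the mean-recall
inequality holds). The corresponding strict assertion is kept in the test
suite and currently fails by that margin; the fixture's CPTs were fixed
before any comparison was run and are not adjusted to manufacture
significance.

### The eight-node fixture

`asia_like_net` is a lung-disease-style toy network (visit → tub;
smoke → lung, bronc; tub, lung → either; either → xray; either, bronc →
dysp) whose CPT values are this package's own: the classical
deterministic or-gate is replaced by a noisy one (deterministic nodes are
degenerate under Dirichlet-multinomial scoring) and marginals are kept
away from 0/1 so arcs are learnable at 1,000 samples.

## Numerical and design choices

* The masked BDeu integral is implemented in its closed lnΓ form; empty
  parent-configuration cells cancel exactly and zero counts need no
  pseudo-count handling beyond the Dirichlet hyperparameters.
* Local scores are memoized per (variable, parent set) and shared across
  all restarts of one experiment; move deltas are stored per candidate
  arc and recomputed only for nodes whose parent set changed.
* `create_random_connected_dag` draws a random permutation, orients a
  random spanning tree forward along it, and adds each remaining forward
  pair with probability `min(1, 2/(v−1))` (expected extra degree ≈ 2).
  Connectivity and acyclicity are guaranteed by construction. Start DAGs
  have blacklisted arcs stripped and are *not* re-connected afterwards.
* Tie-breaks are deterministic everywhere (node-list order), so the whole
  pipeline is bitwise reproducible given its seeds; the Tabu search
  itself draws no random numbers.
* Reversed arcs are scored strictly by default in evaluation (one false
  positive *and* one false negative); a lenient single-error convention
  is available (`reversal="lenient"`).
* Threshold curves are computed from one fitted averaged table per
  dataset, so sensitivity and FPR are monotone in the threshold by the
  nesting property — by design, unlike curves produced by re-learning per
  threshold, which are noisy under random restarts.
* FPR uses all `v(v−1)` ordered pairs minus true arcs as negatives.
* Degenerate inputs: fully masked variables score 0; empty ensembles,
  heterogeneous node sets, unknown levels (named with sample and
  variable), constant columns in `discretize`, and cyclic edge lists all
  raise named errors.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run every comparison at small
problem sizes, chosen as the package's own standard check sizes: 100 random
3-variable datasets for the score oracle and the exhaustive-optimum rate
(n = 200 samples, 10 restarts); 20 seeds × 100 restarts on the three-node
fixture; 10 seeds × 20 restarts on the eight-node suite at sample sizes
20 and 1,000. Larger ensembles change none of the qualitative results,
only the granularity of the arc frequencies.

## Known limitations

* Score-based search over DAGs does not scale to large variable counts;
  run time grows steeply with `v` and with parent-set sizes.
* Equal per-experiment sample sizes are assumed by the unweighted
  average; unequal sizes bias the consensus toward nothing in particular
  (each experiment still gets one vote) but make the per-experiment
  frequency estimates unequally reliable. The suite warns.
* Only perfect (point-mass) clamps are simulated; soft interventions and
  latent confounding are out of scope, as are partially directed outputs
  (every result is a DAG, never a CPDAG/PAG).
* With very small samples per experiment, per-experiment learning is
  noisy and pooling can genuinely win — the sample-size sweep exists to
  show exactly where that crossover sits.
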