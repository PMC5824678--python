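# Methods

## The model

`rangedec` implements likelihood inference of geographic-range evolution on a
dated, fully bifurcating, ultrametric phylogeny under the
Dispersal-Extinction-Cladogenesis (DEC) process. A lineage's state is its
*range* — the subset of discrete areas it occupies, encoded as a bitmask over
an ordered area list. Along a branch the range evolves as a continuous-time
Markov chain:

- **gain** (dispersal): `R -> R + {b}` at rate `d * sum_{a in R} m_t(a, b)`,
  where `m_t` is the dispersal-multiplier matrix of the epoch containing the
  moment of the event;
- **loss** (local extinction): `R -> R - {a}` at rate `e` per occupied area;
- the **empty range** is absorbing (global extinction of the lineage).

`d` (per source/destination area pair per Myr) and `e` (per area per Myr) are
the only free rates; multipliers are fixed model inputs.

At every cladogenesis the ancestral range is partitioned between the
daughters. A single-area ancestor copies itself to both daughters
(*sympatry*). A larger ancestor yields every ordered pair in which one
daughter is a single member area and the other is either the full range
(*subset sympatry*) or its complement (*vicariance*); all outcomes of a given
ancestor are equally weighted. Outcomes whose daughters fall outside a
constrained state space are dropped and the remainder renormalized, so the
per-node outcome distribution stays proper.

The tree likelihood is computed by Felsenstein pruning with cladogenetic
mixing at internal nodes; branch propagation multiplies per-epoch-segment
matrix exponentials (oldest to youngest). The root is summed over non-empty
ranges under a uniform prior (configurable to any probability vector).
Per-node rescaling keeps the recursion in floating range on large trees.

## Range state spaces and the adjacency constraint

The state space is every subset of the areas, optionally filtered by a
maximum range size and/or by connectivity in a geographic adjacency graph
("constrained" regime): a range is allowed iff its induced adjacency subgraph
is connected. Position 0 is always the empty range; order is deterministic
(size, then bitmask).

**Semantics of exclusion.** Two different reasons exclude a range, and they
are treated differently in the generator:

- a range larger than `max_size` is a *computational truncation*: transitions
  into it are simply dropped (rate 0);
- a *disconnected* range under the constrained regime is a *model statement*:
  a transition into it routes its full rate into the absorbing empty range —
  the lineage fragments and is treated as extinct in place.

The absorbing treatment makes the constrained likelihood the probability of
the data *and* of the lineage never occupying a disconnected range — a
sub-event of the unconstrained model. Consequently the unconstrained
maximum likelihood can essentially never be beaten by the constrained one on
the same data (the state-space nesting property the scenario comparison
rests on), and rate-matrix rows still sum to zero, so transition matrices
stay stochastic. With the alternative rate-0 treatment
(`build_generator(..., connectivity_exit="drop")`, the classic
reduced-state-space construction) the constrained model has *smaller* total
exit rates and can spuriously out-score the unconstrained model; we keep it
available for comparison but the absorbing semantics is the default and is
what the scenario grid uses.

## Time stratification

An `EpochSet` carries strictly decreasing boundary ages ending implicitly at
the present (default `18, 5.5, 1.25` Myr in the bundled preset) and one
multiplier matrix per interval. Branches are sliced at boundaries; segment
durations always sum to the branch length. By default the same matrix is
used in every epoch; per-epoch matrices are accepted everywhere.

## Dispersal multipliers

Three bundled 12-area matrices: Matrix I (all ones — cost-free dispersal),
Matrix II (distance costs), Matrix III (distance costs plus a 0.001 barrier
value across the Andes). Matrices are stored exactly as printed, including
asymmetric cells (row = source, column = destination); asymmetry triggers a
QC warning, and `symmetrized()` (element-wise max) is available but never
applied implicitly. `build_multipliers_from_graph` generates a matrix from
adjacency-graph distances: 0.8 / 0.6 / 0.4 / 0.2 for distances 1-4 and 0.08
for 5 or more (the monotone extension of the printed rule's smallest value);
barrier pairs override their distance value with 0.001.

The bundled adjacency graph for the 12 areas is derived from Matrix II: a
pair is adjacent iff its multiplier is 0.8 (the adjacent-pair value). The
0.8 cells are symmetric and the resulting 22-edge graph is connected.
A thirteenth area (Patagonia Subandina) appears in some map legends of the
source material but not in the multiplier tables; the bundled system follows
the tables (A-L).

## Estimation

`DECModel.fit()` maximizes the likelihood over `(d, e) >= 0` by Nelder-Mead
on log rates from three fixed starting points `(0.01, 0.01)`, `(0.1, 0.01)`,
`(0.01, 0.1)`, convergence tolerance 1e-8 on -lnL, log rates clipped to
[-30, 5]. Fitting contains no randomness; the best of the three runs is
reported, and non-convergence sets a flag instead of raising.

**Numerics.** The pruning hot path uses one eigendecomposition per (epoch,
parameter) pair and applies `e^{Qt}` to message vectors in the eigenbasis;
the decomposition is accepted only if it reconstructs the generator to
1e-10 (relative to its largest rate), otherwise dense `scipy` `expm` with a
per-duration cache is used. The public `branch_transition` contract is the
product of per-segment matrix exponentials and is verified against a
Runge-Kutta ODE oracle at 1e-8.

## Ancestral reconstruction and event counting

Marginal per-node probabilities combine downpass conditionals with an uppass
from the root prior; both passes are verified against exhaustive enumeration
of all (node state, outcome) scenarios on small trees. Each node also gets a
single best (ancestral range, split) scenario; ties are broken
deterministically — larger probability, then smaller ancestral range, then
lexicographic bitmask — with daughter assignment keyed on child ids so the
result is invariant under swapping a node's children.

Global event tallies use the best scenario per node: a vicariant best split
counts one vicariance; along every branch the areas gained relative to the
inherited daughter range count as dispersals, areas lost as extinctions
(tips contribute their observed ranges). The full per-branch log is emitted
(`event_table`) so alternative tallies can be derived.

## The synthetic-data generator

`simulate_yule` draws a pure-birth tree: from the root split, inter-event
waits are `Exp(k * birth_rate)` over `k` extant lineages, the splitting
lineage is uniform, and a final `Exp(n * birth_rate)` stem reaches the
present; optional exact rescaling to a target height. `simulate_dec` runs
exact (Gillespie) stochastic simulation of the anagenetic process along
branches with epoch-aware rates and draws cladogenetic outcomes at nodes,
recording a complete event log that replays from the root state to the tip
ranges bit-for-bit. Lineages hitting the empty range stay extinct in place
(the tree is fixed a priori); datasets with any empty tip are redrawn, up to
100 attempts. All randomness flows through one seeded generator.

`make_liolaemus_like(seed)` is the canonical preset emulating the study
design: 53 terminals, 12 areas, tree rescaled to 18 Myr, Matrix II in the
three epochs, ranges capped at two areas, `d = 0.05`, `e = 0.01`.

**What the generator does not emulate:** phylogenetic and dating
uncertainty (the tree is known and exactly ultrametric), sampling biases in
species distributions, range-size-dependent speciation/extinction, and any
feedback between ranges and diversification. A green recovery test
therefore certifies the inference machinery, not the realism of DEC for any
particular empirical system.

## Known limitations

- **Extinction rate is barely identifiable.** Subset-sympatry cladogenesis
  reproduces range contraction at nodes at no rate cost, and discarding
  simulated datasets with empty tips further biases the signal downward, so
  the MLE of `e` sits at zero in essentially every synthetic replicate at
  the preset's scale (`e = 0.01`). Dispersal-rate recovery at the same scale
  is excellent (median |log d-hat/d| around 0.1). This mirrors the tendency
  of DEC analyses to report near-zero extinction.
- **Event tallies are reconstruction-based, not history-based.** Per-node
  best splits systematically miss vicariance events that later dispersal or
  extinction obscures; in 50-tip pilots the dispersal totals track the true
  counts within 30% in every replicate, vicariance in roughly two thirds.
- Polytomies are rejected, not resolved; zero-length internal branches are
  rejected as polytomy-equivalent.
- No founder-event (jump dispersal) parameter, no Bayesian machinery, no
  estimation of the multipliers themselves.
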