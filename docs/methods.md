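# Methods

## The model

A society of `N` agents is described entirely by an `N x N` *feeling
matrix* `F` with entries in `{+1, -1}`: `F[i, j] = +1` means agent `i`
is friendly toward agent `j`. Diagonal entries are fixed at `+1` (everyone
accepts themselves) and are never updated.

Agent `i`'s **ego-group** is

    G̅_i = {i} ∪ { j ≠ i : F[i, j] = +1 and F[j, i] = +1 },

i.e. itself plus everyone with whom it exchanges mutual friendliness, with
`n_i = |G̅_i|`. Groups are *emergent*: nothing constrains two agents'
ego-groups to coincide, and mid-run the mutual-friendship graph is
typically far from a disjoint union of cliques.

**Congruity.** Agents value being *in tune* with their group: sharing
likes and dislikes about third parties. We measure the discrepancy
between two feeling vectors that disagree on `k` of their `N` components
by the Euclidean distance between the corresponding ±ε vectors, with the
magnitude ε = 1/(2√N) chosen so that the distance runs exactly over
[0, 1]:

    d(f_i, f_k) = sqrt(k / N),

0 for perfectly synchronized vectors and 1 for completely desynchronized
ones. The congruity of agent `i` is

    c_i = 1 − (1 / |G_i|) Σ_{k ∈ G_i} d(f_i, f_k),   G_i = G̅_i \ {i},

so `c_i ∈ [0, 1]` with `c_i = 1` for a perfectly synchronized group. An
agent with no peers has `c_i = 1` by convention (there is no one to be
out of tune with).

The square root matters. It makes the *first* disagreement with a peer
the most expensive one, so a well-synchronized group pays a real
congruity price for admitting (or turning toward) anyone who deviates
from its consensus, even on a single component. Under a linear
(fraction-of-disagreements) distance that price is only `1/N` per peer
and vanishes against the unit gain in group size: every society then
unifies, no agent is ever kept out, and none of the phenomena this
package exists to study occur at all. We verified this by exhaustive
simulation over the candidate metric family before fixing the definition.

**Sense of belonging.** Each agent maximizes

    S_i = n_i · c_i^{γ_i} − λ_i · m_i,

where `γ_i ≥ 0` weighs congruity against raw group size, `m_i` is the
number of agents that `i` dislikes, and `λ_i ≥ 0` is an optional guilt
penalty per dislike (default 0). `0^0` is taken as 1, so a γ = 0 agent —
a **philanthropist**, who cares only about how many mutual friendships it
holds — in a singleton group scores exactly its group size.

**Best response with inertia.** When an agent receives a revision
opportunity it evaluates its payoff under each of the `N − 1` single-sign
flips of its own feeling vector (all other rows held fixed) and under no
change. It moves only if some flip is *strictly* better than staying put;
among exactly tied best flips one is chosen uniformly at random from a
seeded generator. Inertia keeps the dynamics deterministic except at
genuine ties (which are rare under the square-root metric because
candidate payoffs are generically irrational) and reflects agents who
adjust their social ties conservatively rather than churning through
payoff-neutral moves. Without inertia an indifferent agent — most
prominently a philanthropist that has exhausted its mutual-friendship
opportunities — random-walks its remaining attitudes forever and no run
ever settles.

**Update schedules.** `synchronous` (default): all agents best-respond to
the same configuration and the flips are applied at once. `sequential`:
agents are visited in index order, each flip applied immediately.
`random`: `N` uniformly drawn agents (with replacement) per time step,
applied immediately. The qualitative behavior is the same across
schedules; all tests of fixed-point structure run under all three.

**Halting.** `run_dynamics` iterates up to a horizon `T` (default 40, the
measurement time used for all sweep statistics; single-trajectory
illustrations use 20). It stops early when a step reproduces its input
(fixed point) or when a configuration recurs within a 4-step window
(cycle, possible in principle under synchronous updates). All
measurements are taken on the final stored configuration.

## Outcome classification

For reporting, *clusters* are connected components of the undirected
mutual-friendship graph; whether each component is a clique is reported
as a diagnostic, not assumed. A configuration is labelled with strict
precedence:

1. **unified** — every ego-group is the whole population (equivalently, a
   single clique cluster of size `N`);
2. **ostracism** — at least one *outcast* (an agent whose ego-group is a
   singleton) while all non-outcasts form a single cluster;
3. **fragmented** — everything else. This residual class contains both
   genuine multi-group fixed points and loose single-cluster states still
   coalescing when the horizon is reached.

## Synthetic initial conditions

Initial feeling matrices are i.i.d. Bernoulli: each off-diagonal entry is
`+1` with probability `p_friend`, independently. This is the study's own
notion of a random society with a tunable friendliness climate; it is not
meant to emulate any empirical network feature (no degree heterogeneity,
homophily, reciprocity correlation, or community structure). Passing
tests therefore demonstrate properties of the model, not claims about
real social networks. At `N = 30, p = 0.4` mutual friendliness between
two agents has probability `0.16`, making the modal initial ego-group
size `1 + mode(Binomial(29, 0.16)) = 5`.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `n_agents` | 30 | population size used in all scripted studies |
| `p_friend` | study-specific | initial friendliness probability per directed pair |
| `gamma` | 1.0 | congruity exponent; 0 defines a philanthropist; > 1 favors tight, homogeneous groups |
| `penalty_lambda` | 0.0 | guilt penalty per disliked agent; > N forces unanimity within N − 1 steps |
| `horizon` | 40 | measurement time for sweeps (20 for single-trajectory plots) |
| `replicates` | 1000 | Monte Carlo replicates per grid point (the original study scale is 10,000) |
| checkerboard states | 16 × 16 | scaled from the original 64 × 64 to keep the default suite in minutes |

Replicate `k` of grid point `g` derives its initial-configuration seed and
its tie-breaking seed from `SeedSequence(master_seed, spawn_key=(g, k))`,
so any single replicate can be reproduced in isolation and the
philanthropist/baseline arms of a sweep see identical starting
configurations (paired comparison).

## Numerical choices

* Payoff comparisons use a relative tolerance of `1e-9`: exact ties
  (symmetric candidates) are preserved, while distinct sums of
  square-root terms essentially never fall inside it at these sizes.
* Candidate payoffs for all `(agent, flip)` pairs are evaluated with dense
  `N × N` linear algebra: flipping component `j` changes the disagreement
  count with any peer by exactly ±1, so the flipped peer-distance sums
  decompose into one matrix product. The implementation is checked against
  a literal brute-force oracle exhaustively for `N ≤ 4` and on random
  instances for `N = 5`.
* Congruity values are clipped to `[0, 1]` as a guard against float
  round-off; mathematically they cannot leave that interval.

## Known limitations

* The defining payoff of the source model is reconstructed from a verbal
  description; this package fixes one concrete reading (square-root
  distance, inertial best response) chosen because it reproduces the
  model's characteristic phenomenology — spontaneous coalescence,
  accidental stable ostracism at γ = 1, fragmentation into several tight
  groups at γ = 1.5, the philanthropist's elevated isolation risk, and
  robustness of all of these to a moderate dislike penalty.
* The philanthropist's *peak* isolation probability over the friendliness
  grid measures ≈ 17% here (1,000 replicates per point): far above an
  ordinary agent's ≈ 0.4%, but below the ≈ 40% reported for the original
  model. Within the reconstruction family we explored (distance exponent
  and scale, congruity normalization, singleton convention, tie rules),
  raising this number always traded away the unified/ostracism dichotomy
  of the basin-of-attraction study; we kept the dichotomy.
* A single checkerboard freezes 28 of 30 feeling vectors, so one board's
  class mix depends heavily on that background draw; only an ensemble of
  backgrounds reliably exhibits both basins.
* Cycle detection only scans a short window (4 steps); longer periodic
  orbits, if any, are reported as `horizon_reached`.
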