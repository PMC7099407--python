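# Methods

## Model and assumptions

The package analyses a two-strategy, two-population evolutionary game.
Each of two virus strains (A, B) consists of individuals that either
carry a mini-CRISPR spacer against the other strain or do not; `x_A`
and `x_B` are the carrier fractions. The model's assumptions:

* **Coinfection probabilities are free parameters.** `p_B_given_A` is
  the probability that an infection by A is joined by B; it is not
  derived from population dynamics (host and virus abundances are not
  modelled) but treated as an ecological input. The two directed
  probabilities are linked to the infection marginals by Bayes'
  theorem, `p_B|A = (p_B / p_A) p_A|B`, which the
  `CoinfectionMarginals` container enforces.
* **Payoffs are mean productivities** relative to a clean single
  infection (normalised to 1). A carried array costs a fraction `c` of
  productivity unconditionally. An untargeted mixed coinfection yields
  `w` (1/2 = no interference; < 1/2 interference; > 1/2 facilitation;
  `w > 1` is rejected). Under mutual targeting "the first to arrive
  wins": expected yield `q(1-c)`. `q_A + q_B < 1` (partial mutual
  destruction on near-simultaneous entry) is supported by passing the
  given `q` values into the same formulas with no renormalisation; the
  model does not specify how the missing probability mass is split
  between joint death and reduced yield, and the payoff formulas are
  applied verbatim.
* **Deterministic replicator dynamics.** Infinite populations, no
  spacer acquisition, no protospacer escape mutations.

## Payoff variants

* `standard` — the base game (table in the README).
* `provirus_pair` — destroying a resident provirus degrades the host
  genome, so a targeting virus gets the mutual-targeting payoff
  `(1-c)(1-p+qp)` regardless of the opponent's strategy
  (`self_only = both_target`). The modified first threshold
  (`2c/(1+c-2w)` at `q = 1/2`) is *derived* from this payoff via the
  linear-root route (see below), not hard-coded.
* `se_blocking` — early-acting superinfection exclusion: arrays help
  neither virus. Modelling convention: the benefit terms are zeroed,
  i.e. every class receives the untargeted-coinfection payoff
  `1-(1-w)p`, times `(1-c)` for array carriers. Payoffs become
  opponent-strategy-independent and carriers are strictly worse off,
  which forces the no-targeting outcome. Per-strain flags
  `se_A`/`se_B` apply the same convention one-sidedly (a provirus
  protected by exclusion that targeting cannot overcome gains nothing
  from its own array, while the unprotected partner still plays the
  ordinary game).

## Thresholds and classification

Every variant's invasion fitness (carrier minus non-carrier fitness at
a fixed opponent composition) is linear in the coinfection probability
`p` with intercept `-c`. The critical thresholds are its roots:
`P* = c / slope₀` against a non-targeting opponent and `P** = c /
slope₁` against a targeting one, reported as `+inf` when the slope is
non-positive (targeting never pays; needed e.g. for `w = 1` in the
late-exclusion lytic–provirus scenario). `threshold_from_payoff`
computes these roots generically from two payoff evaluations; the
closed forms in `critical_thresholds` are cross-checked against it in
the tests. Thresholds may exceed 1; they are then unreachable but still
reported (e.g. the provirus `P* ≥ 1` at `w ≥ 1/2`, and the lytic
strain's `P** = 1` in the lytic–temperate game).

Regime classification uses a single code path: the signs of
`(a, a+b, a', a'+b')`, which are provably equivalent to the threshold
comparisons (`sign(a) = sign(p - P*)`, `sign(a+b) = sign(p - P**)`;
property-tested on random draws). Corner stability follows from those
signs; one stable corner gives a pure regime, the diagonal pair gives
`bistable_mutual_or_none`, the anti-diagonal pair
`bistable_unidirectional`, and no stable corner implies an interior
neutral equilibrium at `(-a'/b', -a/b)` — the `cyclic` regime. Any
coefficient exactly zero (a coinfection probability sitting exactly on
a threshold, a measure-zero and analytically ambiguous situation —
this includes the degenerate `P* = P**` coincidence at `c = 0`) returns
the explicit `boundary` label rather than an arbitrary neighbour. An
independent oracle (`corner_stability_oracle`) re-derives corner
stability directly from the payoff-mixture fitness components and is
held equal to the classifier in the acceptance tests.

The lytic–temperate classifier needs no special casing: with
`q_L = 0`, the lytic strain's invasion fitness against a targeting
resident is `-c_L(1 - p) < 0`, so the mutual-targeting corner is never
stable; the no-targeting / unidirectional / cyclic geometry follows
from the general conditions. The cyclic late-exclusion region
(`P_T* = inf`, `P_T** = c_T`, `P_L* = c_L`) likewise emerges from the
general sign analysis.

## Numerical integration

* Default tolerances `rtol = 1e-8`, `atol = 1e-10`, adaptive LSODA,
  horizon `t_max = 1e4` generations (the cyclic orbit period at
  moderate coefficients is O(10^2)).
* **Loss-free dynamics are integrated in logit coordinates**
  `u = ln(x/(1-x))`, where the reduced system becomes
  `du_A/dt = a + b·σ(u_B)` — smooth, bounded, and free of the `x(1-x)`
  boundary degeneracy. This matters: large-amplitude cyclic orbits
  approach the faces of the unit square exponentially closely, and in
  the original coordinates every stock solver eventually underflows
  there (step size below machine spacing). In logit coordinates the
  reported fractions `σ(u)` are also confined to [0,1] by
  construction. Components started exactly on an invariant face
  (`x = 0`; `x = 1` when `d = 0`) are held there exactly.
* The replicator-mutator system (`d > 0`) is integrated in the
  original coordinates from the payoff-built fitness terms; its
  attractors are interior, away from the degeneracy. Round-off
  excursions beyond [0,1] are clamped only within 1e-12 so that real
  integrator bugs are not masked.
* **Convergence** is declared when the replicator vector-field norm
  falls below `convergence_eps = 1e-9` near (within 1e-6 of) a *stable*
  equilibrium — proximity to a saddle or to an unstable corner (which
  cyclic orbits graze) does not count. For the mutator system, whose
  isolated equilibria are not enumerated in closed form, a vanishing
  field alone suffices.
* **Cycling** is declared on a Poincaré-section return: the section is
  the horizontal line through the interior equilibrium (upward
  crossings), and a crossing within 1e-3 (Euclidean, in fractions) of a
  previous crossing counts, provided the transformed flow stayed away
  from equilibrium over the window. The cyclic regime is a *center* —
  a continuum of closed orbits whose amplitude depends on the initial
  condition — so it must not be "converged away" by a loose equilibrium
  test. The first integral
  `H = a' ln x_A - (a'+b') ln(1-x_A) - a ln x_B + (a+b) ln(1-x_B)`
  is exposed (`conserved_quantity`) to verify orbit closure; its drift
  shrinks with the solver tolerances (tested at two settings).
* `basin_classify` starts from four deterministic near-corner probes
  (0.05/0.95), guaranteeing that both basins of a bistable system are
  sampled, plus seeded uniform starts; all randomness takes an explicit
  seed.

## Spacer-loss extension

Closed forms are implemented for `w = 1/2` only, as derived; other
yields route to direct mutator simulation (a `ValueError` says so).
`P* = 2(c + d - cd)`; the second threshold for strain A divides `P*` by
`1 + x_B(1 - 2(1-c_A)(1-q_A)(1-d_A))` where `x_B = 1 - d_B/s_B` is the
opponent's polymorphic carrier fraction and
`s = (p/2 - c)/(1 - c)` the selection coefficient against array loss.
Subindex conventions (the derivation omits them): the polymorphic
factor uses the opponent's loss rate and selection coefficient; the
remaining factors use the focal strain's own parameters. Both stated
limits — reduction to the loss-free forms at `d = 0`, and
`P* = 2d`, `P** = d/(q - qd + d)` at `c = 0` to first order in `d` —
verify under this reading, and cost/loss exchangeability is
property-tested. When the opponent cannot sustain its array (`s ≤ 0`
or `d ≥ s` with `d > 0`, a case the derivation leaves open), `P**` is
reported as `+inf` with an explicit flag: a rival without a persistent
array is effectively a non-targeting rival, so only `P*` is relevant.
Nonpositive polymorphic fractions are reported as 0 (the array cannot
be maintained) with a warning, the biologically meaningful
continuation rather than an error. The small-loss bistable-topology
indicator `(1-q)(1-c)(1-d)` is evaluated per strain; the exact
bistable boundaries at large `d` are not reconstructed analytically —
`basin_classify` covers that region numerically.

## Scenario conventions

* Prose limits "`w_T ≈ 1`" and "`w_T ≪ 1`" are concretised as exact 1
  and exact 0 defaults (with user override where the scenario leaves
  the parameter free): this reproduces the stated threshold limits
  (`P_T* = inf`, `P_T** = c_T`, `P_L* = c_L`).
* In the lytic–temperate scenarios strain A is always the
  temperate/provirus resident (`q = 1`) and strain B the lytic invader
  (`q = 0`), so "`A_targets_B`" reads "the resident targets the
  invader".
* Host-genome degradation by provirus destruction is modelled only
  through the modified payoff entry, nothing else.
* Multi-virus competition is decomposed into independent ordered pairs,
  valid only for linearly scaling array cost; any other scaling raises
  `NotImplementedError`.

## Synthetic parameter draws

`generate_fixtures` draws costs uniformly on [0.01, 0.3] (matching the
empirical estimate that imperfect self-targeting costs are of order
0.1), yields and arrival probabilities uniformly on [0, 1] (rejecting
`q_A + q_B > 1`), and coinfection probabilities on [0.01, 1]. The
optional `margin` excludes draws whose invasion coefficients lie within
the margin of zero — i.e. parameter sets numerically on a regime
boundary, where classification is ill-conditioned and convergence times
diverge; it conditions the numerical cross-checks and does not bias the
covered regimes. Stratified mode rejection-samples until all seven
non-boundary labels are represented. These draws emulate parameter
uncertainty only; they do not emulate real data (no sampling noise, no
estimation step), so a green cross-check establishes internal
consistency of the analytic and numerical routes, not empirical
adequacy of the game itself.

## Known limitations

* No host/virus population dynamics: coinfection probabilities are
  static inputs, so feedbacks between targeting outcomes and virus
  abundance are outside scope.
* No spacer acquisition, protospacer escape, or finite-population
  (stochastic) effects.
* Local (linear) stability analysis only, matching the analytic
  treatment; global basins are explored numerically.
* The `boundary` label covers all threshold-coincidence cases without
  resolving them further.
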