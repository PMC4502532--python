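# Methods

## Model

A well-mixed population of `n` hardwired strategists (cooperate /
defect) plays a voluntary-contributions game in `k = n/s` groups of
equal size `s`.  Per period:

1. **Matching.** Players are ranked by their binary score, descending,
   with uniformly random tie-breaking, and filled into consecutive
   groups of `s`; lower group index = better-ranked group (an internal
   convention with no payoff consequence).  At most one "boundary"
   group mixes the two score classes.
2. **Play.** Each player commits its contribution `c_i ∈ {0, 1}` (its
   strategy) and earns `φ_i = (1 − c_i) + (r/s) Σ_{j∈group(i)} c_j`.
   The payoff identity `Σφ = n + (r − 1) Σc` holds exactly, and within
   a group a defector outearns a cooperator by exactly 1.
3. **Imitation.** `n` pairwise events: draw `i ≠ j` uniformly; `j`
   adopts `i`'s strategy with Fermi probability
   `W = 1/{1 + exp[(φ_j − φ_i)/K]}`, `K = 0.1`.  Payoffs are the
   period's committed payoffs — they are not recomputed as strategies
   flip mid-period, because contributions are committed for the whole
   period; adopted strategies take effect the next period.  One period
   therefore equals one full Monte Carlo step (each player revises once
   on average).  A `sweeps_per_period` knob exposes the
   imitation-to-rescoring ratio for sensitivity analyses.
4. **Scoring.** From the period's contributions: *image* — score 1/0
   as `c_i` is above/below the population mean, previous score retained
   on exact equality; *group* — all members of a group score 1/0 as the
   group total is above/below the mean group total (ties retain);
   *hybrid* — each agent independently follows the image rule with
   probability `p`, else the group rule.  Both updates are idempotent
   given fixed contributions, and the hybrid rule at `p ∈ {0, 1}` is
   bit-identical to the corresponding pure rule.

Timing is the one place the period structure is genuinely open: the
alternative in which payoffs are refreshed within the imitation sweep
produces a stable interior coexistence (~0.76 cooperation at `r = 4`)
under group scoring instead of extinction, and the opposite extreme
(one imitation event per rescoring) makes group scoring fixate at full
cooperation.  The committed-contribution scheme above is the one under
which image scoring fixates cooperation and group scoring drives it
extinct at the same parameters, which is the phenomenology the model
exists to capture; it is also the reading most consistent with the
formal definition of per-period contributions.

**Initial conditions.** `round(n · init_coop_fraction)` cooperators
placed uniformly at random.  Initial scores default to all-one so that
the first matching is a uniformly random partition via tie-breaking
(no strategy information leaks through initial scores); all-zero and
Bernoulli(q) initializations are available.

**Absorption.** The monomorphic states are absorbing (imitation cannot
reintroduce an absent strategy); realizations that absorb stop early
and the absorbed value is recorded for the remaining periods — an
optimization that cannot change any recorded value.

## Parameters

| symbol | meaning | constraint / default |
| --- | --- | --- |
| `n` | population size | `n = k·s` exactly |
| `s` | group size | headline value 5 |
| `r` | rate of return | `r ∈ [1, s]`; `r/s` is the marginal per-capita return |
| `p` | image-scoring probability | `[0, 1]`; hybrid only |
| `K` | Fermi imitation noise | 0.1 |
| `mc_steps` | periods per realization | desk-scale default 2000 |
| `realizations` | ensemble size | default 20 |
| `measure_window` | trailing periods averaged for the stationary estimate | final 10% of `mc_steps` |

## Mean-field class analysis

Hardwired actions with evolving scores give four classes — C1, D1, C0,
D0 — with masses summing to 1.  **Expected class payoffs** under
score-assorted matching treat masses as continuous agent counts: the
score-1 count fills the top groups, the score-0 count the bottom ones,
with one mixed boundary group of `b1 = n1 mod s` score-1 seats.  A
focal agent's groupmates cooperate with the hypergeometric probability
(pool cooperators minus self)/(pool size minus one); boundary
membership is weighted by seat counts.  This is the exact expectation
of the random matcher for integer compositions (verified against Monte
Carlo sampling in the tests) and a smooth extension otherwise.  At the
benchmark composition `p_C1 = (n−s)/n, p_D1 = 0` it reduces to
`π_C1 = r`, `π_C0 = (s − n·p_D0)(r/s)`, `π_D0 = 1 + π_C0`.

**Replicator flow.** Per class, `dp_as/dt = p_as(π_as − π̄)` with
`π̄ = Σ p_as π_as`; per action the growth rates sum to zero exactly.
The **score-transition map**, applied once per unit time, implements
the scoring rules at the class level: image sends all cooperator mass
to score 1 and all defector mass to score 0 whenever `0 < p_C < 1`
(everyone ties in the monomorphic-action cases, retaining scores);
group compares each group type's expected total with the mean group
total and moves the members' mass accordingly (fluctuations around
expected totals are ignored — the map is deterministic); hybrid is the
p-mixture.  Integration is forward Euler (`dt = 0.05` default for
plain flows, `0.02` in stability probes) with clipping at zero and
renormalization, erroring if drift exceeds 1e−6 before renormalizing.

**Fixed point.** On the benchmark slice the cooperator growth rate
vanishes at a unique interior `p_D0* ∈ (0, s/n)`; it is located by
Brent root-finding with endpoints offset in relative terms (the rate
vanishes linearly at 0, so absolute-epsilon endpoints would drown in
payoff-arithmetic roundoff).  Algebra on the benchmark payoffs gives
the closed form `p_D0* = 1/(1 + (r/s)(n − s))`, used as an independent
symbolic cross-check in the tests; cooperation at the root exceeds
`(s−1)/s` for all tested `(n, s, r)`.

**Stability probes** inject mass ε into D1 (rescaling the rest),
integrate the coupled dynamics, and report *stable* if the final
cooperator mass is at least the unperturbed level minus 2ε.  Under
image scoring the injected free-riders are demoted to D0 at the next
update and competed away; under group scoring they keep their
groupmates' reputation and grow, collapsing cooperation.  ε = 0
returns the unperturbed state with a trivially stable verdict.

## What the generator emulates — and what it does not

The simulator *is* the study system (no external data): ensembles of
seeded realizations over the parameter ranges above, with defaults
matching the headline conditions (`s = 5`, `r = 4`, `n = 1500`,
`K = 0.1`, initial cooperator fraction 0.5, all-one initial scores).
Tests and the ensemble experiments run at desk scale — `n = 150` for
the pure-rule ensembles (2000 periods, 20 realizations) and
`k ∈ {10, 50, 200, 600}` with 10 realizations for the hybrid size
sweep — sizes at which the fixation/extinction outcomes are already
deterministic across the ensemble.  Real group interactions have
features the model deliberately lacks: continuous contribution levels,
multi-level or decaying reputations, network or spatial structure,
mutation, and any mechanism explaining *how* the score ranking is
turned into groups.  Passing tests therefore certify the model's
internal claims, not external validity.

## Numerical choices

- Binary scores allow exact integer tie detection in the group rule
  (`k·group_total` vs `Σc`); image ties occur only in monomorphic
  populations.  Ties always retain the previous score.
- One seeded PCG64 stream per realization (spawned from the ensemble
  seed) covers pair selection, adoption draws, hybrid rule choices and
  matching tie-breaks, making every trajectory bit-reproducible; the
  imitation inner loop is numba-compiled with all randomness pre-drawn
  outside the kernel.
- The exponential-decay estimator fits log ensemble-mean defector
  fraction from where the mean first drops below 90% of its initial
  value until it stalls or falls below 1e−3 — beyond either point the
  mean is dominated by a handful of unabsorbed straggler realizations
  rather than by the decay.
- Critical thresholds in sweeps are operationalized as the first grid
  value whose ensemble-mean stationary cooperation exceeds 0.5.

## Known limitations

- Near the lower end of the return range (`r` close to 1, e.g. 1.1)
  cooperation collapses under *every* scoring rule at the scales
  studied: the per-period exploitation differential (up to `1 − r/s`)
  overwhelms the thin segregation benefit (`r − 1`).  Consequently the
  hybrid rule's population-size effects at `r = 1.1` manifest as
  uniform extinction; the critical-threshold structure in `p` and `r`
  (sharp drops to zero cooperation) appears at higher returns — e.g.
  at `n = 250`, `r = 4` the critical image-scoring probability is
  near `p ≈ 0.2`.
- Image-scoring fixation is likewise not uniform in `r` at desk
  scales; it is robust across `s ∈ {4, 5, 10}` and the tested `n` at
  `r = 4`.
- The mean-field group-scoring transition ignores fluctuations of
  group totals around their expectations; in finite populations those
  fluctuations leak individual-level information (one's own
  contribution shifts one's group total), which is why the stochastic
  and mean-field pictures of group scoring can differ at intermediate
  timing regimes (see Model/timing above).
- The replicator integration alternates flow and score map at unit
  period; it is a modeling choice, not a derived limit.
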