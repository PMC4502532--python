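# scorepgg

Agent-based and mean-field analysis of cooperation in **public goods
games with reputation-scored group matching**.

## The problem

Many social dilemmas are group interactions: each member of a group of
size *s* decides whether to contribute a unit of budget; contributions
are multiplied by a rate of return *r* and shared equally, so player
*i*'s payoff is

    φᵢ = (1 − cᵢ) + (r/s) · Σ_{j ∈ group(i)} cⱼ ,      cᵢ ∈ {0, 1}

With *r* ∈ [1, *s*] contributing is socially beneficial but individually
costly (marginal per-capita return *r*/*s* < 1), so one-shot selfishness
predicts universal defection — the tragedy of the commons.

Reputation can rescue cooperation if it governs who plays with whom.
Here every player carries a **binary score**, and each period the
population of *n* players is partitioned into *k* = *n*/*s* groups by
score ranking (random tie-breaking): high-score players play together.
Three information regimes set the score:

- **image scoring** — your score reflects *your own* last contribution
  relative to the population average (individual actions are public);
- **group scoring** — your score reflects *your group's* total relative
  to the average group total (only group outcomes are public, so
  defectors can hide behind cooperative groupmates);
- **hybrid scoring** — each player's score is updated by the image rule
  with probability *p* and by the group rule otherwise.

Strategies evolve by pairwise Fermi imitation: each period every player
commits its contribution, earns the period payoff, and *n* random pairs
(i, j) are drawn in which *j* adopts *i*'s strategy with probability
*W* = 1/{1 + exp[(φⱼ − φᵢ)/K]}, K = 0.1.

The package answers: when does score-mediated assortment stabilize
cooperation, and how much individual-level information (*p*) is needed?
It provides both the stochastic simulator and the mean-field replicator
analysis over the four action-score classes C1, D1, C0, D0, in which
the expected class payoffs under score-assorted matching satisfy
π_C1 = r, π_C0 = (s − n·p_D0)·r/s, π_D0 = 1 + π_C0 at the
high-cooperation benchmark state, and the cooperator mass evolves as
∂p_C/∂t = Σ_σ p_Cσ (π_Cσ − π̄).

## Worked example

Mean-field analysis at the headline parameters (s = 5, n = 1500, r = 4):

```bash
$ scorepgg analyze --n 1500 --s 5 --r 4
{
  "n": 1500, "k": 300, "s": 5, "r": 4.0,
  "stationary_p_D0_image": 0.0008354218880536046,
  "cooperation_at_fixed_point": 0.9991645781119465,
  "high_cooperation_bound": 0.8,
  "image_scoring_verdict": "stable",
  "group_scoring_verdict": "unstable",
  "limit_from_near_all_defect": 9.868438865446436e-15
}
```

Reading: universal defection is stable under every rule (a lone
cooperator class earns r/s = 0.8 < 1 and dies out — the flow from a
near-all-defect state converges to cooperator fraction ~1e-14).  Under
image scoring there is additionally an interior rest point with
p_D0\* = 1/(1 + (r/s)(n−s)) = 1/1197 ≈ 8.35·10⁻⁴ defectors confined to
the bottom group and a 99.92% cooperation level — far above the
(s−1)/s = 0.8 bound — and a perturbation injecting score-one defectors
decays (stable), because the image rule demotes them next period.
Under group scoring the same perturbation grows (unstable): free-riders
inherit their groupmates' reputation.

The stochastic counterpart (desk scale, n = 150, 20 realizations):

```python
>>> import scorepgg as sp
>>> result, summary = sp.experiment_image(n=150, mc_steps=2000,
...                                       realizations=20, seed=1)
>>> summary["stationary_mean"], summary["all_fixed_at_cooperation"]
(1.0, True)
>>> summary["defector_decay"]
{'decay_rate': 0.2976..., 'r_squared': 0.9974..., 'n_points': 12}
```

Every realization fixes at full cooperation and the ensemble defector
fraction decays exponentially (rate ≈ 0.30 per Monte Carlo step,
log-linear R² ≈ 0.997).  The same ensemble under group scoring
(`sp.experiment_group(...)`) goes extinct from initial cooperator
fractions 0.25 and 0.75 alike.  `sp.experiment_hybrid_size` and
`sp.experiment_hybrid_thresholds` sweep population sizes and the
(r, p) plane and tabulate stationary cooperation with critical-value
estimates.

CLI subcommands: `simulate`, `analyze`, `sweep`, `fixtures` (see
`scorepgg --help`); `simulate` writes a tidy trajectory CSV, a JSON
summary and a config echo from which a rerun is bit-identical.

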