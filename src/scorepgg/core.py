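"""Public goods games with reputation-scored group matching.

A well-mixed population of n agents is partitioned each period into k
groups of size s = n/k by the ranking of a binary reputation score
(random tie-breaking).  Each agent is hardwired to contribute its whole
unit budget (cooperate) or nothing (defect); a group's pot is multiplied
by the rate of return r and shared equally, so agent i's payoff is

    phi_i = (1 - c_i) + (r/s) * sum_{j in group(i)} c_j,

with r in [1, s]: contributing is socially beneficial but individually
costly.  Scores are refreshed each period by one of three rules —
*image scoring* (own contribution vs. the population average), *group
scoring* (own group's total vs. the average group total), or a *hybrid*
that applies the image rule to each agent independently with probability
p and the group rule otherwise.  Strategies evolve by pairwise Fermi
imitation with noise K: contributions are committed per period, so the
imitation events of a period compare the payoffs the period actually
produced, and adopted strategies take effect the following period.

The module is organised in the order the method runs:

1.  parameters, errors, population state;
2.  payoffs, the three scoring rules, score-ranked matching;
3.  the stochastic imitation dynamics (elementary step, Monte Carlo
    step, ensembles of realizations);
4.  the mean-field replicator analysis over the four action-score
    classes C1, D1, C0, D0 (expected class payoffs under assorted
    matching, score-transition maps, fixed points, stability probes);
5.  experiment drivers, parameter sweeps, micro-population fixtures and
    config I/O.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from numba import njit
from scipy.optimize import brentq

logger = logging.getLogger("scorepgg")

COOPERATE = 1
DEFECT = 0

#: Default imitation noise of the Fermi rule.
DEFAULT_K = 0.1

#: Scoring rules accepted throughout the module.
SCORING_RULES = ("image", "group", "hybrid")

#: Tolerance for mass bookkeeping in the mean-field analysis.
MASS_TOL = 1e-12


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (used by the CLI)."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Parameters and population state
# ---------------------------------------------------------------------------


class ParamsError(ValueError):
    """Base class for invalid game parameters."""


class DivisibilityError(ParamsError):
    """n is not an exact multiple of the number of groups k."""


class ReturnRateError(ParamsError):
    """Rate of return r outside [1, s]."""


class ProbabilityError(ParamsError):
    """Image-scoring probability p outside [0, 1]."""


class NoiseError(ParamsError):
    """Imitation noise K is not strictly positive."""


@dataclass(frozen=True)
class Params:
    """Game constants: population n, k groups of size s, return r,
    image-scoring probability p and Fermi noise K.

    Use :func:`validate_params` to construct a checked instance.
    """

    n: int
    k: int
    s: int
    r: float
    p: float = 1.0
    K: float = DEFAULT_K

    @property
    def marginal_return(self) -> float:
        """Marginal per-capita rate of return r/s."""
        return self.r / self.s


def validate_params(
    n: int | None = None,
    k: int | None = None,
    s: int | None = None,
    r: float = 4.0,
    p: float = 1.0,
    K: float = DEFAULT_K,
) -> Params:
    """Validate and complete a parameter set.

    Any two of ``n``, ``k``, ``s`` determine the third via n = k*s.

    Raises
    ------
    DivisibilityError, ReturnRateError, ProbabilityError, NoiseError
        for the corresponding violated constraint.
    """
    given = {"n": n, "k": k, "s": s}
    missing = [name for name, v in given.items() if v is None]
    if len(missing) > 1:
        raise ParamsError(f"need at least two of n, k, s; missing {missing}")
    if n is None:
        n = k * s  # type: ignore[operator]
    elif k is None:
        if n % s:  # type: ignore[operator]
            raise DivisibilityError(f"n={n} is not a multiple of s={s}")
        k = n // s  # type: ignore[operator]
    elif s is None:
        if n % k:
            raise DivisibilityError(f"n={n} is not a multiple of k={k}")
        s = n // k
    n, k, s = int(n), int(k), int(s)
    if min(n, k, s) < 1:
        raise ParamsError("n, k, s must be positive")
    if n != k * s:
        raise DivisibilityError(f"n={n} != k*s={k * s}")
    if not 1.0 <= r <= s:
        raise ReturnRateError(f"r={r} outside [1, s]=[1, {s}]")
    if not 0.0 <= p <= 1.0:
        raise ProbabilityError(f"p={p} outside [0, 1]")
    if not K > 0.0:
        raise NoiseError(f"K={K} must be > 0")
    return Params(n=n, k=k, s=s, r=float(r), p=float(p), K=float(K))


@dataclass
class PopulationState:
    """Per-agent strategy (1=cooperate, 0=defect), binary score and
    group index in [0, k) at one period."""

    strategies: np.ndarray
    scores: np.ndarray
    groups: np.ndarray

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.strategies.copy(), self.scores.copy(), self.groups.copy()
        )

    def validate(self, params: Params) -> None:
        n, k, s = params.n, params.k, params.s
        for name in ("strategies", "scores", "groups"):
            vec = getattr(self, name)
            if vec.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if not np.isin(self.strategies, (0, 1)).all():
            raise ValueError("strategies must be binary")
        if not np.isin(self.scores, (0, 1)).all():
            raise ValueError("scores must be binary")
        counts = np.bincount(self.groups, minlength=k)
        if counts.shape[0] != k or not (counts == s).all():
            raise ValueError("groups must partition agents into k groups of size s")

    @property
    def coop_fraction(self) -> float:
        return float(self.strategies.mean())

    def class_fractions(self) -> np.ndarray:
        """Masses of the four action-score classes (C1, D1, C0, D0)."""
        n = self.strategies.shape[0]
        c = self.strategies.astype(bool)
        one = self.scores.astype(bool)
        return np.array(
            [
                (c & one).sum(),
                (~c & one).sum(),
                (c & ~one).sum(),
                (~c & ~one).sum(),
            ],
            dtype=float,
        ) / n


# ---------------------------------------------------------------------------
# Payoffs, scoring rules, score-ranked matching
# ---------------------------------------------------------------------------


def group_contributions(state: PopulationState, params: Params) -> np.ndarray:
    """Total contributions per group (length-k vector)."""
    return np.bincount(state.groups, weights=state.strategies, minlength=params.k)


def compute_payoffs(state: PopulationState, params: Params) -> np.ndarray:
    """Per-agent payoffs phi_i = (1 - c_i) + (r/s) * group total.

    Keeping the unspent budget and receiving an equal share of the
    multiplied pot; contributing costs exactly one unit relative to
    defecting in the same group.
    """
    totals = group_contributions(state, params)
    c = state.strategies.astype(float)
    return (1.0 - c) + params.marginal_return * totals[state.groups]


def image_score_update(
    contributions: np.ndarray, prev_scores: np.ndarray
) -> np.ndarray:
    """Image scoring: score 1 if own contribution exceeded the population
    average, 0 if below, previous score retained on exact equality."""
    c = np.asarray(contributions)
    mean = c.mean()
    return np.where(c > mean, 1, np.where(c < mean, 0, prev_scores)).astype(
        prev_scores.dtype
    )


def group_score_update(
    contributions: np.ndarray,
    groups: np.ndarray,
    prev_scores: np.ndarray,
) -> np.ndarray:
    """Group scoring: every member of a group whose total contribution
    exceeded the average group total gets score 1; below, 0; exact
    equality retains the previous score.  Individual actions are
    invisible: all members of a group share one outcome."""
    k = int(groups.max()) + 1
    totals = np.bincount(groups, weights=contributions, minlength=k)
    mean_total = totals.mean()
    per_group = np.where(totals > mean_total, 1, np.where(totals < mean_total, 0, -1))
    out = per_group[groups]
    return np.where(out < 0, prev_scores, out).astype(prev_scores.dtype)


def hybrid_score_update(
    contributions: np.ndarray,
    groups: np.ndarray,
    prev_scores: np.ndarray,
    p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hybrid scoring: each agent independently follows the image rule
    with probability p and the group rule otherwise; p=1 and p=0 are
    bit-identical to the pure rules."""
    image = image_score_update(contributions, prev_scores)
    group = group_score_update(contributions, groups, prev_scores)
    use_image = rng.random(contributions.shape[0]) < p
    return np.where(use_image, image, group).astype(prev_scores.dtype)


def match_by_score(
    scores: np.ndarray, params: Params, rng: np.random.Generator
) -> np.ndarray:
    """Score-ranked matching: sort agents by score descending with
    uniformly random tie-breaking and fill consecutive groups of size s.
    Lower group index = better-ranked group; at most one boundary group
    mixes the two scores."""
    order = np.lexsort((rng.random(params.n), -scores))
    groups = np.empty(params.n, dtype=np.int64)
    groups[order] = np.arange(params.n) // params.s
    return groups


# ---------------------------------------------------------------------------
# Stochastic imitation dynamics
# ---------------------------------------------------------------------------


def fermi_probability(phi_j: float, phi_i: float, K: float) -> float:
    """Probability that agent j adopts agent i's strategy:
    W = 1 / (1 + exp[(phi_j - phi_i)/K]).

    Strictly decreasing in phi_j - phi_i, equal to 1/2 at equality; K
    sets the imitation noise.
    """
    x = (phi_j - phi_i) / K
    # clip for exp overflow; the probability saturates anyway
    if x > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


@njit(cache=True)
def _imitation_sweep(
    strategies: np.ndarray,
    phi: np.ndarray,
    K: float,
    ii: np.ndarray,
    jj: np.ndarray,
    uu: np.ndarray,
) -> None:
    """Sequential pairwise imitation events (in place).

    ``phi`` holds the period's payoffs, which are frozen: every agent
    committed its contribution for the whole period, so the payoff j
    compares against is what i actually earned this period even if a
    strategy was revised by an earlier event.  Adopted strategies take
    effect in the next period's play.
    """
    for t in range(ii.shape[0]):
        i = ii[t]
        j = jj[t]
        if j >= i:
            j += 1
        if strategies[i] == strategies[j]:
            continue
        x = (phi[j] - phi[i]) / K
        if x > 700.0:
            w = 0.0
        else:
            w = 1.0 / (1.0 + math.exp(x))
        if uu[t] < w:
            strategies[j] = strategies[i]


def elementary_step(
    state: PopulationState, params: Params, rng: np.random.Generator
) -> PopulationState:
    """One imitation event: draw i != j uniformly from the population;
    j adopts i's strategy with Fermi probability computed from the
    period's payoffs.  Scores and groups are untouched."""
    n = params.n
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    phi = compute_payoffs(state, params)
    w = fermi_probability(phi[j], phi[i], params.K)
    out = state.copy()
    if rng.random() < w:
        out.strategies[j] = out.strategies[i]
    return out


def _mc_step_inplace(
    state: PopulationState,
    params: Params,
    scoring: str,
    rng: np.random.Generator,
    sweeps_per_period: int = 1,
) -> None:
    """One game period = one full Monte Carlo step.

    Every agent plays its committed contribution in its matched group
    and earns the period payoff; n pairwise Fermi imitation events
    (times ``sweeps_per_period``) compare those frozen payoffs and
    revise strategies for the next period; scores are then refreshed
    from the period's contributions and groups are rematched by the new
    scores.
    """
    n = params.n
    contributions = state.strategies.copy()
    phi = compute_payoffs(state, params)
    for _ in range(sweeps_per_period):
        ii = rng.integers(0, n, size=n)
        jj = rng.integers(0, n - 1, size=n)
        uu = rng.random(n)
        _imitation_sweep(state.strategies, phi, params.K, ii, jj, uu)
    if scoring == "image":
        state.scores = image_score_update(contributions, state.scores)
    elif scoring == "group":
        state.scores = group_score_update(contributions, state.groups, state.scores)
    elif scoring == "hybrid":
        state.scores = hybrid_score_update(
            contributions, state.groups, state.scores, params.p, rng
        )
    else:
        raise ValueError(f"unknown scoring rule {scoring!r}")
    state.groups = match_by_score(state.scores, params, rng)


def monte_carlo_step(
    state: PopulationState,
    params: Params,
    rng: np.random.Generator,
    scoring: str = "image",
    sweeps_per_period: int = 1,
) -> PopulationState:
    """Pure-functional wrapper around one full Monte Carlo step: every
    agent gets on average one strategy-revision opportunity, then the
    period bookkeeping (rescore from the period's contributions,
    rematch by the new scores) runs."""
    out = state.copy()
    _mc_step_inplace(out, params, scoring, rng, sweeps_per_period)
    return out


@dataclass
class SimulationConfig:
    """Controls one ensemble: game params, scoring rule, initial
    conditions, run length and seeding.

    ``measure_window`` (trailing periods averaged for the stationary
    estimate) defaults to the final 10% of ``mc_steps``.
    ``init_scores`` is ``"ones"`` (default: the first matching is then a
    uniformly random partition via tie-breaking), ``"zeros"``, or a
    float q for i.i.d. Bernoulli(q) scores.
    """

    params: Params
    scoring: str = "image"
    init_coop_fraction: float = 0.5
    mc_steps: int = 2000
    realizations: int = 20
    seed: int = 0
    measure_window: int | None = None
    init_scores: str | float = "ones"
    sweeps_per_period: int = 1
    record_classes: bool = False

    def __post_init__(self) -> None:
        if self.scoring not in SCORING_RULES:
            raise ValueError(f"scoring must be one of {SCORING_RULES}")
        if not 0.0 <= self.init_coop_fraction <= 1.0:
            raise ValueError("init_coop_fraction outside [0, 1]")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")
        if self.measure_window is None:
            self.measure_window = max(1, self.mc_steps // 10)
        if self.measure_window > self.mc_steps + 1:
            raise ValueError("measure_window larger than the trajectory")

    @property
    def window(self) -> int:
        assert self.measure_window is not None
        return self.measure_window


def init_population(
    config: SimulationConfig, rng: np.random.Generator
) -> PopulationState:
    """Initial state: round(n * init_coop_fraction) cooperators placed
    uniformly at random, scores per config, first matching by score."""
    params = config.params
    n = params.n
    n_coop = int(round(n * config.init_coop_fraction))
    strategies = np.zeros(n, dtype=np.int64)
    strategies[rng.permutation(n)[:n_coop]] = COOPERATE
    if config.init_scores == "ones":
        scores = np.ones(n, dtype=np.int64)
    elif config.init_scores == "zeros":
        scores = np.zeros(n, dtype=np.int64)
    else:
        q = float(config.init_scores)  # type: ignore[arg-type]
        scores = (rng.random(n) < q).astype(np.int64)
    groups = match_by_score(scores, params, rng)
    return PopulationState(strategies, scores, groups)


@dataclass
class SimulationResult:
    """Ensemble output: per-realization cooperator-fraction trajectories
    (shape (realizations, mc_steps + 1)) and, optionally, class-mass
    trajectories (realizations, mc_steps + 1, 4) ordered C1, D1, C0, D0."""

    config: SimulationConfig
    trajectories: np.ndarray
    class_trajectories: np.ndarray | None = None

    @property
    def mean_trajectory(self) -> np.ndarray:
        return self.trajectories.mean(axis=0)

    def stationary_fractions(self) -> np.ndarray:
        """Per-realization stationary cooperator fraction (trailing
        measure-window mean)."""
        w = self.config.window
        return self.trajectories[:, -w:].mean(axis=1)

    def summary(self) -> dict:
        stat = self.stationary_fractions()
        return {
            "scoring": self.config.scoring,
            "n": self.config.params.n,
            "k": self.config.params.k,
            "s": self.config.params.s,
            "r": self.config.params.r,
            "p": self.config.params.p,
            "K": self.config.params.K,
            "init_coop_fraction": self.config.init_coop_fraction,
            "mc_steps": self.config.mc_steps,
            "realizations": self.config.realizations,
            "seed": self.config.seed,
            "stationary_mean": float(stat.mean()),
            "stationary_sd": float(stat.std(ddof=1)) if stat.size > 1 else 0.0,
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-period records: realization, period, coop_fraction
        (+ class masses when recorded)."""
        n_real, n_per = self.trajectories.shape
        frame = pd.DataFrame(
            {
                "realization": np.repeat(np.arange(n_real), n_per),
                "period": np.tile(np.arange(n_per), n_real),
                "coop_fraction": self.trajectories.ravel(),
            }
        )
        if self.class_trajectories is not None:
            for idx, name in enumerate(("p_C1", "p_D1", "p_C0", "p_D0")):
                frame[name] = self.class_trajectories[:, :, idx].ravel()
        return frame


def _run_realization(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    params = config.params
    state = init_population(config, rng)
    steps = config.mc_steps
    traj = np.empty(steps + 1)
    classes = np.empty((steps + 1, 4)) if config.record_classes else None
    traj[0] = state.coop_fraction
    if classes is not None:
        classes[0] = state.class_fractions()
    for t in range(1, steps + 1):
        _mc_step_inplace(state, params, config.scoring, rng, config.sweeps_per_period)
        frac = state.coop_fraction
        traj[t] = frac
        if classes is not None:
            classes[t] = state.class_fractions()
        if frac == 0.0 or frac == 1.0:
            # monomorphic states are absorbing: imitation cannot
            # reintroduce an absent strategy, so fill and stop
            traj[t + 1 :] = frac
            if classes is not None:
                classes[t + 1 :] = classes[t]
            break
    return traj, classes


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run ``realizations`` independently seeded realizations of
    ``mc_steps`` Monte Carlo steps each and collect trajectories.

    Realizations use children of ``SeedSequence(config.seed)``, so the
    whole ensemble is bit-reproducible and realizations are mutually
    independent.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.realizations)
    trajectories = np.empty((config.realizations, config.mc_steps + 1))
    classes = (
        np.empty((config.realizations, config.mc_steps + 1, 4))
        if config.record_classes
        else None
    )
    for idx, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        traj, cls = _run_realization(config, rng)
        trajectories[idx] = traj
        if classes is not None:
            classes[idx] = cls
    return SimulationResult(config, trajectories, classes)


def stationary_fraction(trajectory: np.ndarray, window: int) -> float:
    """Mean cooperator fraction over the trailing ``window`` periods."""
    trajectory = np.asarray(trajectory)
    if window < 1 or window > trajectory.shape[0]:
        raise ValueError("window must be in [1, len(trajectory)]")
    return float(trajectory[-window:].mean())


def fit_exponential_decay(
    mean_defector_fraction: np.ndarray,
    floor: float = 1e-3,
    transient_level: float = 0.9,
) -> dict:
    """Log-linear fit of the ensemble-mean defector fraction.

    The fitted range starts once the decay is underway (the mean has
    dropped below ``transient_level`` times its initial value) and stops
    at the first stall (the mean no longer decreasing) or once it falls
    below ``floor``: past either point the ensemble mean is dominated by
    a handful of unabsorbed straggler realizations rather than the
    decay itself.  Returns the decay rate per Monte Carlo step and the
    R^2 of the log-linear fit.
    """
    y = np.asarray(mean_defector_fraction, dtype=float)
    if y[0] <= 0:
        raise ValueError("no defectors to fit")
    start = int(np.argmax(y < transient_level * y[0]))
    stop = len(y)
    for t in range(start + 1, len(y)):
        if y[t] <= floor or y[t] >= y[t - 1]:
            stop = t
            break
    t = np.arange(start, stop)
    yy = y[start:stop]
    keep = yy > 0
    t, yy = t[keep], yy[keep]
    if t.size < 3:
        raise ValueError("not enough decaying points for a fit")
    from scipy.stats import linregress

    fit = linregress(t, np.log(yy))
    return {
        "decay_rate": -float(fit.slope),
        "r_squared": float(fit.rvalue**2),
        "n_points": int(t.size),
    }


# ---------------------------------------------------------------------------
# Mean-field replicator analysis over the four action-score classes
# ---------------------------------------------------------------------------

CLASS_NAMES = ("C1", "D1", "C0", "D0")


@dataclass(frozen=True)
class ClassState:
    """Masses of the four action-score classes; must sum to 1."""

    p_C1: float
    p_D1: float
    p_C0: float
    p_D0: float

    def __post_init__(self) -> None:
        masses = self.as_array()
        if (masses < -MASS_TOL).any():
            raise ValueError("class masses must be nonnegative")
        if abs(masses.sum() - 1.0) > 1e-9:
            raise ValueError("class masses must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_C1, self.p_D1, self.p_C0, self.p_D0])

    @staticmethod
    def from_array(masses: np.ndarray) -> "ClassState":
        return ClassState(*(float(m) for m in masses))

    @property
    def p_C(self) -> float:
        return self.p_C1 + self.p_C0

    @property
    def p_D(self) -> float:
        return self.p_D1 + self.p_D0


@dataclass(frozen=True)
class ClassPayoffs:
    """Expected payoffs per class and the mass-weighted average."""

    pi_C1: float
    pi_D1: float
    pi_C0: float
    pi_D0: float
    pi_bar: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_C1, self.pi_D1, self.pi_C0, self.pi_D0])


def _pool_geometry(n1: float, s: int) -> tuple[float, float]:
    """Split the score-1 head of the ranking into full groups and the
    single mixed boundary group: returns (full score-1 groups, number of
    score-1 seats in the boundary group)."""
    f1 = math.floor(n1 / s + 1e-9)
    b1 = n1 - s * f1
    if b1 < 1e-9:
        b1 = 0.0
    return f1, b1


def expected_class_payoffs(
    cs: ClassState, params: Params, rule: str | None = None
) -> ClassPayoffs:
    """Expected per-class payoffs under score-assorted matching.

    Mean-field matching model: the score-1 mass occupies the top-ranked
    groups and the score-0 mass the bottom ones, with at most one mixed
    boundary group.  Within each score pool, group composition follows
    the random tie-breaking, so a focal agent's groupmates cooperate
    with hypergeometric probability (pool cooperators minus self, over
    pool size minus one).  Masses are treated as continuous agent
    counts, which extends the finite formulas smoothly.

    ``rule`` is accepted for interface symmetry but unused: expected
    payoffs depend only on the matching, not on how scores will next be
    updated.  Payoffs of empty classes are the limits for one
    infinitesimal test agent of that class.
    """
    n, s, r = params.n, params.s, params.r
    rs = params.marginal_return
    N = cs.as_array() * n  # agent counts: C1, D1, C0, D0
    n1 = N[0] + N[1]
    n0 = N[2] + N[3]
    _, b1 = _pool_geometry(n1, s)

    def mate_coop(pool_size: float, pool_coop: float, self_c: int) -> float:
        """P(a random other member of the pool cooperates) for a focal
        agent of contribution self_c counted inside the pool."""
        if pool_size <= 1.0 + 1e-12:
            return 0.0
        return min(1.0, max(0.0, (pool_coop - self_c) / (pool_size - 1.0)))

    def payoff(score: int, c: int) -> float:
        if score == 1:
            pool, coop, other_pool, other_coop = n1, N[0], n0, N[2]
            # a test agent of an empty score-1 pool sits in the boundary
            eff_pool = max(pool, 1.0)
            q_own = mate_coop(eff_pool, coop + (0 if pool >= 1 else c), c)
            if b1 == 0.0 and pool >= 1.0:
                w_boundary = 0.0
                seats = float(s)
            else:
                seats = b1 if pool >= 1.0 else 1.0
                w_boundary = seats / eff_pool
            q_other = other_coop / other_pool if other_pool > 1e-12 else 0.0
            t_interior = c + (s - 1) * q_own
            t_boundary = c + max(seats - 1.0, 0.0) * q_own + (s - seats) * q_other
        else:
            pool, coop, other_pool, other_coop = n0, N[2], n1, N[0]
            eff_pool = max(pool, 1.0)
            q_own = mate_coop(eff_pool, coop + (0 if pool >= 1 else c), c)
            seats1 = b1  # score-1 seats in the boundary group
            if seats1 == 0.0:
                w_boundary = 0.0
                t_boundary = 0.0
                t_interior = c + (s - 1) * q_own
            else:
                seats0 = s - seats1
                w_boundary = seats0 / eff_pool
                q_other = other_coop / other_pool if other_pool > 1e-12 else 0.0
                t_interior = c + (s - 1) * q_own
                t_boundary = c + max(seats0 - 1.0, 0.0) * q_own + seats1 * q_other
        expected_total = (1.0 - w_boundary) * t_interior + w_boundary * t_boundary
        return (1.0 - c) + rs * expected_total

    pi = np.array(
        [payoff(1, 1), payoff(1, 0), payoff(0, 1), payoff(0, 0)]
    )
    pi_bar = float(cs.as_array() @ pi)
    return ClassPayoffs(*(float(x) for x in pi), pi_bar)


def replicator_derivative(
    cs: ClassState, payoffs: ClassPayoffs
) -> tuple[float, float]:
    """Per-action growth rates (dp_C/dt, dp_D/dt): each action grows by
    the mass-weighted payoff excess of its score classes over the
    population average; the two rates sum to zero."""
    dp_C = cs.p_C1 * (payoffs.pi_C1 - payoffs.pi_bar) + cs.p_C0 * (
        payoffs.pi_C0 - payoffs.pi_bar
    )
    dp_D = cs.p_D1 * (payoffs.pi_D1 - payoffs.pi_bar) + cs.p_D0 * (
        payoffs.pi_D0 - payoffs.pi_bar
    )
    return dp_C, dp_D


def _class_growth(cs: ClassState, params: Params) -> np.ndarray:
    """Per-class replicator velocities dp_as/dt = p_as (pi_as - pi_bar)."""
    pay = expected_class_payoffs(cs, params)
    return cs.as_array() * (pay.as_array() - pay.pi_bar)


def reference_state(params: Params, p_D0: float) -> ClassState:
    """The high-cooperation benchmark composition: all but one group's
    worth of agents are score-1 cooperators (p_C1 = (n-s)/n, p_D1 = 0)
    and the bottom group splits s/n between C0 and D0."""
    s_over_n = params.s / params.n
    if not 0.0 <= p_D0 <= s_over_n:
        raise ValueError("p_D0 must lie in [0, s/n]")
    return ClassState(
        (params.n - params.s) / params.n, 0.0, s_over_n - p_D0, p_D0
    )


def stationary_pD0_image(params: Params) -> float:
    """The defector mass p_D0* in the bottom group at which cooperator
    growth vanishes on the benchmark slice (p_C1 = (n-s)/n, p_D1 = 0,
    p_C0 = s/n - p_D0), found by root bracketing on (0, s/n).

    At the root the overall cooperation level 1 - p_D0* exceeds
    (s-1)/s, the high-cooperation bound.
    """

    def growth(x: float) -> float:
        cs = reference_state(params, x)
        return replicator_derivative(cs, expected_class_payoffs(cs, params))[0]

    s_over_n = params.s / params.n
    # endpoints offset in relative terms: the growth rate vanishes
    # linearly at 0, so an absolute-epsilon endpoint would drown in
    # roundoff of the payoff arithmetic
    lo, hi = s_over_n * 1e-8, s_over_n * (1.0 - 1e-8)
    g_lo, g_hi = growth(lo), growth(hi)
    if g_lo * g_hi > 0:
        raise ValueError("no sign change: no interior root in (0, s/n)")
    return float(brentq(growth, lo, hi, xtol=1e-16, rtol=8.9e-16))


def score_transition(cs: ClassState, params: Params, rule: str) -> ClassState:
    """Mean-field score-transition map for one period, per scoring rule.

    * image: every cooperator contributed 1 > mean (when 0 < p_C < 1)
      so all C mass gets score 1 and all D mass score 0; in the
      degenerate monomorphic-action cases everyone matches the mean and
      scores are retained.
    * group: the assorted groups' expected totals are compared with the
      average group total; each group type's members move to score 1/0
      (ties retain).  Deterministic mean-field: composition fluctuations
      around the expected totals are ignored.
    * hybrid: per-agent Bernoulli(p) mixture of the two maps.
    """
    if rule == "image":
        return _image_transition(cs)
    if rule == "group":
        return _group_transition(cs, params)
    if rule == "hybrid":
        img = _image_transition(cs).as_array()
        grp = _group_transition(cs, params).as_array()
        return ClassState.from_array(params.p * img + (1.0 - params.p) * grp)
    raise ValueError(f"unknown scoring rule {rule!r}")


def _image_transition(cs: ClassState) -> ClassState:
    p_C = cs.p_C
    if p_C <= 0.0 or p_C >= 1.0:
        return cs  # everyone equals the mean contribution: retain
    return ClassState(p_C, 0.0, 0.0, 1.0 - p_C)


def _group_transition(cs: ClassState, params: Params) -> ClassState:
    n, s = params.n, params.s
    N = cs.as_array() * n
    n1 = N[0] + N[1]
    n0 = N[2] + N[3]
    _, b1 = _pool_geometry(n1, s)
    q1 = N[0] / n1 if n1 > 1e-12 else 0.0
    q0 = N[2] / n0 if n0 > 1e-12 else 0.0
    mean_total = s * cs.p_C

    def outcome(total: float) -> int:
        # 1 / 0 / -1 (retain) with an absolute tolerance on expected totals
        if total > mean_total + MASS_TOL:
            return 1
        if total < mean_total - MASS_TOL:
            return 0
        return -1

    out_interior1 = outcome(s * q1)
    out_boundary = outcome(b1 * q1 + (s - b1) * q0)
    out_interior0 = outcome(s * q0)

    # membership weights within each score pool
    w1b = b1 / n1 if n1 > 1e-12 else 0.0
    w0b = (s - b1) / n0 if (b1 > 0.0 and n0 > 1e-12) else 0.0

    new = np.zeros(4)

    def deposit(mass: float, action: str, prev_score: int, out: int) -> None:
        score = prev_score if out == -1 else out
        idx = {("C", 1): 0, ("D", 1): 1, ("C", 0): 2, ("D", 0): 3}[(action, score)]
        new[idx] += mass

    deposit(cs.p_C1 * (1 - w1b), "C", 1, out_interior1)
    deposit(cs.p_C1 * w1b, "C", 1, out_boundary)
    deposit(cs.p_D1 * (1 - w1b), "D", 1, out_interior1)
    deposit(cs.p_D1 * w1b, "D", 1, out_boundary)
    deposit(cs.p_C0 * w0b, "C", 0, out_boundary)
    deposit(cs.p_C0 * (1 - w0b), "C", 0, out_interior0)
    deposit(cs.p_D0 * w0b, "D", 0, out_boundary)
    deposit(cs.p_D0 * (1 - w0b), "D", 0, out_interior0)
    return ClassState.from_array(new)


def integrate_replicator(
    initial: ClassState,
    params: Params,
    rule: str,
    horizon: int = 500,
    dt: float = 0.05,
) -> list[ClassState]:
    """Forward-integrate the coupled class dynamics: per unit time, an
    Euler pass of the per-class replicator flow followed by one
    application of the rule's score-transition map.  Masses are clipped
    at zero and renormalized each substep (error if the drift exceeds
    1e-6 before renormalization).  Returns the per-period trajectory
    (including the initial state)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    substeps = max(1, round(1.0 / dt))
    traj = [initial]
    cs = initial
    for _ in range(horizon):
        masses = cs.as_array()
        for _ in range(substeps):
            masses = masses + dt * _class_growth(ClassState.from_array(masses), params)
            masses = np.clip(masses, 0.0, None)
            total = masses.sum()
            if abs(total - 1.0) > 1e-6:
                raise FloatingPointError("mass normalization failure")
            masses = masses / total
        cs = score_transition(ClassState.from_array(masses), params, rule)
        traj.append(cs)
        p_C = cs.p_C
        if p_C < 1e-14 or p_C > 1.0 - 1e-14:
            break
    return traj


@dataclass(frozen=True)
class StabilityReport:
    """Verdict of a perturbation probe plus the diagnostic trajectory."""

    stable: bool
    verdict: str
    trajectory: list[ClassState]


def stability_probe(
    cs: ClassState,
    params: Params,
    rule: str,
    epsilon: float = 1e-4,
    horizon: int = 300,
    dt: float = 0.02,
) -> StabilityReport:
    """Perturb a state by injecting mass ``epsilon`` into the score-one
    defector class D1 (scaling the rest down), integrate the coupled
    class dynamics, and report whether cooperation persists.

    Verdict: *stable* if the final cooperator mass is at least the
    unperturbed level minus the perturbation size (the defector
    incursion decays), *unstable* if cooperators lose ground.  Under
    image scoring the injected D1 mass is demoted to D0 by the next
    score update and then competed away; under group scoring it keeps
    its score-one groupmates' reputation and grows.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if epsilon == 0.0:
        return StabilityReport(True, "stable", [cs])
    masses = cs.as_array() * (1.0 - epsilon)
    masses[1] += epsilon
    perturbed = ClassState.from_array(masses)
    traj = integrate_replicator(perturbed, params, rule, horizon=horizon, dt=dt)
    final_p_C = traj[-1].p_C
    stable = final_p_C >= cs.p_C - 2.0 * epsilon
    return StabilityReport(stable, "stable" if stable else "unstable", traj)


# ---------------------------------------------------------------------------
# Experiments, sweeps, fixtures and config I/O
# ---------------------------------------------------------------------------


def _merge_geometry(defaults: dict, overrides: dict) -> dict:
    """Combine default and user-supplied population geometry (n, k, s):
    user keys win; defaults fill in until the geometry is determined."""
    geo = {key: overrides.pop(key) for key in ("n", "k", "s") if key in overrides}
    for key, val in defaults.items():
        if len(geo) >= 2:
            break
        if key not in geo:
            geo[key] = val
    return geo


def experiment_image(**overrides) -> tuple[SimulationResult, dict]:
    """Image-scoring baseline: cooperators rise to complete dominance
    and the defector fraction decays exponentially.

    Defaults: s=5, n=1500, r=4 (override ``n``/``k``/``s`` etc. to scale
    down).  The summary reports the per-realization stationary
    fractions and the fitted exponential decay of the ensemble defector
    fraction.
    """
    geo = _merge_geometry({"s": 5, "n": 1500}, overrides)
    config = _build_config(
        scoring="image",
        **geo,
        **{"r": 4.0, "p": 1.0, **overrides},
    )
    result = run_simulation(config)
    summary = result.summary()
    try:
        summary["defector_decay"] = fit_exponential_decay(1.0 - result.mean_trajectory)
    except ValueError:
        summary["defector_decay"] = None
    summary["all_fixed_at_cooperation"] = bool(
        (result.stationary_fractions() == 1.0).all()
    )
    return result, summary


def experiment_group(
    init_fractions: Sequence[float] = (0.25, 0.75), **overrides
) -> tuple[list[SimulationResult], dict]:
    """Group-scoring baseline: cooperators die out irrespective of the
    initial cooperator fraction (two initial fractions by default)."""
    results = []
    geo = _merge_geometry({"s": 5, "n": 1500}, overrides)
    for init in init_fractions:
        config = _build_config(
            scoring="group",
            **geo,
            **{"r": 4.0, "p": 0.0, **overrides, "init_coop_fraction": init},
        )
        results.append(run_simulation(config))
    summary = {
        "init_fractions": list(init_fractions),
        "stationary_means": [float(r.stationary_fractions().mean()) for r in results],
        "all_extinct": bool(
            all((r.stationary_fractions() == 0.0).all() for r in results)
        ),
    }
    return results, summary


def experiment_hybrid_size(
    k_grid: Sequence[int] = (10, 50, 200, 600),
    survival_threshold: float = 0.5,
    **overrides,
) -> pd.DataFrame:
    """Hybrid scoring at a minute image-scoring probability: sweep the
    number of groups k (hence the population size n = k*s) and record
    stationary cooperation and the per-cell survival frequency.
    Defaults p=0.01, s=5, r=1.1.
    """
    rows = []
    s = overrides.pop("s", 5)
    for k in k_grid:
        config = _build_config(
            scoring="hybrid", k=k, s=s, **{"r": 1.1, "p": 0.01, **overrides}
        )
        result = run_simulation(config)
        stat = result.stationary_fractions()
        rows.append(
            {
                "n": config.params.n,
                "k": config.params.k,
                "s": config.params.s,
                "r": config.params.r,
                "p": config.params.p,
                "coop_mean": float(stat.mean()),
                "coop_sd": float(stat.std(ddof=1)) if stat.size > 1 else 0.0,
                "survival_frequency": float((stat > survival_threshold).mean()),
                "realizations": config.realizations,
                "seed": config.seed,
            }
        )
    return pd.DataFrame(rows)


def experiment_hybrid_thresholds(
    k_grid: Sequence[int] = (10, 50, 200),
    r_grid: Sequence[float] = (1.1, 1.5, 2.0, 3.0, 4.0),
    p_grid: Sequence[float] = (0.002, 0.01, 0.05, 0.2, 1.0),
    **overrides,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phase structure of hybrid scoring: a main sweep over r at
    p=0.01 and an inset sweep over p at r=1.1, for several k.

    Returns the full phase table and a per-k table of estimated
    critical thresholds (first grid value whose ensemble-mean
    stationary fraction exceeds 0.5) for r and p; NaN where cooperation
    never prevails on the grid.
    """
    rows = []
    s = overrides.pop("s", 5)
    for k in k_grid:
        for r in r_grid:
            cfg = _build_config(scoring="hybrid", k=k, s=s, r=r, p=0.01, **overrides)
            rows.append(_phase_row(cfg, sweep="r"))
        for p in p_grid:
            cfg = _build_config(scoring="hybrid", k=k, s=s, r=1.1, p=p, **overrides)
            rows.append(_phase_row(cfg, sweep="p"))
    table = pd.DataFrame(rows)
    crit = []
    for k in k_grid:
        sub_r = table[(table.sweep == "r") & (table.k == k)].sort_values("r")
        sub_p = table[(table.sweep == "p") & (table.k == k)].sort_values("p")
        crit.append(
            {
                "k": k,
                "critical_r": _first_exceeding(sub_r, "r"),
                "critical_p": _first_exceeding(sub_p, "p"),
            }
        )
    return table, pd.DataFrame(crit)


def _phase_row(config: SimulationConfig, sweep: str) -> dict:
    result = run_simulation(config)
    stat = result.stationary_fractions()
    return {
        "sweep": sweep,
        "n": config.params.n,
        "k": config.params.k,
        "s": config.params.s,
        "r": config.params.r,
        "p": config.params.p,
        "coop_mean": float(stat.mean()),
        "coop_sd": float(stat.std(ddof=1)) if stat.size > 1 else 0.0,
        "realizations": config.realizations,
        "seed": config.seed,
    }


def _first_exceeding(sub: pd.DataFrame, column: str, level: float = 0.5):
    hit = sub[sub.coop_mean > level]
    return float(hit.iloc[0][column]) if len(hit) else float("nan")


def _build_config(
    scoring: str,
    n: int | None = None,
    k: int | None = None,
    s: int | None = None,
    r: float = 4.0,
    p: float = 1.0,
    K: float = DEFAULT_K,
    init_coop_fraction: float = 0.5,
    mc_steps: int = 2000,
    realizations: int = 20,
    seed: int = 0,
    **rest,
) -> SimulationConfig:
    params = validate_params(n=n, k=k, s=s, r=r, p=p, K=K)
    return SimulationConfig(
        params=params,
        scoring=scoring,
        init_coop_fraction=init_coop_fraction,
        mc_steps=mc_steps,
        realizations=realizations,
        seed=seed,
        **rest,
    )


# Deterministic micro-populations for unit tests and worked examples.
def _fixture_lone_cooperator() -> tuple[PopulationState, Params]:
    params = validate_params(n=25, s=5, r=4.0)
    strategies = np.zeros(25, dtype=np.int64)
    strategies[0] = COOPERATE
    scores = np.ones(25, dtype=np.int64)
    groups = np.arange(25) // 5
    return PopulationState(strategies, scores, groups), params


def _fixture_two_groups_split() -> tuple[PopulationState, Params]:
    params = validate_params(n=10, s=5, r=4.0)
    strategies = np.array([1] * 5 + [0] * 5, dtype=np.int64)
    scores = np.array([1] * 5 + [0] * 5, dtype=np.int64)
    groups = np.arange(10) // 5
    return PopulationState(strategies, scores, groups), params


def _fixture_boundary_tie() -> tuple[PopulationState, Params]:
    # seven score-1 agents for ten seats: the second group mixes and the
    # matcher must break ties among the seven at random
    params = validate_params(n=10, s=5, r=4.0)
    strategies = np.array([1] * 7 + [0] * 3, dtype=np.int64)
    scores = np.array([1] * 7 + [0] * 3, dtype=np.int64)
    groups = np.arange(10) // 5
    return PopulationState(strategies, scores, groups), params


FIXTURES: dict[str, Callable[[], tuple[PopulationState, Params]]] = {
    "lone_cooperator": _fixture_lone_cooperator,
    "two_groups_split": _fixture_two_groups_split,
    "boundary_tie": _fixture_boundary_tie,
}


def make_fixture(name: str) -> tuple[PopulationState, Params]:
    """Return a named deterministic micro-population (state, params)."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return factory()


def load_config(path: str | Path, **overrides) -> SimulationConfig:
    """Build a SimulationConfig from a flat YAML/JSON mapping, with
    keyword overrides (CLI flags) taking precedence."""
    raw: dict = {}
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    scoring = raw.pop("scoring", "image")
    return _build_config(scoring=scoring, **raw)


def write_outputs(
    result: SimulationResult, out: str | Path, echo: Mapping | None = None
) -> None:
    """Write a tidy trajectory CSV, a JSON summary and a config echo
    next to ``out`` (a basename; suffixes .csv/.json/.config.json are
    appended).  Rerunning from the echo reproduces the CSV bit-exactly."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out.with_suffix(".csv"), index=False)
    with open(out.with_suffix(".json"), "w") as fh:
        json.dump(result.summary(), fh, indent=2)
    with open(out.with_suffix(".config.json"), "w") as fh:
        json.dump(dict(echo) if echo is not None else result.summary(), fh, indent=2)
    logger.info("wrote %s.{csv,json,config.json}", out)
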