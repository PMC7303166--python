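"""Payoffs, fitness, environment feedback, and the Moran death-birth update.

The model
---------
Each agent i carries a strategy x_i in [0, 1]: the probability of engaging in
controlled (deliberative, costly, flexible) rather than automatic (reflexive,
cheap, inflexible) cognitive processing.  Payoffs per generation t are

    pi_C = 1 - c + w * (1 - <x>_{i,t})        controlled processing
    pi_A = 1 - p_{i,t}                        automatic processing

where c is the fixed cost of control, w the impact of contact with automatic
agents on controlled agents (harmful if w < 0, beneficial if w > 0),
<x>_{i,t} the mean strategy of agent i's contact neighbourhood including i
itself, and p the state of the environment — the relative decision-making
advantage of control.  Fitness is the strategy-weighted mixture

    f_{i,t} = x_i * pi_C + (1 - x_i) * pi_A.

The environment relaxes toward 1 - <x> with time-lag tau_p:

    p_t = p_{t-1} + ((1 - <x>_{t-1}) - p_{t-1}) / tau_p

computed population-wide (a single scalar p; "global environment") or per
agent over the including-self neighbourhood ("local environment").  tau_p = 1
recovers the instantaneous feedback p_t = 1 - <x>_{t-1}.

Strategies evolve by a Moran death-birth process: each generation one learner
is drawn uniformly at random; with probability u it mutates to a uniform
random strategy, otherwise it copies a teacher drawn from its learning pool
with probability proportional to exp(s * fitness), s being the intensity of
selection.

Each of the three interaction dimensions — learning, contact, environment —
is independently *local* (restricted to network neighbours) or *global*
(whole population), giving the 2**3 = 8 scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Literal

import numpy as np

from .topology import Topology

__all__ = [
    "Params",
    "Scenario",
    "PopulationState",
    "contact_mean",
    "payoff_controlled",
    "payoff_automatic",
    "fitness",
    "fitness_all",
    "update_environment",
    "teacher_probabilities",
    "select_teacher",
    "moran_step",
]

Scope = Literal["local", "global"]


@dataclass(frozen=True)
class Params:
    """Model constants.

    c : fixed cost of controlled processing (payoff units).
    w : impact of automatic processing on the payoff of control; may be
        negative (automatics harm controls) or positive (controls profit
        from automatics).
    s : intensity of selection (softmax temperature of teacher choice);
        s = 0 is neutral drift.
    u : mutation probability per learning event.
    tau_p : time-lag of cognition-environment feedback, >= 1.
    """

    c: float = 0.5
    w: float = -0.15
    s: float = 10.0
    u: float = 0.01
    tau_p: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.u <= 1.0):
            raise ValueError(f"mutation rate u must lie in [0, 1], got {self.u}")
        if self.s < 0:
            raise ValueError(f"selection intensity s must be >= 0, got {self.s}")
        if self.tau_p < 1:
            raise ValueError(f"environment lag tau_p must be >= 1, got {self.tau_p}")
        for name in ("c", "w", "s", "u", "tau_p"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")
        if not (0.0 <= self.c <= 1.0) or abs(self.w) > 1.0:
            warnings.warn(
                f"c={self.c}, w={self.w} outside the studied ranges; payoffs "
                "may leave [0, 1]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Scenario:
    """Local/global scope of each interaction dimension."""

    learning: Scope = "local"
    contact: Scope = "local"
    environment: Scope = "local"

    def __post_init__(self):
        for dim in ("learning", "contact", "environment"):
            v = getattr(self, dim)
            if v not in ("local", "global"):
                raise ValueError(f"{dim} scope must be 'local' or 'global', got {v!r}")

    @classmethod
    def fully_local(cls) -> "Scenario":
        return cls("local", "local", "local")

    @classmethod
    def fully_global(cls) -> "Scenario":
        return cls("global", "global", "global")

    @classmethod
    def all_scenarios(cls) -> tuple["Scenario", ...]:
        """All 8 combinations, fully-local first, fully-global last."""
        return tuple(
            cls(l, c, e)
            for l, c, e in product(("local", "global"), repeat=3)
        )

    @classmethod
    def from_string(cls, text: str) -> "Scenario":
        """Parse ``"local,global,local"`` as (learning, contact, environment)."""
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 3:
            raise ValueError(
                "scenario string must have 3 comma-separated scopes "
                "(learning,contact,environment)"
            )
        return cls(*parts)

    @property
    def tag(self) -> str:
        """Compact label, e.g. ``LGL`` = local learning, global contact, local env."""
        return "".join(getattr(self, d)[0].upper() for d in ("learning", "contact", "environment"))


@dataclass
class PopulationState:
    """Strategies, environment, and generation counter.

    ``p`` is a scalar under a global environment and a per-agent array under
    a local one; both stay in [0, 1] because the update is a convex
    combination for tau_p >= 1.
    """

    x: np.ndarray
    p: float | np.ndarray
    t: int = 0

    def copy(self) -> "PopulationState":
        p = self.p if np.isscalar(self.p) else np.array(self.p)
        return PopulationState(np.array(self.x), p, self.t)

    @classmethod
    def initial(cls, n: int, scenario: Scenario, x0: float = 0.01,
                p0: float | None = None) -> "PopulationState":
        """Homogeneous start: x_i = x0 and p = p0 (default 1 - x0, the
        environment consistent with the initial strategies)."""
        x = np.full(n, float(x0))
        if p0 is None:
            p0 = 1.0 - float(x0)
        p = float(p0) if scenario.environment == "global" else np.full(n, float(p0))
        return cls(x=x, p=p, t=0)


# ---------------------------------------------------------------------------
# payoffs and fitness


def contact_mean(state: PopulationState, top: Topology, scenario: Scenario, i: int) -> float:
    """Mean strategy of agent i's contact pool (neighbours + self if local,
    whole population if global)."""
    if not (0 <= i < top.n_agents):
        raise IndexError(f"agent index {i} out of range")
    if scenario.contact == "global":
        return float(state.x.mean())
    nbrs = top.neighbors(i)
    return float((state.x[nbrs].sum() + state.x[i]) / (len(nbrs) + 1))


def payoff_controlled(params: Params, xbar: float):
    """Payoff of controlled processing: 1 - c + w * (1 - xbar)."""
    return 1.0 - params.c + params.w * (1.0 - xbar)


def payoff_automatic(p):
    """Payoff of automatic processing: 1 - p."""
    return 1.0 - p


def _fitness_from_means(x, c: float, w: float, m_contact, p):
    # single formula shared by the scalar and vectorized fitness paths
    return x * (1.0 - c + w * (1.0 - m_contact)) + (1.0 - x) * (1.0 - p)


def fitness(state: PopulationState, top: Topology, scenario: Scenario,
            params: Params, i: int) -> float:
    """Fitness of agent i: x_i * pi_C + (1 - x_i) * pi_A."""
    m = contact_mean(state, top, scenario, i)
    p_i = state.p if np.isscalar(state.p) else state.p[i]
    return float(_fitness_from_means(state.x[i], params.c, params.w, m, p_i))


def fitness_all(state: PopulationState, top: Topology, scenario: Scenario,
                params: Params, contact_means=None) -> np.ndarray:
    """Vector of all agents' fitnesses.

    ``contact_means`` may carry precomputed contact-pool means (a scalar for
    global contact, a per-agent array for local) to avoid recomputation in
    tight loops.
    """
    if contact_means is None:
        if scenario.contact == "global":
            contact_means = state.x.mean()
        else:
            contact_means = top.neighborhood_mean(state.x, include_self=True)
    return _fitness_from_means(state.x, params.c, params.w, contact_means, state.p)


# ---------------------------------------------------------------------------
# environment feedback


def update_environment(state: PopulationState, top: Topology, scenario: Scenario,
                       params: Params, neighbor_means=None) -> PopulationState:
    """Relax p toward 1 - <x> with lag tau_p (in place; returns the state).

    Local environment: p_i += ((1 - <x>_i) - p_i) / tau_p with <x>_i over the
    including-self neighbourhood.  Global: the single p relaxes toward
    1 - <x> with <x> the population mean.  With tau_p = 1 the update lands
    exactly on 1 - <x>.
    """
    tau = params.tau_p
    if scenario.environment == "global":
        xbar = float(state.x.mean())
        state.p = float(state.p + ((1.0 - xbar) - state.p) / tau)
    else:
        if neighbor_means is None:
            neighbor_means = top.neighborhood_mean(state.x, include_self=True)
        state.p += ((1.0 - neighbor_means) - state.p) / tau
    return state


# ---------------------------------------------------------------------------
# Moran death-birth update


def teacher_probabilities(fitnesses, s: float) -> np.ndarray:
    """Softmax selection probabilities exp(s*f) / sum(exp(s*f)).

    The maximum is subtracted before exponentiation, so the result is
    invariant to adding any constant to all fitnesses and does not overflow
    at strong selection.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("empty candidate set")
    z = np.exp(s * (f - f.max()))
    return z / z.sum()


def _weighted_index(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Inverse-CDF draw from unnormalized nonnegative weights (one uniform).

    ``side='right'`` makes zero-weight entries unreachable, so masking a
    candidate by zeroing its weight is equivalent to removing it.
    """
    cum = np.cumsum(weights)
    r = rng.random() * cum[-1]
    return int(np.searchsorted(cum, r, side="right"))


def select_teacher(fitnesses, candidates, s: float, rng: np.random.Generator) -> int:
    """Draw a teacher from ``candidates`` with probability prop. to exp(s*f)."""
    candidates = np.asarray(list(candidates) if not isinstance(candidates, np.ndarray)
                            else candidates, dtype=np.intp)
    if candidates.size == 0:
        raise ValueError("empty candidate set")
    f = np.asarray(fitnesses, dtype=float)
    if f.shape[0] != candidates.shape[0]:
        raise ValueError("fitnesses and candidates must align")
    z = np.exp(s * (f - f.max()))
    return int(candidates[_weighted_index(z, rng)])


def moran_step(state: PopulationState, top: Topology, scenario: Scenario,
               params: Params, rng: np.random.Generator,
               contact_means=None) -> PopulationState:
    """One death-birth event (in place; returns the state).

    RNG draw order per generation, fixed for reproducibility:

    1. learner index, uniform over agents;
    2. one uniform for the mutation coin;
    3. if mutating: one uniform, the learner's new strategy;
       else: one uniform for the inverse-CDF teacher draw.

    The teacher pool excludes the learner: its network neighbours under
    local learning, all other agents under global learning.  Exactly one
    strategy entry may change; the generation counter increments.
    """
    n = top.n_agents
    x = state.x
    learner = int(rng.integers(n))

    if rng.random() < params.u:
        x[learner] = rng.random()
        state.t += 1
        return state

    if scenario.learning == "global":
        f = fitness_all(state, top, scenario, params, contact_means=contact_means)
        z = np.exp(params.s * (f - f.max()))
        z[learner] = 0.0
        teacher = _weighted_index(z, rng)
    else:
        pool = top.neighbors(learner)
        if contact_means is None:
            if scenario.contact == "global":
                m_pool = x.mean()
            else:
                m_pool = top.neighborhood_mean(x, include_self=True)[pool]
        elif np.isscalar(contact_means) or np.ndim(contact_means) == 0:
            m_pool = contact_means
        else:
            m_pool = contact_means[pool]
        p_pool = state.p if np.isscalar(state.p) else state.p[pool]
        f = _fitness_from_means(x[pool], params.c, params.w, m_pool, p_pool)
        z = np.exp(params.s * (f - f.max()))
        teacher = int(pool[_weighted_index(z, rng)])

    x[learner] = x[teacher]
    state.t += 1
    return state
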