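"""Two-species resource-trade lifecycle model.

A plant and a mycorrhizal fungus repeatedly gather carbon (C) and
phosphorus (P), exchange fixed fractions of their specialised resource,
and grow by Liebig's law of the minimum over a short shared lifetime.
The plant is the C specialist (uptake equal to its biomass each step)
and acquires P at efficiency ``alpha`` per unit biomass; the fungus is
the P specialist and acquires C at efficiency ``beta``.  The heritable
trading strategy is the pair ``(gamma, epsilon)``: the fraction of the
plant's gathered C given to the fungus and of the fungus's gathered P
given to the plant.  Negative fractions mean the organism *takes* its
specialised resource from its partner, clamped so it can never take
more than the partner gathered that step.

With both strategy components non-negative the per-step recursion is

    X[n+1] = X[n] + min(alpha*X[n] + eps*Y[n], X[n]*(1 - gamma))
    Y[n+1] = Y[n] + min(Y[n]*(1 - eps),  beta*Y[n] + gamma*X[n])

from X[0] = Y[0] = 1; final biomass after ``T`` steps (default 10) is
the organism's fitness.  Resources are not stored between steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GROWTH_TOL",
    "UptakeEfficiencies",
    "ExchangeStrategy",
    "StepOutcome",
    "LifecycleResult",
    "resolve_exchange",
    "simulate_lifecycle",
    "closed_form_fitness",
    "lifecycle_arrays",
]

#: An organism "grew" iff its final biomass exceeds 1 by more than this
#: absolute tolerance (guards float noise at the no-growth boundary).
GROWTH_TOL = 1e-12

DEFAULT_TIMESTEPS = 10


@dataclass(frozen=True)
class UptakeEfficiencies:
    """Fixed environment pair: nonspecialised uptake per unit biomass.

    ``alpha`` is the plant's P uptake efficiency and ``beta`` the
    fungus's C uptake efficiency, both fractions in [0, 1].
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")


@dataclass(frozen=True)
class ExchangeStrategy:
    """Heritable trait pair (gamma, epsilon), fractions in [-1, 1].

    ``gamma`` is the share of the plant's gathered C given to the fungus
    and ``epsilon`` the share of the fungus's gathered P given to the
    plant; negative values mean the resource is taken from the partner.
    """

    gamma: float
    epsilon: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must lie in [-1, 1], got {self.gamma}")
        if not (-1.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon must lie in [-1, 1], got {self.epsilon}")


@dataclass(frozen=True)
class StepOutcome:
    """Ledger of a single gather/exchange/grow timestep.

    Transfers are signed: ``c_transfer`` > 0 moves C from plant to
    fungus, ``p_transfer`` > 0 moves P from fungus to plant; both are
    post-clamp amounts actually moved.
    """

    plant_c_pool: float
    plant_p_pool: float
    fungus_c_pool: float
    fungus_p_pool: float
    c_transfer: float
    p_transfer: float
    plant_growth: float
    fungus_growth: float


@dataclass(frozen=True)
class LifecycleResult:
    """Trajectories, transfers and final fitnesses of one paired lifetime."""

    plant_biomass: np.ndarray  # X_0..X_T
    fungus_biomass: np.ndarray  # Y_0..Y_T
    c_transfers: np.ndarray  # length T, signed
    p_transfers: np.ndarray  # length T, signed
    T: int

    @property
    def plant_fitness(self) -> float:
        return float(self.plant_biomass[-1])

    @property
    def fungus_fitness(self) -> float:
        return float(self.fungus_biomass[-1])

    @property
    def total_c_to_fungus(self) -> float:
        """Net signed C moved plant->fungus over the lifetime."""
        return float(self.c_transfers.sum())

    @property
    def total_p_to_plant(self) -> float:
        """Net signed P moved fungus->plant over the lifetime."""
        return float(self.p_transfers.sum())

    @property
    def c_given(self) -> float:
        return float(self.c_transfers[self.c_transfers > 0].sum())

    @property
    def c_taken(self) -> float:
        return float(-self.c_transfers[self.c_transfers < 0].sum())

    @property
    def p_given(self) -> float:
        return float(self.p_transfers[self.p_transfers > 0].sum())

    @property
    def p_taken(self) -> float:
        return float(-self.p_transfers[self.p_transfers < 0].sum())

    @property
    def plant_grew(self) -> bool:
        return self.plant_fitness > 1.0 + GROWTH_TOL

    @property
    def fungus_grew(self) -> bool:
        return self.fungus_fitness > 1.0 + GROWTH_TOL


def _validate_biomass(x: float, y: float) -> None:
    if not (x > 0.0 and y > 0.0):
        raise ValueError(f"biomasses must be positive, got x={x}, y={y}")


def resolve_exchange(
    x: float,
    y: float,
    uptake: UptakeEfficiencies,
    strategy: ExchangeStrategy,
) -> StepOutcome:
    """One gather/exchange/grow step for plant biomass ``x``, fungus ``y``.

    Gathering: the plant acquires C equal to its biomass and P equal to
    ``alpha * x``; the fungus acquires P equal to its biomass and C equal
    to ``beta * y``.  Each resource then has exactly one transfer: a
    giver sends the stated share of its own gathered pool; a taker
    claims the stated share of its own gathered specialised resource
    from the partner, clamped to what the partner gathered this step.
    Growth is the minimum of each organism's two post-exchange pools.
    """
    _validate_biomass(x, y)
    a, b = uptake.alpha, uptake.beta
    g, e = strategy.gamma, strategy.epsilon

    if g >= 0.0:
        c_transfer = g * x
    else:
        c_transfer = -min(-g * x, b * y)
    if e >= 0.0:
        p_transfer = e * y
    else:
        p_transfer = -min(-e * y, a * x)

    plant_c = x - c_transfer
    fungus_c = b * y + c_transfer
    plant_p = a * x + p_transfer
    fungus_p = y - p_transfer

    return StepOutcome(
        plant_c_pool=plant_c,
        plant_p_pool=plant_p,
        fungus_c_pool=fungus_c,
        fungus_p_pool=fungus_p,
        c_transfer=c_transfer,
        p_transfer=p_transfer,
        plant_growth=min(plant_c, plant_p),
        fungus_growth=min(fungus_c, fungus_p),
    )


def simulate_lifecycle(
    uptake: UptakeEfficiencies,
    strategy: ExchangeStrategy,
    T: int = DEFAULT_TIMESTEPS,
) -> LifecycleResult:
    """Iterate :func:`resolve_exchange` for ``T`` steps from X_0 = Y_0 = 1.

    Pools are discarded between steps (no storage); biomass only ever
    accumulates the per-step growth increment.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    xs = np.empty(T + 1)
    ys = np.empty(T + 1)
    cts = np.empty(T)
    pts = np.empty(T)
    xs[0] = ys[0] = 1.0
    for n in range(T):
        step = resolve_exchange(xs[n], ys[n], uptake, strategy)
        xs[n + 1] = xs[n] + step.plant_growth
        ys[n + 1] = ys[n] + step.fungus_growth
        cts[n] = step.c_transfer
        pts[n] = step.p_transfer
    return LifecycleResult(
        plant_biomass=xs, fungus_biomass=ys, c_transfers=cts, p_transfers=pts, T=T
    )


def closed_form_fitness(
    uptake: UptakeEfficiencies,
    strategy: ExchangeStrategy,
    T: int = DEFAULT_TIMESTEPS,
) -> tuple[float, float] | None:
    """Analytic fitness pair where one exists, else ``None``.

    Two closed forms: with no exchange the species grow independently as
    ``(1+alpha)^T`` and ``(1+beta)^T``; with no nonspecialised uptake
    and a symmetric giving strategy gamma = epsilon = g in [0, 1] both
    organisms stay equal and grow as ``(1 + min(g, 1-g))^T``.
    """
    a, b = uptake.alpha, uptake.beta
    g, e = strategy.gamma, strategy.epsilon
    if g == 0.0 and e == 0.0:
        return (1.0 + a) ** T, (1.0 + b) ** T
    if a == 0.0 and b == 0.0 and g == e and g >= 0.0:
        m = min(g, 1.0 - g)
        return (1.0 + m) ** T, (1.0 + m) ** T
    return None


def lifecycle_arrays(
    alpha,
    beta,
    gamma,
    epsilon,
    T: int = DEFAULT_TIMESTEPS,
):
    """Vectorised lifecycle over broadcastable parameter arrays.

    All four parameters may be scalars or arrays broadcastable against
    each other.  Returns a dict of arrays on the broadcast shape:
    ``plant_fitness``, ``fungus_fitness``, net transfer totals
    ``total_c_to_fungus`` / ``total_p_to_plant`` and boolean grew flags.
    Used for landscape grids and paired populations; agrees with
    :func:`simulate_lifecycle` pointwise.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    g = np.asarray(gamma, dtype=float)
    e = np.asarray(epsilon, dtype=float)
    if np.any(a < 0) or np.any(a > 1) or np.any(b < 0) or np.any(b > 1):
        raise ValueError("uptake efficiencies must lie in [0, 1]")
    if np.any(np.abs(g) > 1) or np.any(np.abs(e) > 1):
        raise ValueError("exchange strategies must lie in [-1, 1]")

    shape = np.broadcast_shapes(a.shape, b.shape, g.shape, e.shape)
    x = np.ones(shape)
    y = np.ones(shape)
    c_net = np.zeros(shape)
    p_net = np.zeros(shape)
    give_c = g >= 0
    give_p = e >= 0
    for _ in range(T):
        ct = np.where(give_c, g * x, -np.minimum(-g * x, b * y))
        pt = np.where(give_p, e * y, -np.minimum(-e * y, a * x))
        plant_c = x - ct
        fungus_c = b * y + ct
        plant_p = a * x + pt
        fungus_p = y - pt
        x = x + np.minimum(plant_c, plant_p)
        y = y + np.minimum(fungus_c, fungus_p)
        c_net += ct
        p_net += pt
    return {
        "plant_fitness": x,
        "fungus_fitness": y,
        "total_c_to_fungus": c_net,
        "total_p_to_plant": p_net,
        "plant_grew": x > 1.0 + GROWTH_TOL,
        "fungus_grew": y > 1.0 + GROWTH_TOL,
    }
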