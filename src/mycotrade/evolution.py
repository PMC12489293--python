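"""Individual-based co-evolution of resource-exchange strategies.

Paired plant and fungus populations of fixed size evolve their trading
traits (gamma for plants, epsilon for fungi).  Each generation every
plant is paired with exactly one fungus, uniformly at random; the pair
lives one shared lifecycle and each individual's final biomass is its
fitness.  Individuals whose biomass never exceeded the initial value
cannot reproduce; the next generation is drawn with replacement
proportional to the remaining weights, each offspring mutated by a
Gaussian step and clipped to [-1, 1].  A generation in which every
member of a population fails to grow is an extinction, which terminates
the run (also for the surviving partner population, whose fate alone is
outside this model's scope).

Two interchangeable engines exist: a numpy reference implementation
(:func:`step_generation`, the readable specification of one generation)
and a numba kernel used by default for sweep-scale runs.  Both are
fully deterministic per seed but consume different random streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np

from . import _kernels
from .core import (
    DEFAULT_TIMESTEPS,
    GROWTH_TOL,
    ExchangeStrategy,
    UptakeEfficiencies,
    lifecycle_arrays,
)

__all__ = [
    "EvolutionConfig",
    "GenerationRecord",
    "EvolutionTrajectory",
    "init_populations",
    "step_generation",
    "run_evolution",
]

_OUTCOME_NAMES = {
    _kernels.OUTCOME_REACHED_CAP: "reached_cap",
    _kernels.OUTCOME_PLANT_EXTINCT: "plant_extinct",
    _kernels.OUTCOME_FUNGUS_EXTINCT: "fungus_extinct",
    _kernels.OUTCOME_BOTH_EXTINCT: "both_extinct",
}


@dataclass(frozen=True)
class EvolutionConfig:
    """Settings of one evolution simulation.

    ``mutation_sd`` is the standard deviation of the Gaussian mutation
    applied to every offspring trait (strategy units); ``initial_spread``
    is the founding variation around ``initial_strategy`` (0 founds a
    monomorphic population).  ``weight_mode`` selects the reproductive
    weight of a grown individual: "absolute" uses final biomass,
    "gained" uses final biomass minus the initial unit.
    """

    uptake: UptakeEfficiencies
    initial_strategy: ExchangeStrategy
    population_size: int = 200
    mutation_sd: float = 0.02
    generation_cap: int = 2000
    initial_spread: float = 0.0
    seed: int = 0
    T: int = DEFAULT_TIMESTEPS
    weight_mode: str = "absolute"
    engine: str = "fast"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be >= 0")
        if self.generation_cap < 1:
            raise ValueError("generation_cap must be >= 1")
        if self.weight_mode not in ("absolute", "gained"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.engine not in ("fast", "reference"):
            raise ValueError(f"unknown engine {self.engine!r}")

    def with_(self, **kwargs) -> "EvolutionConfig":
        return replace(self, **kwargs)


class GenerationRecord(NamedTuple):
    generation: int
    mean_gamma: float
    mean_epsilon: float
    frac_plants_grew: float
    frac_fungi_grew: float


@dataclass(frozen=True)
class EvolutionTrajectory:
    """Per-generation population summaries plus the run outcome.

    ``terminal_generation`` equals the number of generations evaluated;
    records are contiguous from generation 0.
    """

    mean_gamma: np.ndarray
    mean_epsilon: np.ndarray
    frac_plants_grew: np.ndarray
    frac_fungi_grew: np.ndarray
    outcome: str
    terminal_generation: int
    seed: int
    final_plant_traits: np.ndarray | None = None
    final_fungus_traits: np.ndarray | None = None

    @property
    def records(self) -> list[GenerationRecord]:
        return [
            GenerationRecord(i, *vals)
            for i, vals in enumerate(
                zip(
                    self.mean_gamma,
                    self.mean_epsilon,
                    self.frac_plants_grew,
                    self.frac_fungi_grew,
                )
            )
        ]

    @property
    def mean_strategy(self) -> np.ndarray:
        """(n_generations, 2) array of per-generation mean (gamma, epsilon)."""
        return np.column_stack([self.mean_gamma, self.mean_epsilon])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(len(self.mean_gamma)),
                "mean_gamma": self.mean_gamma,
                "mean_epsilon": self.mean_epsilon,
                "frac_plants_grew": self.frac_plants_grew,
                "frac_fungi_grew": self.frac_fungi_grew,
            }
        )


def init_populations(
    config: EvolutionConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Found both populations around the initial strategy.

    Traits are the initial component plus Gaussian(0, initial_spread)
    noise, clipped to [-1, 1]; zero spread founds monomorphic
    populations.
    """
    n = config.population_size
    g0 = config.initial_strategy.gamma
    e0 = config.initial_strategy.epsilon
    if config.initial_spread > 0:
        gam = g0 + rng.normal(0.0, config.initial_spread, n)
        eps = e0 + rng.normal(0.0, config.initial_spread, n)
    else:
        gam = np.full(n, g0)
        eps = np.full(n, e0)
    return np.clip(gam, -1.0, 1.0), np.clip(eps, -1.0, 1.0)


def step_generation(
    plant_traits: np.ndarray,
    fungus_traits: np.ndarray,
    uptake: UptakeEfficiencies,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray | None, np.ndarray | None, GenerationRecord, tuple[bool, bool]]:
    """Advance both populations one generation (numpy reference engine).

    Returns the offspring trait vectors (``None`` for a species with no
    viable parents), the summary record of the *current* generation, and
    (plant_extinct, fungus_extinct) flags.  The record's means describe
    the parental generation, i.e. the populations as passed in.
    """
    if len(plant_traits) != len(fungus_traits):
        raise ValueError("plant and fungus populations must have equal size")
    n = len(plant_traits)
    perm = rng.permutation(n)
    paired_eps = fungus_traits[perm]
    res = lifecycle_arrays(
        uptake.alpha, uptake.beta, plant_traits, paired_eps, T=config.T
    )
    x = res["plant_fitness"]
    y = res["fungus_fitness"]
    grew_p = res["plant_grew"]
    grew_f = res["fungus_grew"]
    if config.weight_mode == "gained":
        wp = np.where(grew_p, x - 1.0, 0.0)
        wf_paired = np.where(grew_f, y - 1.0, 0.0)
    else:
        wp = np.where(grew_p, x, 0.0)
        wf_paired = np.where(grew_f, y, 0.0)
    wf = np.empty(n)
    wf[perm] = wf_paired

    record = GenerationRecord(
        generation=-1,  # filled by the caller
        mean_gamma=float(plant_traits.mean()),
        mean_epsilon=float(fungus_traits.mean()),
        frac_plants_grew=float(grew_p.mean()),
        frac_fungi_grew=float(grew_f.mean()),
    )
    plant_extinct = not np.any(wp > 0)
    fungus_extinct = not np.any(wf > 0)
    if plant_extinct or fungus_extinct:
        return None, None, record, (plant_extinct, fungus_extinct)

    parents_p = rng.choice(n, size=n, p=wp / wp.sum())
    parents_f = rng.choice(n, size=n, p=wf / wf.sum())
    next_g = plant_traits[parents_p]
    next_e = fungus_traits[parents_f]
    if config.mutation_sd > 0:
        next_g = next_g + rng.normal(0.0, config.mutation_sd, n)
        next_e = next_e + rng.normal(0.0, config.mutation_sd, n)
    return (
        np.clip(next_g, -1.0, 1.0),
        np.clip(next_e, -1.0, 1.0),
        record,
        (False, False),
    )


def _run_reference(config: EvolutionConfig) -> EvolutionTrajectory:
    rng = np.random.default_rng(config.seed)
    gam, eps = init_populations(config, rng)
    mean_g, mean_e, fr_p, fr_f = [], [], [], []
    outcome = "reached_cap"
    for gen in range(config.generation_cap):
        next_g, next_e, rec, (px, fx) = step_generation(
            gam, eps, config.uptake, config, rng
        )
        mean_g.append(rec.mean_gamma)
        mean_e.append(rec.mean_epsilon)
        fr_p.append(rec.frac_plants_grew)
        fr_f.append(rec.frac_fungi_grew)
        if px or fx:
            outcome = (
                "both_extinct" if (px and fx) else "plant_extinct" if px else "fungus_extinct"
            )
            break
        gam, eps = next_g, next_e
    return EvolutionTrajectory(
        mean_gamma=np.array(mean_g),
        mean_epsilon=np.array(mean_e),
        frac_plants_grew=np.array(fr_p),
        frac_fungi_grew=np.array(fr_f),
        outcome=outcome,
        terminal_generation=len(mean_g),
        seed=config.seed,
        final_plant_traits=gam,
        final_fungus_traits=eps,
    )


def _run_fast(config: EvolutionConfig) -> EvolutionTrajectory:
    rng = np.random.default_rng(config.seed)
    gam, eps = init_populations(config, rng)
    kernel_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    mg, me, fp, ff, n_rec, outcome, fin_g, fin_e = _kernels.evolution_kernel(
        gam,
        eps,
        float(config.uptake.alpha),
        float(config.uptake.beta),
        int(config.T),
        int(config.generation_cap),
        float(config.mutation_sd),
        kernel_seed,
        config.weight_mode == "gained",
    )
    return EvolutionTrajectory(
        mean_gamma=mg[:n_rec].copy(),
        mean_epsilon=me[:n_rec].copy(),
        frac_plants_grew=fp[:n_rec].copy(),
        frac_fungi_grew=ff[:n_rec].copy(),
        outcome=_OUTCOME_NAMES[int(outcome)],
        terminal_generation=int(n_rec),
        seed=config.seed,
        final_plant_traits=fin_g,
        final_fungus_traits=fin_e,
    )


def run_evolution(config: EvolutionConfig) -> EvolutionTrajectory:
    """Run one simulation to extinction or the generation cap.

    The trajectory is exactly reproducible from ``config.seed`` for a
    given engine choice.
    """
    if config.engine == "reference":
        return _run_reference(config)
    return _run_fast(config)
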