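"""Coupled fitness landscapes over the strategy plane.

For a fixed uptake-efficiency pair the plant and fungus fitness surfaces
over (gamma, epsilon) are interdependent — each organism's growth feeds
back on its partner's resources — hence "coupled".  This module builds
those grids, classifies every strategy against the no-exchange baseline
(mutualism / parasitism / competition / neutral), and derives the
extinction-zone, viable-range, resources-received and maximum-fitness
layers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_TIMESTEPS,
    ExchangeStrategy,
    UptakeEfficiencies,
    lifecycle_arrays,
)

__all__ = [
    "InteractionType",
    "ExtinctionZone",
    "StrategyGrid",
    "LandscapeSet",
    "build_strategy_grid",
    "compute_landscape",
    "classify_point",
    "extinction_mask",
    "viable_range",
    "resources_received",
    "fitness_maxima",
]

#: Relative tolerance for fitness ties against the baseline.
NEUTRAL_TOL = 1e-9

DEFAULT_RESOLUTION = 500


class InteractionType(enum.IntEnum):
    """Strategy classification relative to the no-exchange baseline.

    Parasitism is named for the beneficiary: PLANT_PARASITIC means the
    plant gains and the fungus loses.  NEUTRAL marks a fitness tie for
    either organism (e.g. a plant with alpha = 0 never grows, so its
    fitness always ties the baseline).
    """

    NEUTRAL = 0
    MUTUALISM = 1
    PLANT_PARASITIC = 2
    FUNGUS_PARASITIC = 3
    COMPETITION = 4


class ExtinctionZone(enum.IntEnum):
    """Which organism(s) fail to grow past initial biomass at a strategy."""

    NONE = 0
    PLANT_ONLY = 1
    FUNGUS_ONLY = 2
    BOTH = 3


@dataclass(frozen=True)
class StrategyGrid:
    """Evenly spaced, endpoint-inclusive strategy values per axis."""

    gamma_values: np.ndarray
    epsilon_values: np.ndarray

    @property
    def resolution(self) -> tuple[int, int]:
        return len(self.gamma_values), len(self.epsilon_values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.resolution


def build_strategy_grid(
    resolution: int = DEFAULT_RESOLUTION, lo: float = -1.0, hi: float = 1.0
) -> StrategyGrid:
    """Uniform inclusive grid of ``resolution`` values per axis in [lo, hi]."""
    if resolution < 2:
        raise ValueError(f"resolution must be >= 2, got {resolution}")
    if not (-1.0 <= lo < hi <= 1.0):
        raise ValueError(f"need -1 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    values = np.linspace(lo, hi, resolution)
    return StrategyGrid(gamma_values=values, epsilon_values=values.copy())


@dataclass(frozen=True)
class LandscapeSet:
    """All per-strategy layers for one uptake combination.

    Every 2-D array is indexed ``[i, j]`` for strategy
    ``(gamma_values[i], epsilon_values[j])``.
    """

    uptake: UptakeEfficiencies
    grid: StrategyGrid
    plant_fitness: np.ndarray
    fungus_fitness: np.ndarray
    interaction_type: np.ndarray  # InteractionType codes, uint8
    extinction: np.ndarray  # ExtinctionZone codes, uint8
    total_p_to_plant: np.ndarray
    total_c_to_fungus: np.ndarray
    plant_grew: np.ndarray
    fungus_grew: np.ndarray
    baseline_plant_fitness: float
    baseline_fungus_fitness: float
    T: int = DEFAULT_TIMESTEPS


def _classify_arrays(
    plant_fit, fungus_fit, baseline_plant, baseline_fungus, tol=NEUTRAL_TOL
):
    pf = np.asarray(plant_fit, dtype=float)
    ff = np.asarray(fungus_fit, dtype=float)
    p_up = pf > baseline_plant * (1.0 + tol)
    p_dn = pf < baseline_plant * (1.0 - tol)
    f_up = ff > baseline_fungus * (1.0 + tol)
    f_dn = ff < baseline_fungus * (1.0 - tol)
    out = np.full(pf.shape, InteractionType.NEUTRAL, dtype=np.uint8)
    out[p_up & f_up] = InteractionType.MUTUALISM
    out[p_dn & f_dn] = InteractionType.COMPETITION
    out[p_up & f_dn] = InteractionType.PLANT_PARASITIC
    out[p_dn & f_up] = InteractionType.FUNGUS_PARASITIC
    return out


def classify_point(
    plant_fit: float,
    fungus_fit: float,
    baseline_plant: float,
    baseline_fungus: float,
    tol: float = NEUTRAL_TOL,
) -> InteractionType:
    """Classify one fitness pair against the no-exchange baseline.

    Mutualism: both exceed their baseline; competition: both fall below;
    parasitism: one up, one down (named for the beneficiary); neutral:
    either organism ties its baseline within relative tolerance ``tol``.
    """
    code = _classify_arrays(
        np.array(plant_fit), np.array(fungus_fit), baseline_plant, baseline_fungus, tol
    )
    return InteractionType(int(code))


def compute_landscape(
    uptake: UptakeEfficiencies,
    grid: StrategyGrid | None = None,
    T: int = DEFAULT_TIMESTEPS,
    tol: float = NEUTRAL_TOL,
) -> LandscapeSet:
    """Evaluate the paired lifecycle at every grid strategy.

    The baseline is the (0, 0) strategy of the same uptake pair,
    i.e. fitnesses (1+alpha)^T and (1+beta)^T.
    """
    if grid is None:
        grid = build_strategy_grid()
    gam = grid.gamma_values[:, None]
    eps = grid.epsilon_values[None, :]
    res = lifecycle_arrays(uptake.alpha, uptake.beta, gam, eps, T=T)
    baseline_plant = (1.0 + uptake.alpha) ** T
    baseline_fungus = (1.0 + uptake.beta) ** T
    interaction = _classify_arrays(
        res["plant_fitness"], res["fungus_fitness"], baseline_plant, baseline_fungus, tol
    )
    extinction = np.full(res["plant_fitness"].shape, ExtinctionZone.NONE, dtype=np.uint8)
    pg, fg = res["plant_grew"], res["fungus_grew"]
    extinction[~pg & fg] = ExtinctionZone.PLANT_ONLY
    extinction[pg & ~fg] = ExtinctionZone.FUNGUS_ONLY
    extinction[~pg & ~fg] = ExtinctionZone.BOTH
    return LandscapeSet(
        uptake=uptake,
        grid=grid,
        plant_fitness=res["plant_fitness"],
        fungus_fitness=res["fungus_fitness"],
        interaction_type=interaction,
        extinction=extinction,
        total_p_to_plant=res["total_p_to_plant"],
        total_c_to_fungus=res["total_c_to_fungus"],
        plant_grew=pg,
        fungus_grew=fg,
        baseline_plant_fitness=baseline_plant,
        baseline_fungus_fitness=baseline_fungus,
        T=T,
    )


def extinction_mask(landscape: LandscapeSet) -> np.ndarray:
    """Per-cell extinction category derived from the grew flags."""
    return landscape.extinction


def viable_range(landscape: LandscapeSet) -> np.ndarray:
    """Boolean grid: True where both organisms achieved positive growth."""
    return landscape.plant_grew & landscape.fungus_grew


def resources_received(
    uptake: UptakeEfficiencies,
    strategy: ExchangeStrategy,
    T: int = DEFAULT_TIMESTEPS,
) -> tuple[float, float]:
    """Net lifetime transfer totals (P to plant, C to fungus) at one strategy.

    Post-clamp per-step transfers are summed with sign, so resource
    taken accumulates as a negative contribution.
    """
    res = lifecycle_arrays(uptake.alpha, uptake.beta, strategy.gamma, strategy.epsilon, T=T)
    return float(res["total_p_to_plant"]), float(res["total_c_to_fungus"])


@dataclass(frozen=True)
class LayerMaxima:
    """Argmax of one landscape layer with all exactly-tied cells."""

    strategy: ExchangeStrategy
    value: float
    tied: tuple[ExchangeStrategy, ...]


def _argmax_layer(layer: np.ndarray, grid: StrategyGrid) -> LayerMaxima:
    vmax = layer.max()
    ii, jj = np.nonzero(layer == vmax)
    # lexicographic (gamma, epsilon): row-major nonzero is already sorted
    tied = tuple(
        ExchangeStrategy(float(grid.gamma_values[i]), float(grid.epsilon_values[j]))
        for i, j in zip(ii, jj)
    )
    return LayerMaxima(strategy=tied[0], value=float(vmax), tied=tied)


def fitness_maxima(landscape: LandscapeSet) -> dict[str, LayerMaxima]:
    """Argmax strategies for both fitness layers and both transfer layers.

    Ties (exact float equality with the layer maximum) are broken by the
    smallest (gamma, epsilon) in lexicographic order; all tied cells are
    also reported.
    """
    return {
        "plant_fitness": _argmax_layer(landscape.plant_fitness, landscape.grid),
        "fungus_fitness": _argmax_layer(landscape.fungus_fitness, landscape.grid),
        "total_p_to_plant": _argmax_layer(landscape.total_p_to_plant, landscape.grid),
        "total_c_to_fungus": _argmax_layer(landscape.total_c_to_fungus, landscape.grid),
    }
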