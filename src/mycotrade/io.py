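"""Serialization of landscapes, trajectories and sweep summaries.

All tables are plain tab-separated text with a JSON sidecar manifest
(parameters, seeds, software version) so any run can be reproduced
bit-for-bit.  Floats are written with shortest-round-trip repr, so a
read-back table equals the in-memory original exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ExchangeStrategy, UptakeEfficiencies
from .evolution import EvolutionConfig, EvolutionTrajectory
from .landscapes import (
    ExtinctionZone,
    InteractionType,
    LandscapeSet,
    StrategyGrid,
    compute_landscape,
)
from .stability import StabilityReport, SweepSummary

__all__ = [
    "write_landscape",
    "read_landscape",
    "write_trajectory",
    "read_trajectory",
    "write_sweep",
    "read_sweep",
    "write_manifest",
]

_INTERACTION_NAMES = {t: t.name.lower() for t in InteractionType}
_EXTINCTION_NAMES = {
    ExtinctionZone.NONE: "none",
    ExtinctionZone.PLANT_ONLY: "plant_only",
    ExtinctionZone.FUNGUS_ONLY: "fungus_only",
    ExtinctionZone.BOTH: "both",
}


def _sib(prefix: Path, ext: str) -> Path:
    # not Path.with_suffix: prefixes may contain dots (e.g. "a0.1_b0")
    return prefix.parent / (prefix.name + ext)


def write_manifest(path: Path | str, **payload) -> None:
    payload = {"software": "mycotrade", "version": __version__, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def landscape_frame(landscape: LandscapeSet) -> pd.DataFrame:
    """Long-format table, one row per (gamma, epsilon) cell."""
    gg, ee = np.meshgrid(
        landscape.grid.gamma_values, landscape.grid.epsilon_values, indexing="ij"
    )
    inter = np.vectorize(lambda c: _INTERACTION_NAMES[InteractionType(c)])(
        landscape.interaction_type
    )
    ext = np.vectorize(lambda c: _EXTINCTION_NAMES[ExtinctionZone(c)])(
        landscape.extinction
    )
    return pd.DataFrame(
        {
            "gamma": gg.ravel(),
            "epsilon": ee.ravel(),
            "plant_fitness": landscape.plant_fitness.ravel(),
            "fungus_fitness": landscape.fungus_fitness.ravel(),
            "interaction_type": inter.ravel(),
            "extinction": ext.ravel(),
            "total_p_to_plant": landscape.total_p_to_plant.ravel(),
            "total_c_to_fungus": landscape.total_c_to_fungus.ravel(),
        }
    )


def write_landscape(landscape: LandscapeSet, prefix: Path | str) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` plus ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table = _sib(prefix, ".tsv")
    sidecar = _sib(prefix, ".json")
    landscape_frame(landscape).to_csv(table, sep="\t", index=False)
    write_manifest(
        sidecar,
        alpha=landscape.uptake.alpha,
        beta=landscape.uptake.beta,
        resolution=list(landscape.grid.resolution),
        gamma_lo=float(landscape.grid.gamma_values[0]),
        gamma_hi=float(landscape.grid.gamma_values[-1]),
        epsilon_lo=float(landscape.grid.epsilon_values[0]),
        epsilon_hi=float(landscape.grid.epsilon_values[-1]),
        T=landscape.T,
        baseline_plant_fitness=landscape.baseline_plant_fitness,
        baseline_fungus_fitness=landscape.baseline_fungus_fitness,
    )
    return table, sidecar


def read_landscape(prefix: Path | str) -> LandscapeSet:
    """Round-trip reader for :func:`write_landscape` output."""
    prefix = Path(prefix)
    meta = json.loads(_sib(prefix, ".json").read_text())
    df = pd.read_csv(_sib(prefix, ".tsv"), sep="\t", float_precision="round_trip")
    n_g, n_e = meta["resolution"]
    shape = (n_g, n_e)
    grid = StrategyGrid(
        gamma_values=df["gamma"].to_numpy().reshape(shape)[:, 0],
        epsilon_values=df["epsilon"].to_numpy().reshape(shape)[0, :],
    )
    name_to_inter = {v: k for k, v in _INTERACTION_NAMES.items()}
    name_to_ext = {v: k for k, v in _EXTINCTION_NAMES.items()}
    inter = (
        df["interaction_type"].map(name_to_inter).to_numpy(dtype=np.uint8).reshape(shape)
    )
    ext = df["extinction"].map(name_to_ext).to_numpy(dtype=np.uint8).reshape(shape)
    plant_fitness = df["plant_fitness"].to_numpy().reshape(shape)
    fungus_fitness = df["fungus_fitness"].to_numpy().reshape(shape)
    from .core import GROWTH_TOL

    return LandscapeSet(
        uptake=UptakeEfficiencies(meta["alpha"], meta["beta"]),
        grid=grid,
        plant_fitness=plant_fitness,
        fungus_fitness=fungus_fitness,
        interaction_type=inter,
        extinction=ext,
        total_p_to_plant=df["total_p_to_plant"].to_numpy().reshape(shape),
        total_c_to_fungus=df["total_c_to_fungus"].to_numpy().reshape(shape),
        plant_grew=plant_fitness > 1.0 + GROWTH_TOL,
        fungus_grew=fungus_fitness > 1.0 + GROWTH_TOL,
        baseline_plant_fitness=meta["baseline_plant_fitness"],
        baseline_fungus_fitness=meta["baseline_fungus_fitness"],
        T=meta["T"],
    )


def _config_payload(config: EvolutionConfig) -> dict:
    return {
        "alpha": config.uptake.alpha,
        "beta": config.uptake.beta,
        "initial_gamma": config.initial_strategy.gamma,
        "initial_epsilon": config.initial_strategy.epsilon,
        "population_size": config.population_size,
        "mutation_sd": config.mutation_sd,
        "generation_cap": config.generation_cap,
        "initial_spread": config.initial_spread,
        "seed": config.seed,
        "T": config.T,
        "weight_mode": config.weight_mode,
        "engine": config.engine,
    }


def write_trajectory(
    trajectory: EvolutionTrajectory, config: EvolutionConfig, prefix: Path | str
) -> tuple[Path, Path]:
    """Write per-generation table plus a JSON run manifest."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table = _sib(prefix, ".tsv")
    trajectory.to_frame().to_csv(table, sep="\t", index=False)
    write_manifest(
        _sib(prefix, ".json"),
        config=_config_payload(config),
        outcome=trajectory.outcome,
        terminal_generation=trajectory.terminal_generation,
        seed=trajectory.seed,
    )
    return table, _sib(prefix, ".json")


def read_trajectory(prefix: Path | str) -> EvolutionTrajectory:
    prefix = Path(prefix)
    meta = json.loads(_sib(prefix, ".json").read_text())
    df = pd.read_csv(_sib(prefix, ".tsv"), sep="\t", float_precision="round_trip")
    return EvolutionTrajectory(
        mean_gamma=df["mean_gamma"].to_numpy(),
        mean_epsilon=df["mean_epsilon"].to_numpy(),
        frac_plants_grew=df["frac_plants_grew"].to_numpy(),
        frac_fungi_grew=df["frac_fungi_grew"].to_numpy(),
        outcome=meta["outcome"],
        terminal_generation=meta["terminal_generation"],
        seed=meta["seed"],
    )


def write_sweep(
    summary: SweepSummary, config: EvolutionConfig, prefix: Path | str
) -> tuple[Path, Path]:
    """Write the per-combination report table plus a JSON manifest."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table = _sib(prefix, ".tsv")
    summary.to_frame().to_csv(table, sep="\t", index=False)
    write_manifest(
        _sib(prefix, ".json"),
        alphas=summary.alphas,
        betas=summary.betas,
        master_seed=summary.master_seed,
        config=_config_payload(config),
        percentages=summary.percentages(),
    )
    return table, _sib(prefix, ".json")


def read_sweep(prefix: Path | str) -> pd.DataFrame:
    """Read back the sweep report table (manifest available as JSON)."""
    return pd.read_csv(
        _sib(Path(prefix), ".tsv"), sep="\t", float_precision="round_trip"
    )
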