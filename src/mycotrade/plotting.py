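"""Raster exports of landscape maps and trajectory overlays.

Colour semantics: interaction types are light blue (mutualism), green
(plant is parasitic), orange (fungus is parasitic), yellow
(competition) and white (neutral tie); extinction zones overlay in
greys (light = plant only, medium = fungus only, dark = both).
Trajectories draw as black dots over the map.  Resources-received maps
use a diverging scale: orange where the resource is given, blue where
it is taken.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap, TwoSlopeNorm

from .evolution import EvolutionTrajectory
from .landscapes import ExtinctionZone, InteractionType, LandscapeSet

__all__ = ["plot_interaction_map", "plot_resources_map"]

_INTERACTION_COLORS = {
    InteractionType.NEUTRAL: "#ffffff",
    InteractionType.MUTUALISM: "#9ecae9",
    InteractionType.PLANT_PARASITIC: "#74c476",
    InteractionType.FUNGUS_PARASITIC: "#fdae6b",
    InteractionType.COMPETITION: "#ffe873",
}
_EXTINCTION_COLORS = {
    ExtinctionZone.PLANT_ONLY: "#d9d9d9",
    ExtinctionZone.FUNGUS_ONLY: "#969696",
    ExtinctionZone.BOTH: "#525252",
}


def _extent(landscape: LandscapeSet):
    g = landscape.grid.gamma_values
    e = landscape.grid.epsilon_values
    return (g[0], g[-1], e[0], e[-1])


def plot_interaction_map(
    landscape: LandscapeSet,
    path: Path | str,
    trajectory: EvolutionTrajectory | None = None,
    dpi: int = 150,
) -> Path:
    """Interaction-type map with extinction overlay and optional trajectory."""
    img = np.empty(landscape.interaction_type.shape, dtype=int)
    colors = []
    for idx, t in enumerate(InteractionType):
        img[landscape.interaction_type == t] = idx
        colors.append(_INTERACTION_COLORS[t])
    offset = len(colors)
    for k, (zone, color) in enumerate(_EXTINCTION_COLORS.items()):
        img[landscape.extinction == zone] = offset + k
        colors.append(color)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    ax.imshow(
        img.T,
        origin="lower",
        extent=_extent(landscape),
        cmap=ListedColormap(colors),
        vmin=-0.5,
        vmax=len(colors) - 0.5,
        interpolation="nearest",
        aspect="auto",
    )
    if trajectory is not None:
        ax.plot(
            trajectory.mean_gamma,
            trajectory.mean_epsilon,
            ".",
            color="black",
            markersize=1.5,
        )
        ax.plot(trajectory.mean_gamma[0], trajectory.mean_epsilon[0], "o",
                color="navy", markersize=6)
        ax.plot(trajectory.mean_gamma[-1], trajectory.mean_epsilon[-1], "o",
                color="darkorange", markersize=6)
    ax.set_xlabel("plant C to fungus (gamma)")
    ax.set_ylabel("fungus P to plant (epsilon)")
    ax.set_title(
        f"interaction types, alpha={landscape.uptake.alpha:g}, "
        f"beta={landscape.uptake.beta:g}"
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_resources_map(
    landscape: LandscapeSet,
    path: Path | str,
    layer: str = "total_p_to_plant",
    dpi: int = 150,
) -> Path:
    """Diverging map of a lifetime transfer-total layer over viable cells."""
    data = getattr(landscape, layer).astype(float).copy()
    viable = landscape.plant_grew & landscape.fungus_grew
    data[~viable] = np.nan
    vmax = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
    vmax = vmax or 1.0
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(
        data.T,
        origin="lower",
        extent=_extent(landscape),
        cmap="PuOr_r",
        norm=TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax),
        interpolation="nearest",
        aspect="auto",
    )
    fig.colorbar(im, ax=ax, label=layer)
    ax.set_xlabel("plant C to fungus (gamma)")
    ax.set_ylabel("fungus P to plant (epsilon)")
    ax.set_title(
        f"{layer}, alpha={landscape.uptake.alpha:g}, beta={landscape.uptake.beta:g}"
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
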