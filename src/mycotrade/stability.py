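"""Detection and classification of evolutionarily stable trading strategies.

For one uptake-efficiency combination the pipeline is: run exploratory
evolution simulations from a coarse grid of viable founding strategies;
pool the per-generation mean strategies of the final generations of
every run that reached the generation cap; cluster the pooled points
(single linkage) and fit each cluster a covariance ellipse covering 95%
of its points — these are the candidate stable areas.  A candidate is
then stress-tested: 36 independent simulations founded at its center
must each keep their population mean strategy inside the ellipse for at
least 500 consecutive generations.  All replicates remaining makes the
area stable, some remaining makes it semi-stable, none failing the
candidate.  Finally the area is located on the interaction-type
landscape: entirely (>= 99% of interior cells) in the mutualism zone,
spanning mutualism and parasitism (parasitic share >= 1%), or — never
observed, hence flagged as novel — some other zone combination.

The sweep repeats this per uptake combination (the reference grid is 21
plant values x 11 fungus values = 231 combinations) and aggregates
category and stability percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core import ExchangeStrategy, UptakeEfficiencies, lifecycle_arrays
from .evolution import EvolutionConfig, EvolutionTrajectory, run_evolution
from .landscapes import (
    InteractionType,
    LandscapeSet,
    build_strategy_grid,
    compute_landscape,
    fitness_maxima,
)

__all__ = [
    "EllipseShape",
    "StableArea",
    "StabilityReport",
    "SweepSummary",
    "fit_area_from_points",
    "detect_areas_from_points",
    "explore_candidates",
    "test_stability",
    "classify_landscape",
    "area_fitness_maxima",
    "characterize_uptake",
    "run_sweep",
    "default_sweep_grids",
]

#: Quantile of cluster points an area ellipse must cover.
DEFAULT_COVERAGE = 0.95
#: Single-linkage merge threshold between pooled endpoints (strategy units).
DEFAULT_LINKAGE_THRESHOLD = 0.1
#: Number of trailing generations pooled from each cap-reaching run.
DEFAULT_TAIL = 500
#: Pooled points are thinned to at most this many before clustering.
MAX_CLUSTER_POINTS = 2000
#: Containment margin of the stability test: the replicate must stay
#: within the area ellipse with its Mahalanobis radius inflated by this
#: factor.  The fitted ellipse covers 95% of stationary points, so a
#: stationary replicate pokes just beyond it ~5% of generations; the
#: margin absorbs those excursions (max of ~500 correlated draws of a
#: chi-square(2) radius is ~1.4x its 95% quantile) while genuine
#: departures -- drift off the area, runs to extinction -- far exceed it.
DEFAULT_CONTAINMENT_INFLATION = 1.5
#: A replicate counts as having left the area only after this many
#: consecutive generations outside the (inflated) ellipse.  Stationary
#: excursions of the population mean last a handful of generations and
#: return; a population that truly departed does not come back quickly.
DEFAULT_DEPARTURE_PATIENCE = 10
#: A run's trailing generations enter the candidate pool only if the
#: tail is stationary: the drift between the means of its first and
#: last quarters must not exceed this fraction of the tail's RMS spread.
#: Around a true attractor the quarter-means agree to a small fraction
#: of the cloud size (~sqrt(2/q)); a population wandering neutrally (a
#: drift plateau that eventually crosses into an extinction zone) shows
#: quarter-mean drift comparable to its whole spread, so the two
#: regimes separate cleanly on this scale-free ratio.
DEFAULT_DRIFT_FRACTION = 0.5

CATEGORY_MUTUALISM = "mutualism_stable"
CATEGORY_MUT_PAR = "mutualism_parasitism_stable"
CATEGORY_NONE = "none"
CATEGORY_NOVEL = "novel"

_PARASITIC = (InteractionType.PLANT_PARASITIC, InteractionType.FUNGUS_PARASITIC)


@dataclass(frozen=True)
class EllipseShape:
    """Covariance ellipse in strategy space.

    Membership: (p - center)^T cov^{-1} (p - center) <= radius^2; the
    semi-axes are radius * sqrt(eigvals(cov)).
    """

    center: np.ndarray
    cov: np.ndarray
    radius: float

    @property
    def semi_axes(self) -> np.ndarray:
        vals = np.linalg.eigvalsh(self.cov)
        return self.radius * np.sqrt(np.maximum(vals, 0.0))[::-1]

    @property
    def orientation(self) -> float:
        """Angle (radians) of the major axis from the gamma axis."""
        vals, vecs = np.linalg.eigh(self.cov)
        major = vecs[:, int(np.argmax(vals))]
        return float(np.arctan2(major[1], major[0]))

    def contains(self, points: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        cov = self.cov + np.eye(2) * 1e-15  # guard exact degeneracy
        sol = np.linalg.solve(cov, pts.T)
        d2 = np.einsum("ij,ji->i", pts, sol)
        return d2 <= self.radius**2 * (1.0 + rtol) + 1e-12


@dataclass(frozen=True)
class StableArea:
    """A candidate or confirmed stable strategy area."""

    center: ExchangeStrategy
    shape: EllipseShape
    uptake: UptakeEfficiencies
    n_points: int = 0
    interaction_types_spanned: frozenset = frozenset()


@dataclass(frozen=True)
class StabilityReport:
    """Stability characterisation of one uptake combination."""

    uptake: UptakeEfficiencies
    category: str  # mutualism_stable | mutualism_parasitism_stable | none | novel
    stability: str  # stable | semi_stable | not_applicable
    area: StableArea | None
    replicates_remaining: int
    n_replicates: int
    max_plant_fitness_in_area: float
    max_fungus_fitness_in_area: float
    plant_max_coincides: bool | None = None
    fungus_max_coincides: bool | None = None
    novel_outcome: bool = False
    empty_interior: bool = False
    n_candidates: int = 0


def fit_area_from_points(
    points: np.ndarray,
    uptake: UptakeEfficiencies,
    coverage: float = DEFAULT_COVERAGE,
) -> StableArea:
    """Fit a covariance ellipse to a point cloud in strategy space.

    The ellipse is centred on the cloud mean with the cloud covariance
    shape, scaled so the empirical ``coverage`` quantile of Mahalanobis
    distances lies on the boundary.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    center = pts.mean(axis=0)
    dev = pts - center
    if len(pts) > 1:
        cov = dev.T @ dev / (len(pts) - 1)
    else:
        cov = np.zeros((2, 2))
    cov_r = cov + np.eye(2) * 1e-15
    sol = np.linalg.solve(cov_r, dev.T)
    d2 = np.einsum("ij,ji->i", dev, sol)
    radius = float(np.sqrt(np.quantile(d2, coverage))) if len(pts) > 1 else 0.0
    return StableArea(
        center=ExchangeStrategy(
            float(np.clip(center[0], -1, 1)), float(np.clip(center[1], -1, 1))
        ),
        shape=EllipseShape(center=center, cov=cov, radius=radius),
        uptake=uptake,
        n_points=len(pts),
    )


def detect_areas_from_points(
    points: np.ndarray,
    uptake: UptakeEfficiencies,
    linkage_threshold: float = DEFAULT_LINKAGE_THRESHOLD,
    coverage: float = DEFAULT_COVERAGE,
    boundary_margin: float = 0.0,
) -> list[StableArea]:
    """Cluster pooled trajectory endpoints and fit one ellipse per cluster.

    Single-linkage agglomeration cut at ``linkage_threshold`` strategy
    units; clusters are returned largest first.  Point clouds larger
    than an internal cap are thinned by uniform stride before
    clustering (the fit then uses the thinned members).  Candidates
    whose ellipse extends beyond the [-1, 1] strategy domain are
    discarded: an area invariant, and what distinguishes a genuine
    interior attractor from a population pinned against the trait
    boundary by clipping.  ``boundary_margin`` widens that exclusion:
    within about two mutation steps of the boundary the trait
    distribution is censored by clipping, so a cloud there reflects the
    clip, not free dynamics.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        return []
    if len(pts) > MAX_CLUSTER_POINTS:
        stride = int(np.ceil(len(pts) / MAX_CLUSTER_POINTS))
        pts = pts[::stride]
    if len(pts) == 1:
        labels = np.ones(1, dtype=int)
    else:
        labels = fcluster(
            linkage(pdist(pts), method="single"),
            t=linkage_threshold,
            criterion="distance",
        )
    areas = []
    for lab in np.unique(labels):
        cluster = pts[labels == lab]
        area = fit_area_from_points(cluster, uptake, coverage)
        half_extent = area.shape.radius * np.sqrt(np.diag(area.shape.cov))
        bbox_lo = area.shape.center - half_extent
        bbox_hi = area.shape.center + half_extent
        lim = 1.0 - boundary_margin + 1e-9
        if np.all(bbox_lo >= -lim) and np.all(bbox_hi <= lim):
            areas.append(area)
    areas.sort(key=lambda a: -a.n_points)
    return areas


def _viable_founding_points(
    uptake: UptakeEfficiencies,
    founding_resolution: int,
    T: int,
) -> np.ndarray:
    """Coarse founding grid restricted to the viable exchange range."""
    vals = np.linspace(-1.0, 1.0, founding_resolution)
    gg, ee = np.meshgrid(vals, vals, indexing="ij")
    res = lifecycle_arrays(uptake.alpha, uptake.beta, gg, ee, T=T)
    viable = res["plant_grew"] & res["fungus_grew"]
    return np.column_stack([gg[viable], ee[viable]])


def explore_candidates(
    uptake: UptakeEfficiencies,
    config: EvolutionConfig,
    n_starts: int = 9,
    founding_resolution: int = 9,
    tail: int = DEFAULT_TAIL,
    linkage_threshold: float = DEFAULT_LINKAGE_THRESHOLD,
    coverage: float = DEFAULT_COVERAGE,
    seeds: np.ndarray | None = None,
    drift_fraction: float = DEFAULT_DRIFT_FRACTION,
) -> list[StableArea]:
    """Exploratory runs from viable founders; candidate areas from tails.

    Up to ``n_starts`` founding strategies are taken evenly spaced from
    the viable cells of a ``founding_resolution``-per-axis grid.  Runs
    that reach the generation cap with a stationary tail (quarter-mean
    drift over the final ``tail`` generations at most
    ``drift_fraction`` of the tail's RMS spread) contribute those tail
    mean strategies to the pooled cloud; clustering the pool yields the
    candidates.  All runs extinct or still drifting gives an empty
    list.
    """
    founders = _viable_founding_points(uptake, founding_resolution, config.T)
    if len(founders) == 0:
        return []
    if len(founders) > n_starts:
        idx = np.unique(np.linspace(0, len(founders) - 1, n_starts).round().astype(int))
        founders = founders[idx]
    if seeds is None:
        seeds = (
            np.random.SeedSequence(config.seed).generate_state(len(founders)) % (2**31)
        )
    pooled = []
    for (g0, e0), s in zip(founders, seeds):
        traj = run_evolution(
            config.with_(
                initial_strategy=ExchangeStrategy(float(g0), float(e0)),
                seed=int(s),
            )
        )
        if traj.outcome == "reached_cap":
            pts = traj.mean_strategy[-tail:]
            q = max(1, len(pts) // 4)
            drift = np.linalg.norm(pts[-q:].mean(axis=0) - pts[:q].mean(axis=0))
            spread = float(np.sqrt(pts.var(axis=0).sum()))
            if drift <= max(drift_fraction * spread, 1e-9):
                pooled.append(pts)
    if not pooled:
        return []
    return detect_areas_from_points(
        np.vstack(pooled),
        uptake,
        linkage_threshold,
        coverage,
        boundary_margin=2.0 * config.mutation_sd,
    )


def test_stability(
    area: StableArea,
    config: EvolutionConfig,
    n_replicates: int = 36,
    min_generations: int = DEFAULT_TAIL,
    seeds: np.ndarray | None = None,
    containment_inflation: float = DEFAULT_CONTAINMENT_INFLATION,
    departure_patience: int = DEFAULT_DEPARTURE_PATIENCE,
) -> tuple[str, int]:
    """36-replicate containment test of a candidate area.

    Each replicate is founded at the area center and remains iff, over
    ``min_generations`` generations from generation 0, its population
    mean strategy is never outside the area ellipse for more than
    ``departure_patience`` consecutive generations (the ellipse radius
    is inflated by ``containment_inflation``; both margins absorb the
    short stationary excursions expected past a 95%-coverage boundary,
    while a population that truly left does not return).  Extinction
    before the horizon counts as departure.  Returns the verdict
    ("stable" if all 36 remain, "semi_stable" if some, "none" if none)
    and the count remaining.
    """
    if seeds is None:
        seeds = (
            np.random.SeedSequence(config.seed + 1).generate_state(n_replicates)
            % (2**31)
        )
    test_shape = EllipseShape(
        center=area.shape.center,
        cov=area.shape.cov,
        radius=area.shape.radius * containment_inflation,
    )
    remaining = 0
    for s in seeds[:n_replicates]:
        traj = run_evolution(
            config.with_(
                initial_strategy=area.center,
                seed=int(s),
                generation_cap=min_generations,
            )
        )
        if traj.terminal_generation < min_generations:
            continue  # extinct before the containment horizon
        outside = ~test_shape.contains(traj.mean_strategy)
        if not outside.any():
            remaining += 1
            continue
        # longest run of consecutive generations spent outside
        changes = np.diff(np.concatenate([[0], outside.view(np.int8), [0]]))
        run_lengths = np.flatnonzero(changes == -1) - np.flatnonzero(changes == 1)
        if run_lengths.max() <= departure_patience:
            remaining += 1
    if remaining == n_replicates:
        return "stable", remaining
    if remaining > 0:
        return "semi_stable", remaining
    return "none", 0


def _interior_mask(area: StableArea, landscape: LandscapeSet) -> tuple[np.ndarray, bool]:
    gg, ee = np.meshgrid(
        landscape.grid.gamma_values, landscape.grid.epsilon_values, indexing="ij"
    )
    pts = np.column_stack([gg.ravel(), ee.ravel()])
    mask = area.shape.contains(pts).reshape(gg.shape)
    empty = not mask.any()
    if empty:
        # ellipse fell between grid points: evaluate at the nearest cell
        d2 = (gg - area.center.gamma) ** 2 + (ee - area.center.epsilon) ** 2
        mask = d2 == d2.min()
    return mask, empty


def classify_landscape(
    area: StableArea | None,
    landscape: LandscapeSet,
    mutualism_threshold: float = 0.99,
    parasitism_threshold: float = 0.01,
) -> tuple[str, bool, frozenset]:
    """Zone classification of a (confirmed) stable area.

    Returns (category, novel_flag, interaction types spanned).  With no
    area the category is "none".  Zone fractions are taken over the
    non-neutral interior cells: a neutral cell marks a fitness *tie*
    (e.g. an organism with zero nonspecialised uptake that never grows
    off its baseline), which is neither benefit nor detriment and so
    cannot decide between the benefit-based categories.  An area whose
    interior is entirely neutral is flagged novel.
    """
    if area is None:
        return CATEGORY_NONE, False, frozenset()
    mask, _ = _interior_mask(area, landscape)
    codes = landscape.interaction_type[mask]
    spanned = frozenset(t for t in InteractionType if np.any(codes == t))
    codes = codes[codes != InteractionType.NEUTRAL]
    n = len(codes)
    if n == 0:
        return CATEGORY_NOVEL, True, spanned
    frac = {t: np.count_nonzero(codes == t) / n for t in InteractionType}
    if frac[InteractionType.MUTUALISM] >= mutualism_threshold:
        return CATEGORY_MUTUALISM, False, spanned
    par_frac = sum(frac[t] for t in _PARASITIC)
    if frac[InteractionType.MUTUALISM] > 0 and par_frac >= parasitism_threshold:
        return CATEGORY_MUT_PAR, False, spanned
    return CATEGORY_NOVEL, True, spanned


def area_fitness_maxima(
    area: StableArea, landscape: LandscapeSet
) -> dict[str, float | bool]:
    """Fitness maxima inside the area and coincidence with global maxima.

    The coincidence flag is true when some globally maximal cell lies
    inside the area or within one grid cell of its boundary.
    """
    mask, empty = _interior_mask(area, landscape)
    maxima = fitness_maxima(landscape)
    out: dict[str, float | bool] = {"empty_interior": empty}
    dg = np.diff(landscape.grid.gamma_values).max(initial=0.0)
    de = np.diff(landscape.grid.epsilon_values).max(initial=0.0)
    pad = float(np.hypot(dg, de))
    interior_pts = np.column_stack(
        [
            np.meshgrid(
                landscape.grid.gamma_values,
                landscape.grid.epsilon_values,
                indexing="ij",
            )[0][mask],
            np.meshgrid(
                landscape.grid.gamma_values,
                landscape.grid.epsilon_values,
                indexing="ij",
            )[1][mask],
        ]
    )
    for organ, layer in (
        ("plant", landscape.plant_fitness),
        ("fungus", landscape.fungus_fitness),
    ):
        out[f"max_{organ}_fitness_in_area"] = float(layer[mask].max())
        tied = maxima[f"{organ}_fitness"].tied
        coincide = False
        for s in tied:
            d = np.hypot(
                interior_pts[:, 0] - s.gamma, interior_pts[:, 1] - s.epsilon
            ).min()
            if d <= pad:
                coincide = True
                break
        out[f"{organ}_max_coincides"] = coincide
    return out


def characterize_uptake(
    uptake: UptakeEfficiencies,
    config: EvolutionConfig,
    landscape_resolution: int = 201,
    n_starts: int = 9,
    n_replicates: int = 36,
    min_generations: int = DEFAULT_TAIL,
    landscape: LandscapeSet | None = None,
    seed: int | None = None,
) -> StabilityReport:
    """Full per-combination pipeline: explore, stress-test, classify."""
    if seed is not None:
        config = config.with_(seed=seed)
    config = config.with_(uptake=uptake)
    if landscape is None:
        landscape = compute_landscape(
            uptake, build_strategy_grid(landscape_resolution), T=config.T
        )
    ss = np.random.SeedSequence(config.seed)
    explore_seeds = ss.generate_state(64) % (2**31)
    candidates = explore_candidates(
        uptake, config, n_starts=n_starts, seeds=explore_seeds
    )
    best = None
    best_verdict = "none"
    best_remaining = 0
    for k, cand in enumerate(candidates):
        rep_seeds = (
            np.random.SeedSequence([config.seed, 1000 + k]).generate_state(n_replicates)
            % (2**31)
        )
        verdict, remaining = test_stability(
            cand, config, n_replicates, min_generations, seeds=rep_seeds
        )
        if verdict == "none":
            continue
        if best is None or remaining > best_remaining:
            best, best_verdict, best_remaining = cand, verdict, remaining
    if best is None:
        return StabilityReport(
            uptake=uptake,
            category=CATEGORY_NONE,
            stability="not_applicable",
            area=None,
            replicates_remaining=0,
            n_replicates=n_replicates,
            max_plant_fitness_in_area=float("nan"),
            max_fungus_fitness_in_area=float("nan"),
            n_candidates=len(candidates),
        )
    category, novel, spanned = classify_landscape(best, landscape)
    best = StableArea(
        center=best.center,
        shape=best.shape,
        uptake=uptake,
        n_points=best.n_points,
        interaction_types_spanned=spanned,
    )
    fit_info = area_fitness_maxima(best, landscape)
    return StabilityReport(
        uptake=uptake,
        category=category,
        stability=best_verdict,
        area=best,
        replicates_remaining=best_remaining,
        n_replicates=n_replicates,
        max_plant_fitness_in_area=fit_info["max_plant_fitness_in_area"],
        max_fungus_fitness_in_area=fit_info["max_fungus_fitness_in_area"],
        plant_max_coincides=fit_info["plant_max_coincides"],
        fungus_max_coincides=fit_info["fungus_max_coincides"],
        novel_outcome=novel,
        empty_interior=fit_info["empty_interior"],
        n_candidates=len(candidates),
    )


def default_sweep_grids() -> tuple[np.ndarray, np.ndarray]:
    """Reference uptake grids: plant 0..1 by 0.05, fungus 0..1 by 0.1."""
    return np.linspace(0.0, 1.0, 21), np.linspace(0.0, 1.0, 11)


@dataclass
class SweepSummary:
    """All per-combination reports plus aggregate percentages."""

    alphas: np.ndarray
    betas: np.ndarray
    reports: list[StabilityReport]
    master_seed: int

    def percentages(self) -> dict[str, float]:
        n = len(self.reports)
        counts = {
            CATEGORY_MUTUALISM: 0,
            CATEGORY_MUT_PAR: 0,
            CATEGORY_NONE: 0,
            CATEGORY_NOVEL: 0,
        }
        semi = 0
        for r in self.reports:
            counts[r.category] += 1
            if r.stability == "semi_stable":
                semi += 1
        out = {k: 100.0 * v / n for k, v in counts.items() if k != CATEGORY_NOVEL}
        if counts[CATEGORY_NOVEL]:
            out[CATEGORY_NOVEL] = 100.0 * counts[CATEGORY_NOVEL] / n
        out["semi_stable"] = 100.0 * semi / n
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.reports:
            row = {
                "alpha": r.uptake.alpha,
                "beta": r.uptake.beta,
                "category": r.category,
                "stability": r.stability,
                "replicates_remaining": r.replicates_remaining,
                "n_candidates": r.n_candidates,
                "max_plant_fitness_in_area": r.max_plant_fitness_in_area,
                "max_fungus_fitness_in_area": r.max_fungus_fitness_in_area,
            }
            if r.area is not None:
                axes = r.area.shape.semi_axes
                row.update(
                    center_gamma=r.area.center.gamma,
                    center_epsilon=r.area.center.epsilon,
                    semi_major=axes[0],
                    semi_minor=axes[1],
                    orientation=r.area.shape.orientation,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _report_payload(report: StabilityReport) -> dict:
    out = {
        "alpha": report.uptake.alpha,
        "beta": report.uptake.beta,
        "category": report.category,
        "stability": report.stability,
        "replicates_remaining": report.replicates_remaining,
        "n_replicates": report.n_replicates,
        "max_plant_fitness_in_area": report.max_plant_fitness_in_area,
        "max_fungus_fitness_in_area": report.max_fungus_fitness_in_area,
        "plant_max_coincides": report.plant_max_coincides,
        "fungus_max_coincides": report.fungus_max_coincides,
        "novel_outcome": report.novel_outcome,
        "empty_interior": report.empty_interior,
        "n_candidates": report.n_candidates,
    }
    if report.area is not None:
        out["area"] = {
            "center": list(report.area.shape.center),
            "cov": [list(r) for r in report.area.shape.cov],
            "radius": report.area.shape.radius,
            "n_points": report.area.n_points,
            "interaction_types_spanned": sorted(
                int(t) for t in report.area.interaction_types_spanned
            ),
        }
    return out


def _report_from_payload(payload: dict) -> StabilityReport:
    uptake = UptakeEfficiencies(payload["alpha"], payload["beta"])
    area = None
    if "area" in payload:
        p = payload["area"]
        shape = EllipseShape(
            center=np.asarray(p["center"], dtype=float),
            cov=np.asarray(p["cov"], dtype=float),
            radius=float(p["radius"]),
        )
        area = StableArea(
            center=ExchangeStrategy(
                float(np.clip(shape.center[0], -1, 1)),
                float(np.clip(shape.center[1], -1, 1)),
            ),
            shape=shape,
            uptake=uptake,
            n_points=p["n_points"],
            interaction_types_spanned=frozenset(
                InteractionType(t) for t in p["interaction_types_spanned"]
            ),
        )
    def _nan(v):
        return float("nan") if v is None else v

    return StabilityReport(
        uptake=uptake,
        category=payload["category"],
        stability=payload["stability"],
        area=area,
        replicates_remaining=payload["replicates_remaining"],
        n_replicates=payload["n_replicates"],
        max_plant_fitness_in_area=_nan(payload["max_plant_fitness_in_area"]),
        max_fungus_fitness_in_area=_nan(payload["max_fungus_fitness_in_area"]),
        plant_max_coincides=payload["plant_max_coincides"],
        fungus_max_coincides=payload["fungus_max_coincides"],
        novel_outcome=payload["novel_outcome"],
        empty_interior=payload["empty_interior"],
        n_candidates=payload["n_candidates"],
    )


def run_sweep(
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
    config_template: EvolutionConfig | None = None,
    master_seed: int = 0,
    landscape_resolution: int = 201,
    n_starts: int = 9,
    n_replicates: int = 36,
    min_generations: int = DEFAULT_TAIL,
    progress: bool = False,
    checkpoint_dir: "str | None" = None,
) -> SweepSummary:
    """Stability characterisation over every uptake combination.

    Per-combination seeds are derived deterministically from
    ``master_seed`` so the sweep is reproducible and each combination
    is independently re-runnable.  With ``checkpoint_dir`` each
    finished combination is written as a JSON file named after its
    uptake pair; an interrupted sweep re-run with the same directory
    and seed resumes where it stopped.
    """
    if alphas is None or betas is None:
        d_alphas, d_betas = default_sweep_grids()
        alphas = d_alphas if alphas is None else np.asarray(alphas, dtype=float)
        betas = d_betas if betas is None else np.asarray(betas, dtype=float)
    if config_template is None:
        config_template = EvolutionConfig(
            uptake=UptakeEfficiencies(0.0, 0.0),
            initial_strategy=ExchangeStrategy(0.0, 0.0),
        )
    combos = [(float(a), float(b)) for a in alphas for b in betas]
    combo_seeds = np.random.SeedSequence(master_seed).generate_state(len(combos)) % (
        2**31
    )
    ckpt = None
    if checkpoint_dir is not None:
        from pathlib import Path

        ckpt = Path(checkpoint_dir)
        ckpt.mkdir(parents=True, exist_ok=True)
    reports = []
    for (a, b), s in zip(combos, combo_seeds):
        path = ckpt / f"combo_a{a:.4f}_b{b:.4f}.json" if ckpt is not None else None
        if path is not None and path.exists():
            rep = _report_from_payload(json.loads(path.read_text()))
        else:
            rep = characterize_uptake(
                UptakeEfficiencies(a, b),
                config_template,
                landscape_resolution=landscape_resolution,
                n_starts=n_starts,
                n_replicates=n_replicates,
                min_generations=min_generations,
                seed=int(s),
            )
            if path is not None:
                path.write_text(json.dumps(_report_payload(rep), indent=2) + "\n")
        reports.append(rep)
        if progress:
            print(
                f"alpha={a:.2f} beta={b:.2f} -> {rep.category} ({rep.stability})",
                flush=True,
            )
    return SweepSummary(
        alphas=np.asarray(alphas, dtype=float),
        betas=np.asarray(betas, dtype=float),
        reports=reports,
        master_seed=master_seed,
    )
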