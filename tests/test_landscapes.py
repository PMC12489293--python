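"""Tests of the coupled-landscape layers and classification."""

import numpy as np
import pytest

from mycotrade.core import ExchangeStrategy, UptakeEfficiencies, simulate_lifecycle
from mycotrade.landscapes import (
    ExtinctionZone,
    InteractionType,
    build_strategy_grid,
    classify_point,
    compute_landscape,
    extinction_mask,
    fitness_maxima,
    resources_received,
    viable_range,
)


def grid_of(resolution):
    return build_strategy_grid(resolution)


def test_build_strategy_grid():
    g = build_strategy_grid(3)
    np.testing.assert_array_equal(g.gamma_values, [-1, 0, 1])
    g = build_strategy_grid(500)
    assert len(g.gamma_values) == 500
    assert g.gamma_values[0] == -1 and g.gamma_values[-1] == 1
    np.testing.assert_allclose(np.diff(g.gamma_values), 2 / 499)
    g = build_strategy_grid(2, 0, 1)
    np.testing.assert_array_equal(g.epsilon_values, [0, 1])
    with pytest.raises(ValueError):
        build_strategy_grid(1)
    with pytest.raises(ValueError):
        build_strategy_grid(10, 0.5, 0.5)


def test_landscape_matches_pointwise_lifecycle(rng):
    uptake = UptakeEfficiencies(0.3, 0.6)
    ls = compute_landscape(uptake, grid_of(41))
    for _ in range(50):
        i = rng.integers(41)
        j = rng.integers(41)
        res = simulate_lifecycle(
            uptake,
            ExchangeStrategy(
                float(ls.grid.gamma_values[i]), float(ls.grid.epsilon_values[j])
            ),
        )
        assert ls.plant_fitness[i, j] == pytest.approx(res.plant_fitness, rel=1e-12)
        assert ls.fungus_fitness[i, j] == pytest.approx(res.fungus_fitness, rel=1e-12)
        assert ls.total_p_to_plant[i, j] == pytest.approx(
            res.total_p_to_plant, rel=1e-12, abs=1e-12
        )


def test_baselines_are_exact_closed_forms():
    ls = compute_landscape(UptakeEfficiencies(0.1, 0.1), grid_of(21))
    assert ls.baseline_plant_fitness == pytest.approx(1.1**10, rel=1e-14)
    assert ls.baseline_fungus_fitness == pytest.approx(1.1**10, rel=1e-14)


def test_classify_point_cases():
    base = 1.1**10
    assert classify_point(base, base, base, base) is InteractionType.NEUTRAL
    assert classify_point(57.0, 57.0, base, base) is InteractionType.MUTUALISM
    assert classify_point(1.0, 1.0, base, base) is InteractionType.COMPETITION
    assert classify_point(57.0, 1.0, base, base) is InteractionType.PLANT_PARASITIC
    assert classify_point(1.0, 57.0, base, base) is InteractionType.FUNGUS_PARASITIC


def test_commensal_edge_is_neutral():
    """A plant with zero P uptake ties its baseline whatever the fungus does."""
    res = simulate_lifecycle(UptakeEfficiencies(0.0, 0.5), ExchangeStrategy(0.5, 0.0))
    # hand iteration: Y_{n+1} = 1.5 Y_n + 0.5 from Y_0 = 1
    y = 1.0
    for _ in range(10):
        y = 1.5 * y + 0.5
    assert res.plant_fitness == 1.0
    assert res.fungus_fitness == pytest.approx(y, rel=1e-12)
    cat = classify_point(res.plant_fitness, res.fungus_fitness, 1.0, 1.5**10)
    assert cat is InteractionType.NEUTRAL


def test_partitions_assign_exactly_one_category():
    ls = compute_landscape(UptakeEfficiencies(0.4, 0.7), grid_of(31))
    assert set(np.unique(ls.interaction_type)) <= {int(t) for t in InteractionType}
    assert set(np.unique(ls.extinction)) <= {int(z) for z in ExtinctionZone}
    # origin cell is neutral and its extinction matches the baseline flags
    i = j = 15  # gamma = epsilon = 0 on a 31-point grid
    assert ls.grid.gamma_values[i] == 0.0
    assert ls.interaction_type[i, j] == InteractionType.NEUTRAL
    assert ls.extinction[i, j] == ExtinctionZone.NONE  # both grow alone here


def test_extinction_categories():
    ls = compute_landscape(UptakeEfficiencies(0.0, 0.0), grid_of(3))
    assert ls.extinction[1, 1] == ExtinctionZone.BOTH  # origin, no uptake
    ls = compute_landscape(UptakeEfficiencies(0.1, 0.0), grid_of(3))
    assert ls.extinction[1, 1] == ExtinctionZone.FUNGUS_ONLY
    mask = extinction_mask(ls)
    np.testing.assert_array_equal(mask, ls.extinction)


@pytest.mark.parametrize("resolution", [21, 40])
def test_no_uptake_viability_is_open_unit_square(resolution):
    """With alpha = beta = 0 both grow exactly when 0 < gamma < 1 and 0 < epsilon < 1."""
    ls = compute_landscape(UptakeEfficiencies(0, 0), grid_of(resolution))
    viable = viable_range(ls)
    gg, ee = np.meshgrid(ls.grid.gamma_values, ls.grid.epsilon_values, indexing="ij")
    expected = (gg > 0) & (gg < 1) & (ee > 0) & (ee < 1)
    np.testing.assert_array_equal(viable, expected)
    np.testing.assert_array_equal(viable, ls.extinction == ExtinctionZone.NONE)


def test_full_uptake_origin_viable_and_no_mutualism():
    ls = compute_landscape(UptakeEfficiencies(1, 1), grid_of(21))
    assert viable_range(ls)[10, 10]  # both double each step alone
    # nothing beats unconstrained doubling: the mutualism zone is empty
    assert not np.any(ls.interaction_type == InteractionType.MUTUALISM)


def test_transpose_symmetry_for_equal_uptake():
    ls = compute_landscape(UptakeEfficiencies(0.3, 0.3), grid_of(21))
    np.testing.assert_allclose(ls.plant_fitness, ls.fungus_fitness.T, rtol=1e-12)
    np.testing.assert_allclose(ls.total_p_to_plant, ls.total_c_to_fungus.T, rtol=1e-12)


def test_resources_received():
    assert resources_received(
        UptakeEfficiencies(0.3, 0.6), ExchangeStrategy(0, 0)
    ) == (0.0, 0.0)
    p, c = resources_received(UptakeEfficiencies(0, 0), ExchangeStrategy(0.3, 0))
    assert (p, c) == (0.0, pytest.approx(3.0, abs=1e-12))
    _, c = resources_received(UptakeEfficiencies(0.7, 0.0), ExchangeStrategy(-0.5, 0.2))
    assert c == 0.0  # nothing to take from a fungus that gathers no C


def test_fitness_maxima_symmetric_no_uptake():
    # grid containing 0.5 exactly: 21 points over [-1, 1]
    ls = compute_landscape(UptakeEfficiencies(0, 0), grid_of(21))
    m = fitness_maxima(ls)
    assert m["plant_fitness"].strategy == ExchangeStrategy(0.5, 0.5)
    assert m["fungus_fitness"].strategy == ExchangeStrategy(0.5, 0.5)
    assert m["plant_fitness"].value == pytest.approx(1.5**10, rel=1e-12)


def test_fitness_maxima_full_uptake_plant_prefers_keeping():
    ls = compute_landscape(UptakeEfficiencies(1, 1), grid_of(51))
    m = fitness_maxima(ls)
    assert all(s.gamma <= 0 for s in m["plant_fitness"].tied)


def test_fitness_maxima_constant_layer_reports_all_ties():
    ls = compute_landscape(UptakeEfficiencies(0, 0), grid_of(5))
    # plant fitness is constant (=1) along epsilon <= 0: check tie reporting on
    # a fully constant layer instead
    const = np.zeros_like(ls.plant_fitness)
    from mycotrade.landscapes import _argmax_layer

    res = _argmax_layer(const, ls.grid)
    assert len(res.tied) == 25
    assert res.strategy == ExchangeStrategy(-1.0, -1.0)
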