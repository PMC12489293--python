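"""Tests of the individual-based evolution model."""

import numpy as np
import pytest

from mycotrade.core import ExchangeStrategy, UptakeEfficiencies
from mycotrade.evolution import (
    EvolutionConfig,
    init_populations,
    run_evolution,
    step_generation,
)
from mycotrade.fixtures import selection_case


def make_config(**kwargs):
    base = dict(
        uptake=UptakeEfficiencies(0.1, 0.1),
        initial_strategy=ExchangeStrategy(0.2, 0.3),
        population_size=50,
        generation_cap=20,
        seed=7,
    )
    base.update(kwargs)
    return EvolutionConfig(**base)


def test_init_populations_monomorphic_and_spread():
    cfg = make_config(initial_spread=0.0, population_size=200)
    rng = np.random.default_rng(0)
    gam, eps = init_populations(cfg, rng)
    assert len(gam) == len(eps) == 200
    assert np.all(gam == 0.2) and np.all(eps == 0.3)
    cfg = make_config(initial_spread=0.5, population_size=200)
    gam, eps = init_populations(cfg, np.random.default_rng(0))
    gam2, eps2 = init_populations(cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(gam, gam2)
    assert np.all(np.abs(gam) <= 1) and np.all(np.abs(eps) <= 1)
    assert gam.std() > 0


def test_step_generation_flags_extinction():
    cfg = make_config(uptake=UptakeEfficiencies(0, 0),
                      initial_strategy=ExchangeStrategy(0, 0))
    rng = np.random.default_rng(1)
    gam, eps = init_populations(cfg, rng)
    nxt_g, nxt_e, rec, (px, fx) = step_generation(gam, eps, cfg.uptake, cfg, rng)
    assert px and fx
    assert nxt_g is None and nxt_e is None
    assert rec.frac_plants_grew == 0.0 and rec.frac_fungi_grew == 0.0


def test_step_generation_zero_mutation_is_static():
    cfg = make_config(mutation_sd=0.0)
    rng = np.random.default_rng(2)
    gam, eps = init_populations(cfg, rng)
    nxt_g, nxt_e, rec, _ = step_generation(gam, eps, cfg.uptake, cfg, rng)
    assert np.all(nxt_g == 0.2) and np.all(nxt_e == 0.3)
    for engine in ("reference", "fast"):
        traj = run_evolution(cfg.with_(mutation_sd=0.0, engine=engine))
        np.testing.assert_allclose(traj.mean_gamma, 0.2, rtol=1e-14)
        np.testing.assert_allclose(traj.mean_epsilon, 0.3, rtol=1e-14)
        assert np.all(traj.final_plant_traits == 0.2)


def test_step_generation_rejects_mismatched_sizes():
    cfg = make_config()
    with pytest.raises(ValueError):
        step_generation(np.zeros(5), np.zeros(6), cfg.uptake, cfg,
                        np.random.default_rng(0))


def test_selection_response_matches_analytic_expectation():
    """The favoured genotype's expected offspring share is w-weighted."""
    case = selection_case()
    n, k = case["population_size"], case["g1_count"]
    cfg = make_config(
        uptake=UptakeEfficiencies(case["alpha"], case["beta"]),
        population_size=n,
        mutation_sd=0.0,
    )
    gam = np.array([case["g1"]] * k + [case["g2"]] * (n - k))
    eps = np.full(n, case["fungus_epsilon"])
    rng = np.random.default_rng(123)
    shares = []
    for _ in range(300):
        nxt_g, _, _, _ = step_generation(gam, eps, cfg.uptake, cfg, rng)
        shares.append(np.mean(nxt_g == case["g1"]))
    observed = float(np.mean(shares))
    expected = case["expected_g1_offspring_share"]
    se = np.sqrt(expected * (1 - expected) / (n * 300))
    assert observed == pytest.approx(expected, abs=5 * se)
    assert expected > k / n  # the fitter genotype gains ground


@pytest.mark.parametrize("engine", ["reference", "fast"])
def test_trajectories_are_deterministic_per_seed(engine):
    cfg = make_config(engine=engine, generation_cap=30)
    a = run_evolution(cfg)
    b = run_evolution(cfg)
    np.testing.assert_array_equal(a.mean_gamma, b.mean_gamma)
    np.testing.assert_array_equal(a.mean_epsilon, b.mean_epsilon)
    assert a.outcome == b.outcome
    c = run_evolution(cfg.with_(seed=cfg.seed + 1))
    assert not np.array_equal(a.mean_gamma, c.mean_gamma)


@pytest.mark.parametrize("engine", ["reference", "fast"])
def test_extinction_only_founding_terminates_immediately(engine):
    cfg = make_config(
        uptake=UptakeEfficiencies(0, 0),
        initial_strategy=ExchangeStrategy(0, 0),
        engine=engine,
    )
    traj = run_evolution(cfg)
    assert traj.outcome == "both_extinct"
    assert traj.terminal_generation == 1
    assert len(traj.records) == 1 and traj.records[0].generation == 0


def test_traits_stay_in_bounds_and_population_constant():
    cfg = make_config(
        uptake=UptakeEfficiencies(0.1, 0.0),
        initial_strategy=ExchangeStrategy(0.9, 0.9),
        mutation_sd=0.1,
        generation_cap=50,
        engine="reference",
    )
    traj = run_evolution(cfg)
    assert np.all(np.abs(traj.mean_gamma) <= 1)
    assert np.all(np.abs(traj.mean_epsilon) <= 1)
    assert len(traj.final_plant_traits) == cfg.population_size
    assert np.all(np.abs(traj.final_plant_traits) <= 1)


def test_engines_agree_statistically():
    """Both engines settle the low-uptake mutualism at the same strategy."""
    cfg = make_config(
        uptake=UptakeEfficiencies(0.1, 0.1),
        initial_strategy=ExchangeStrategy(0.4, 0.4),
        population_size=200,
        mutation_sd=0.02,
        generation_cap=400,
    )
    ends = {}
    for engine in ("reference", "fast"):
        traj = run_evolution(cfg.with_(engine=engine))
        assert traj.outcome == "reached_cap"
        ends[engine] = traj.mean_strategy[-100:].mean(axis=0)
    np.testing.assert_allclose(ends["reference"], ends["fast"], atol=0.05)


def test_third_quadrant_high_uptake_escalates_to_extinction():
    """Mutual taking ratchets downward and collapses the pairing."""
    cfg = make_config(
        uptake=UptakeEfficiencies(0.8, 0.8),
        initial_strategy=ExchangeStrategy(-0.3, -0.3),
        population_size=200,
        generation_cap=2000,
        mutation_sd=0.02,
    )
    extinct = 0
    more_negative = 0
    for seed in range(8):
        traj = run_evolution(cfg.with_(seed=500 + seed))
        if traj.outcome != "reached_cap":
            extinct += 1
        end = traj.mean_strategy[-1]
        if end[0] < -0.3 and end[1] < -0.3:
            more_negative += 1
    assert extinct >= 7
    assert more_negative >= 7
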