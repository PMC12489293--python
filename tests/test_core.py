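"""Unit and property tests of the lifecycle model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mycotrade.core import (
    ExchangeStrategy,
    UptakeEfficiencies,
    closed_form_fitness,
    lifecycle_arrays,
    resolve_exchange,
    simulate_lifecycle,
)
from mycotrade.fixtures import exchange_cases, lifecycle_cases

from conftest import ledger_lifecycle

uptakes = st.floats(0, 1)
strategies = st.floats(-1, 1)


@pytest.mark.parametrize("case", exchange_cases())
def test_exchange_matches_hand_ledger(case):
    """Single steps reproduce hand bookkeeping, clamp branches included."""
    out = resolve_exchange(
        case["x"],
        case["y"],
        UptakeEfficiencies(case["alpha"], case["beta"]),
        ExchangeStrategy(case["gamma"], case["epsilon"]),
    )
    for key, expected in case["expected"].items():
        assert getattr(out, key) == pytest.approx(expected, abs=1e-12), key


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(x=0.0, y=1.0),
        dict(x=1.0, y=-1.0),
    ],
)
def test_exchange_rejects_nonpositive_biomass(kwargs):
    with pytest.raises(ValueError):
        resolve_exchange(
            kwargs.get("x", 1.0),
            kwargs.get("y", 1.0),
            UptakeEfficiencies(0.1, 0.1),
            ExchangeStrategy(0.0, 0.0),
        )


@pytest.mark.parametrize(
    "cls,args", [
        (UptakeEfficiencies, (-0.1, 0.0)),
        (UptakeEfficiencies, (0.0, 1.2)),
        (ExchangeStrategy, (-1.5, 0.0)),
        (ExchangeStrategy, (0.0, 1.01)),
    ],
)
def test_parameter_domain_errors(cls, args):
    with pytest.raises(ValueError):
        cls(*args)


@pytest.mark.parametrize("case", lifecycle_cases())
def test_lifecycle_matches_closed_forms(case):
    """No-exchange and symmetric-giving lifetimes follow geometric growth."""
    res = simulate_lifecycle(
        UptakeEfficiencies(case["alpha"], case["beta"]),
        ExchangeStrategy(case["gamma"], case["epsilon"]),
        T=case["T"],
    )
    assert res.plant_fitness == pytest.approx(
        case["expected"]["plant_fitness"], rel=1e-12
    )
    assert res.fungus_fitness == pytest.approx(
        case["expected"]["fungus_fitness"], rel=1e-12
    )


def test_closed_form_cases():
    T = 10
    assert closed_form_fitness(
        UptakeEfficiencies(0.2, 0.5), ExchangeStrategy(0, 0), T
    ) == pytest.approx((1.2**10, 1.5**10))
    assert closed_form_fitness(
        UptakeEfficiencies(0, 0), ExchangeStrategy(1, 1), T
    ) == pytest.approx((1.0, 1.0))
    assert (
        closed_form_fitness(UptakeEfficiencies(0.3, 0.1), ExchangeStrategy(0.2, 0.1), T)
        is None
    )


def test_no_uptake_no_exchange_never_grows():
    res = simulate_lifecycle(UptakeEfficiencies(0, 0), ExchangeStrategy(0, 0))
    assert res.plant_fitness == 1.0 and res.fungus_fitness == 1.0
    assert not res.plant_grew and not res.fungus_grew


def test_transfer_totals_and_splits():
    # plant keeps biomass 1 and donates 0.3 C per step for 10 steps
    res = simulate_lifecycle(UptakeEfficiencies(0, 0), ExchangeStrategy(0.3, 0))
    assert res.total_c_to_fungus == pytest.approx(3.0, abs=1e-12)
    assert res.fungus_fitness == pytest.approx(4.0, abs=1e-12)
    assert res.c_given == pytest.approx(3.0) and res.c_taken == 0.0
    # nothing to take from a fungus that gathers no C
    res = simulate_lifecycle(UptakeEfficiencies(0.4, 0.0), ExchangeStrategy(-0.5, 0))
    assert res.total_c_to_fungus == 0.0


@settings(max_examples=300, derandomize=True, deadline=None)
@given(alpha=uptakes, beta=uptakes, gamma=strategies, epsilon=strategies)
def test_lifecycle_invariants(alpha, beta, gamma, epsilon):
    """Monotone biomass, fitness >= 1, per-step conservation, pools >= 0."""
    uptake = UptakeEfficiencies(alpha, beta)
    strategy = ExchangeStrategy(gamma, epsilon)
    res = simulate_lifecycle(uptake, strategy)
    assert np.all(np.diff(res.plant_biomass) >= 0)
    assert np.all(np.diff(res.fungus_biomass) >= 0)
    assert res.plant_fitness >= 1.0 and res.fungus_fitness >= 1.0
    for x, y in zip(res.plant_biomass[:-1], res.fungus_biomass[:-1]):
        step = resolve_exchange(x, y, uptake, strategy)
        # redistribution: gathered C and P are moved, never created
        assert step.plant_c_pool + step.fungus_c_pool == pytest.approx(
            x + beta * y, rel=1e-12, abs=1e-12
        )
        assert step.plant_p_pool + step.fungus_p_pool == pytest.approx(
            alpha * x + y, rel=1e-12, abs=1e-12
        )
        for pool in (
            step.plant_c_pool,
            step.plant_p_pool,
            step.fungus_c_pool,
            step.fungus_p_pool,
        ):
            assert pool >= -1e-12


@settings(max_examples=200, derandomize=True, deadline=None)
@given(alpha=uptakes, beta=uptakes, gamma=strategies, epsilon=strategies)
def test_role_symmetry(alpha, beta, gamma, epsilon):
    """Swapping (alpha, gamma) with (beta, epsilon) swaps the two fitnesses."""
    res = simulate_lifecycle(UptakeEfficiencies(alpha, beta), ExchangeStrategy(gamma, epsilon))
    swapped = simulate_lifecycle(
        UptakeEfficiencies(beta, alpha), ExchangeStrategy(epsilon, gamma)
    )
    assert res.plant_fitness == pytest.approx(swapped.fungus_fitness, rel=1e-12)
    assert res.fungus_fitness == pytest.approx(swapped.plant_fitness, rel=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(alpha=uptakes, beta=uptakes, gamma=strategies, epsilon=strategies)
def test_scalar_matches_vectorized(alpha, beta, gamma, epsilon):
    res = simulate_lifecycle(UptakeEfficiencies(alpha, beta), ExchangeStrategy(gamma, epsilon))
    vec = lifecycle_arrays(alpha, beta, gamma, epsilon)
    assert float(vec["plant_fitness"]) == pytest.approx(res.plant_fitness, rel=1e-12)
    assert float(vec["fungus_fitness"]) == pytest.approx(res.fungus_fitness, rel=1e-12)
    assert float(vec["total_c_to_fungus"]) == pytest.approx(
        res.total_c_to_fungus, rel=1e-12, abs=1e-12
    )


def test_ledger_oracle_equivalence(rng):
    """Explicit bookkeeping oracle agrees with the implementation."""
    for _ in range(500):
        a, b = rng.uniform(0, 1, 2)
        g, e = rng.uniform(-1, 1, 2)
        res = simulate_lifecycle(UptakeEfficiencies(a, b), ExchangeStrategy(g, e))
        oracle = ledger_lifecycle(a, b, g, e)
        assert res.plant_fitness == pytest.approx(oracle["plant_fitness"], rel=1e-12)
        assert res.fungus_fitness == pytest.approx(oracle["fungus_fitness"], rel=1e-12)
        np.testing.assert_allclose(res.plant_biomass, oracle["plant_biomass"], rtol=1e-12)


def test_custom_timestep_count():
    res = simulate_lifecycle(UptakeEfficiencies(0.1, 0.1), ExchangeStrategy(0, 0), T=3)
    assert res.plant_fitness == pytest.approx(1.1**3, rel=1e-12)
    with pytest.raises(ValueError):
        simulate_lifecycle(UptakeEfficiencies(0.1, 0.1), ExchangeStrategy(0, 0), T=0)
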