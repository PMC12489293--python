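"""Shared helpers: an independent scalar ledger oracle.

The ledger below re-derives the gather/give/take/clamp/grow bookkeeping
step by step in plain python, independently of the package's
implementation, so tests can compare the two routes.
"""

from __future__ import annotations

import numpy as np
import pytest


def ledger_step(x, y, alpha, beta, gamma, epsilon):
    """One explicit bookkeeping step; returns (pools, transfers, growths)."""
    # gather
    plant_c = x
    plant_p = alpha * x
    fungus_p = y
    fungus_c = beta * y
    # exchange: one transfer per resource
    if gamma >= 0:
        moved_c = gamma * plant_c  # plant gives
    else:
        want = -gamma * plant_c  # plant takes, at most what fungus gathered
        moved_c = -min(want, fungus_c)
    if epsilon >= 0:
        moved_p = epsilon * fungus_p  # fungus gives
    else:
        want = -epsilon * fungus_p
        moved_p = -min(want, plant_p)
    plant_c -= moved_c
    fungus_c += moved_c
    fungus_p -= moved_p
    plant_p += moved_p
    # grow by the scarcer pool
    return (
        (plant_c, plant_p, fungus_c, fungus_p),
        (moved_c, moved_p),
        (min(plant_c, plant_p), min(fungus_c, fungus_p)),
    )


def ledger_lifecycle(alpha, beta, gamma, epsilon, T=10):
    """Full lifetime by explicit bookkeeping; returns dict of outputs."""
    x, y = 1.0, 1.0
    c_net = p_net = 0.0
    xs, ys = [x], [y]
    for _ in range(T):
        _, (mc, mp), (gx, gy) = ledger_step(x, y, alpha, beta, gamma, epsilon)
        x += gx
        y += gy
        c_net += mc
        p_net += mp
        xs.append(x)
        ys.append(y)
    return {
        "plant_fitness": x,
        "fungus_fitness": y,
        "total_c_to_fungus": c_net,
        "total_p_to_plant": p_net,
        "plant_biomass": np.array(xs),
        "fungus_biomass": np.array(ys),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
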