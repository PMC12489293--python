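"""Reference fixtures for validating the trade model.

Small parameter sets with independently derived expected values,
emitted as plain JSON: hand-ledger single-step exchange cases
(including the take-clamp branches), closed-form lifecycle fitnesses, a
tiny landscape with its expected viability pattern, and a two-genotype
selection scenario with its analytic one-generation expectation.  The
expected numbers below are hand bookkeeping or textbook formulas, not
output of the simulation code, so the test suite can use them as an
independent oracle.
"""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["exchange_cases", "lifecycle_cases", "landscape_case", "selection_case", "generate_fixtures"]


def exchange_cases() -> list[dict]:
    """Single-step ledgers: gather, give/take with clamp, grow."""
    return [
        # symmetric giving: plant gathers C=1, P=0.1; fungus P=1, C=0.2;
        # transfers 0.3 C and 0.4 P
        {
            "x": 1.0, "y": 1.0, "alpha": 0.1, "beta": 0.2, "gamma": 0.3, "epsilon": 0.4,
            "expected": {
                "c_transfer": 0.3, "p_transfer": 0.4,
                "plant_c_pool": 0.7, "plant_p_pool": 0.5,
                "fungus_c_pool": 0.5, "fungus_p_pool": 0.6,
                "plant_growth": 0.5, "fungus_growth": 0.5,
            },
        },
        # plant tries to take 5 C but the fungus only gathered 0.2
        {
            "x": 10.0, "y": 1.0, "alpha": 0.0, "beta": 0.2, "gamma": -0.5, "epsilon": 0.0,
            "expected": {
                "c_transfer": -0.2, "p_transfer": 0.0,
                "plant_c_pool": 10.2, "plant_p_pool": 0.0,
                "fungus_c_pool": 0.0, "fungus_p_pool": 1.0,
                "plant_growth": 0.0, "fungus_growth": 0.0,
            },
        },
        # empty-pool clamp: fungus gathered no C, nothing to take
        {
            "x": 1.0, "y": 1.0, "alpha": 0.3, "beta": 0.0, "gamma": -0.5, "epsilon": 0.0,
            "expected": {
                "c_transfer": 0.0, "p_transfer": 0.0,
                "plant_c_pool": 1.0, "plant_p_pool": 0.3,
                "fungus_c_pool": 0.0, "fungus_p_pool": 1.0,
                "plant_growth": 0.3, "fungus_growth": 0.0,
            },
        },
        # mutual taking, both clamped against the partner's gathered pool
        {
            "x": 2.0, "y": 1.0, "alpha": 0.5, "beta": 0.5, "gamma": -1.0, "epsilon": -1.0,
            "expected": {
                # plant takes min(2, 0.5) = 0.5 C; fungus takes min(1, 1) = 1 P
                "c_transfer": -0.5, "p_transfer": -1.0,
                "plant_c_pool": 2.5, "plant_p_pool": 0.0,
                "fungus_c_pool": 0.0, "fungus_p_pool": 2.0,
                "plant_growth": 0.0, "fungus_growth": 0.0,
            },
        },
        # give-everything edge: donor's own pool empties
        {
            "x": 1.0, "y": 1.0, "alpha": 0.2, "beta": 0.3, "gamma": 1.0, "epsilon": 0.5,
            "expected": {
                "c_transfer": 1.0, "p_transfer": 0.5,
                "plant_c_pool": 0.0, "plant_p_pool": 0.7,
                "fungus_c_pool": 1.3, "fungus_p_pool": 0.5,
                "plant_growth": 0.0, "fungus_growth": 0.5,
            },
        },
    ]


def lifecycle_cases(T: int = 10) -> list[dict]:
    """Closed-form lifetime fitness pairs."""
    cases = []
    for a, b in [(0.0, 0.0), (0.1, 0.3), (0.2, 0.5), (1.0, 1.0)]:
        cases.append(
            {
                "alpha": a, "beta": b, "gamma": 0.0, "epsilon": 0.0, "T": T,
                "expected": {
                    "plant_fitness": (1.0 + a) ** T,
                    "fungus_fitness": (1.0 + b) ** T,
                },
            }
        )
    for g in [0.3, 0.5, 1.0]:
        m = min(g, 1.0 - g)
        cases.append(
            {
                "alpha": 0.0, "beta": 0.0, "gamma": g, "epsilon": g, "T": T,
                "expected": {
                    "plant_fitness": (1.0 + m) ** T,
                    "fungus_fitness": (1.0 + m) ** T,
                },
            }
        )
    return cases


def landscape_case() -> dict:
    """5x5 grid at alpha = beta = 0: who can grow at all?

    Without nonspecialised uptake each organism's limiting pool is what
    its partner gives, and a full give empties the giver's own pool, so
    both grow exactly when both strategies lie strictly inside (0, 1).
    """
    values = [-1.0, -0.5, 0.0, 0.5, 1.0]
    viable = [[0 < g < 1 and 0 < e < 1 for e in values] for g in values]
    return {
        "alpha": 0.0,
        "beta": 0.0,
        "gamma_values": values,
        "epsilon_values": values,
        "expected_viable": viable,
        "expected_interaction_at_origin": "neutral",
    }


def selection_case() -> dict:
    """Two plant genotypes against a monomorphic fungus population.

    With fungi all at epsilon = 0.5 and alpha = beta = 0, a plant's
    fitness depends only on its own gamma: w(g) = lifetime fitness of
    the pair (g, 0.5).  For k copies of g1 and n-k of g2, the expected
    offspring share of g1 under fitness-proportional sampling is
    k*w1 / (k*w1 + (n-k)*w2) exactly.
    """
    # w(g) with alpha=beta=0, partner eps=0.5: X_{n+1} = X_n + min(0.5*Y_n, (1-g)*X_n),
    # Y_{n+1} = Y_n + min(0.5*Y_n, g*X_n) -- evaluated by hand iteration for
    # g=0.5 (symmetric closed form) and g=0.25.
    w_half = 1.5**10  # = 57.6650390625
    # hand iteration for g = 0.25 (10 steps), X=Y=1 initially:
    x, y = 1.0, 1.0
    for _ in range(10):
        x, y = x + min(0.5 * y, 0.75 * x), y + min(0.5 * y, 0.25 * x)
    n, k = 200, 50
    share = k * w_half / (k * w_half + (n - k) * x)
    return {
        "alpha": 0.0, "beta": 0.0, "fungus_epsilon": 0.5,
        "g1": 0.5, "g2": 0.25, "population_size": n, "g1_count": k,
        "w1": w_half, "w2": x,
        "expected_g1_offspring_share": share,
    }


def generate_fixtures(outdir: Path | str) -> list[Path]:
    """Emit all fixture families as JSON files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "exchange_cases.json": exchange_cases(),
        "lifecycle_cases.json": lifecycle_cases(),
        "landscape_case.json": landscape_case(),
        "selection_case.json": selection_case(),
    }
    paths = []
    for name, payload in files.items():
        p = outdir / name
        p.write_text(json.dumps(payload, indent=2) + "\n")
        paths.append(p)
    return paths
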