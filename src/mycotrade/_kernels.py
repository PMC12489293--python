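"""Numba-compiled inner loops for the individual-based evolution model.

The kernel reproduces exactly the generation cycle of
:mod:`mycotrade.evolution`: uniform one-to-one pairing, paired
lifecycles, fitness-proportional reproduction with the no-growth
exclusion, Gaussian mutation and [-1, 1] clipping.  It uses numba's own
RNG (seeded per call), so trajectories are deterministic per seed but
follow a different random stream from the numpy reference engine.

If numba is unavailable at import time a pure-python fallback with the
same call signature (and same numpy legacy RNG) is used.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - numba is a declared dependency
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

GROWTH_TOL = 1e-12

OUTCOME_REACHED_CAP = 0
OUTCOME_PLANT_EXTINCT = 1
OUTCOME_FUNGUS_EXTINCT = 2
OUTCOME_BOTH_EXTINCT = 3


@njit(cache=True)
def evolution_kernel(
    gamma0,
    eps0,
    alpha,
    beta,
    T,
    generation_cap,
    mutation_sd,
    seed,
    weight_gained,
):
    """Run one evolution simulation to extinction or the generation cap.

    Returns (mean_gamma, mean_epsilon, frac_plants_grew, frac_fungi_grew,
    n_records, outcome_code, final_gamma, final_epsilon); the per-
    generation arrays are allocated at ``generation_cap`` length and
    only the first ``n_records`` entries are meaningful.
    """
    np.random.seed(seed)
    n = gamma0.size
    gam = gamma0.copy()
    eps = eps0.copy()
    mean_g = np.zeros(generation_cap)
    mean_e = np.zeros(generation_cap)
    frac_p = np.zeros(generation_cap)
    frac_f = np.zeros(generation_cap)
    perm = np.empty(n, dtype=np.int64)
    wp = np.empty(n)
    wf = np.empty(n)
    new_g = np.empty(n)
    new_e = np.empty(n)

    outcome = OUTCOME_REACHED_CAP
    n_records = 0
    for gen in range(generation_cap):
        # uniform one-to-one pairing (Fisher-Yates)
        for i in range(n):
            perm[i] = i
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp

        grew_p = 0
        grew_f = 0
        for i in range(n):
            g = gam[i]
            e = eps[perm[i]]
            x = 1.0
            y = 1.0
            for _ in range(T):
                if g >= 0.0:
                    ct = g * x
                else:
                    ct = -min(-g * x, beta * y)
                if e >= 0.0:
                    pt = e * y
                else:
                    pt = -min(-e * y, alpha * x)
                plant_c = x - ct
                fungus_c = beta * y + ct
                plant_p = alpha * x + pt
                fungus_p = y - pt
                x += min(plant_c, plant_p)
                y += min(fungus_c, fungus_p)
            if x > 1.0 + GROWTH_TOL:
                wp[i] = x - 1.0 if weight_gained else x
                grew_p += 1
            else:
                wp[i] = 0.0
            if y > 1.0 + GROWTH_TOL:
                wf[perm[i]] = y - 1.0 if weight_gained else y
                grew_f += 1
            else:
                wf[perm[i]] = 0.0

        mean_g[gen] = gam.mean()
        mean_e[gen] = eps.mean()
        frac_p[gen] = grew_p / n
        frac_f[gen] = grew_f / n
        n_records = gen + 1

        sum_p = wp.sum()
        sum_f = wf.sum()
        if sum_p <= 0.0 or sum_f <= 0.0:
            if sum_p <= 0.0 and sum_f <= 0.0:
                outcome = OUTCOME_BOTH_EXTINCT
            elif sum_p <= 0.0:
                outcome = OUTCOME_PLANT_EXTINCT
            else:
                outcome = OUTCOME_FUNGUS_EXTINCT
            break

        cum_p = np.cumsum(wp)
        cum_f = np.cumsum(wf)
        for i in range(n):
            u = np.random.random() * cum_p[n - 1]
            k = np.searchsorted(cum_p, u, side="right")
            if k >= n:
                k = n - 1
            v = gam[k]
            if mutation_sd > 0.0:
                v += np.random.normal(0.0, mutation_sd)
            new_g[i] = min(1.0, max(-1.0, v))

            u = np.random.random() * cum_f[n - 1]
            k = np.searchsorted(cum_f, u, side="right")
            if k >= n:
                k = n - 1
            v = eps[k]
            if mutation_sd > 0.0:
                v += np.random.normal(0.0, mutation_sd)
            new_e[i] = min(1.0, max(-1.0, v))
        gam, new_g = new_g, gam
        eps, new_e = new_e, eps

    return mean_g, mean_e, frac_p, frac_f, n_records, outcome, gam, eps
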