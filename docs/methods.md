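# Methods

## The fitness model

One plant and one mycorrhizal fungus are locked into repeated
interactions over a shared lifetime of `T = 10` timesteps. Each step
has three stages:

1. **Gather.** The plant takes up C equal to its biomass `X` (it is the
   C specialist) and P equal to `alpha * X`; the fungus takes up P equal
   to its biomass `Y` and C equal to `beta * Y`. The uptake
   efficiencies `alpha, beta` (fractions in [0, 1]) are fixed
   environmental parameters; they fold together nutrient availability
   and the organism's ability to acquire it.
2. **Exchange.** The heritable strategy `(gamma, epsilon)`, fractions in
   [-1, 1], moves resources: the plant gives `gamma * X` of its
   gathered C to the fungus, the fungus gives `epsilon * Y` of its
   gathered P to the plant. A negative component means the organism
   *takes* its specialised resource from the partner instead, clamped
   to what the partner gathered that step (you can empty the partner's
   pool, never drive it negative). Each resource moves exactly once per
   step, so the two clamps never interact.
3. **Grow.** Each organism grows by its scarcer post-exchange pool
   (Liebig's law of the minimum). Pools are then discarded: there is no
   storage between steps.

For non-negative strategies this is the recursion

    X[n+1] = X[n] + min(alpha*X[n] + eps*Y[n], X[n]*(1 - gamma))
    Y[n+1] = Y[n] + min(Y[n]*(1 - eps),  beta*Y[n] + gamma*X[n])

from `X[0] = Y[0] = 1`; final biomass is fitness. Useful closed forms
(used as test oracles): with no exchange the pair grows independently
as `(1+alpha)^T, (1+beta)^T`; with `alpha = beta = 0` and
`gamma = eps = g in [0, 1]` both grow as `(1 + min(g, 1-g))^T`.

Numerical choices: all arithmetic is double precision; transfers are
never rounded. An organism "grew" iff its final biomass exceeds
`1 + 1e-12` (the tolerance guards float noise exactly at the no-growth
boundary). `gamma = 1` (donating the entire gathered pool, hence zero
own growth that step) is legal, not an error.

## Coupled landscapes

For a fixed `(alpha, beta)` the plant and fungus fitness surfaces over
the `(gamma, epsilon)` plane are computed on an evenly spaced,
endpoint-inclusive grid (default 500 x 500 over [-1, 1]; a cell is a
point, no area weighting). Each strategy is classified against the
no-exchange baseline `(1+alpha)^T, (1+beta)^T`:

- **mutualism** — both above baseline;
- **plant/fungus parasitic** — one above, one below (named for the
  beneficiary);
- **competition** — both below;
- **neutral** — either organism within relative tolerance `1e-9` of its
  baseline. The classical three-way scheme omits ties, but ties occupy
  whole regions here (an organism with zero nonspecialised uptake never
  grows, whatever its partner does), so they get their own category and
  are never merged into parasitism or competition.

Derived layers: the **extinction zones** (which organism(s) fail to
grow), the **viable range** (both grow), lifetime transfer totals
(net signed sums of post-clamp transfers — taking accumulates
negatively — with given/taken magnitude splits also available), and
per-layer argmax strategies with exact-tie reporting (ties broken
lexicographically by `(gamma, epsilon)`).

## The individual-based evolution model

Populations of 200 plants and 200 fungi carry `gamma` and `epsilon`
respectively. Per generation: a uniform random one-to-one pairing;
each pair lives one lifecycle; reproductive weight is final biomass for
individuals that grew and 0 otherwise ("gained biomass" weighting is
available as a switch); the next generation is drawn with replacement
proportionally to weight, every offspring mutated by a Gaussian step of
SD 0.02 (strategy units) and clipped to [-1, 1]. Founding is
monomorphic by default. Extinction — a generation in which every
member of a population fails to grow — terminates the run, including
the partner population (the survivor's solo fate is out of scope).
Runs stop at extinction or a 2000-generation cap.

These internals (population size, mutation kernel, selection scheme,
pairing, founding) are the package's own reconstruction of a standard
Wright–Fisher-style design; all are exposed in `EvolutionConfig` and
none is hard-coded. Two engines implement the identical generation
cycle: a numpy reference (`step_generation`) and a numba kernel used by
default (~50x faster, needed at sweep scale). Both are deterministic
per seed; they consume different random streams, so cross-engine
agreement is statistical, not bitwise. Replicate seeds are spawned
deterministically from a master seed so any replicate can be re-run
alone.

## Finding and testing stable strategy areas

Per uptake combination:

1. **Explore.** Up to 9 evolution runs founded at viable strategies
   (taken evenly from a coarse 9 x 9 founding grid restricted to the
   viable range). Runs that reach the cap contribute the mean
   strategies of their final 500 generations — but only if that tail is
   *stationary*: the drift between the means of its first and last
   quarters must be at most half the tail's RMS spread. The ratio is
   scale-free on purpose: around a true attractor quarter-means agree
   to a small fraction of the cloud size, whereas a population
   wandering a quasi-neutral plateau (which eventually blunders into an
   extinction zone) drifts by about its whole spread.
2. **Candidate areas.** Pooled tail points (thinned by uniform stride
   to at most 2000 for the pairwise-distance step) are clustered by
   single linkage cut at 0.1 strategy units; each cluster gets a
   covariance ellipse centred on its mean and scaled so 95% of its
   points lie inside. Candidates whose ellipse leaves the [-1, 1]^2
   domain — with a margin of two mutation SDs — are discarded: within a
   couple of mutation steps of the boundary the trait distribution is
   censored by clipping, and such "areas" are boundary pinning, not
   free dynamics (at `alpha = beta = 1` exactly, a clip-pinned corner
   population survives indefinitely and would otherwise register as a
   stable mutual-taking area).
3. **Stability test.** 36 replicates are founded at the candidate
   center and run 500 generations. A replicate *remains* iff its
   population mean strategy never leaves the ellipse — radius inflated
   1.5x — for more than 10 consecutive generations, and does not go
   extinct. The margins exist because a literal all-generations-inside
   rule against a 95%-coverage boundary is unsatisfiable: a perfectly
   stationary replicate pokes just outside ~5% of generations in brief
   1–5-generation excursions; genuine departures (drift-off or death)
   exceed both margins by far. All 36 remaining makes the area
   **stable**, at least one **semi-stable**, none discards the
   candidate.
4. **Classification.** The confirmed area is located on the
   interaction-type landscape (computed at 201 x 201 inside sweeps;
   the thresholds below are config-exposed). Non-neutral interior
   cells decide: >= 99% mutualism -> *mutualism-stable*; mutualism
   present with >= 1% parasitic cells -> *mutualism–parasitism*;
   anything else raises a **novel-outcome flag** rather than being
   silently mapped. Neutral cells are excluded because a tie is
   neither benefit nor detriment; without that, edge combinations
   (`alpha = 0` or `beta = 0`) pad genuinely mutualistic areas with up
   to ~44% tie cells. The area's fitness maxima and whether the global
   per-organism argmax falls within one grid cell of the area are also
   reported.

The sweep repeats this over 21 plant x 11 fungus uptake values (231
combinations; ~6 minutes on one CPU with the numba engine) and
aggregates category percentages plus the semi-stable share.

## What the defaults emulate, and limits

The defaults above *are* the study conditions: 10-step lifetimes,
500-point landscape axes (201 inside sweeps), 2000-generation caps,
36-replicate / 500-generation stability testing, 231 uptake
combinations. The model deliberately excludes partner choice,
sanctions, storage, multiple partners, spatial structure and
within-lifetime plasticity, so passing tests say nothing about systems
where those mechanisms dominate; the point is what emerges *without*
them.

Known limitations:

- The stability pipeline's free constants (drift ratio 0.5, containment
  inflation 1.5, patience 10, linkage cut 0.1, coverage 95%, zone
  thresholds 99%/1%, founding grid 9 x 9) are reconstructions of an
  under-specified procedure. The qualitative map is robust to them;
  the exact split between semi-stable and stable, and the occasional
  borderline plateau at one high uptake efficiency (e.g.
  `beta = 0.9`, `alpha` 0.35–0.45) that registers as a novel
  parasitism-only semi-stable area in some seedings, are not.
- Selection near-neutrality at high uptake efficiencies makes outcomes
  there drift-dominated; population size and mutation SD shift the
  basin boundaries (the narrow interior attractor at
  `alpha = beta = 0.8` is found by the deterministic gradient but can
  be missed by a population whose trait variance exceeds the basin).
- Trait clipping at [-1, 1] is a modelling choice; an unbounded trait
  with clamped exchange behaves differently exactly at the extremes.
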