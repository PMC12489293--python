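# mycotrade

An individual-based eco-evolutionary model of resource trade between a
plant and a mycorrhizal fungus, for researchers studying the stability
of trade mutualisms: when is carbon-for-phosphorus exchange
evolutionarily stable, when does it slide into parasitism, and when
does cheating drive both partners extinct — with *no* stabilising
mechanism beyond repeated one-to-one interaction and fitness feedback
(no partner choice, no sanctions, no rewards)?

## The model

A plant (biomass `X`, C specialist) and a fungus (biomass `Y`, P
specialist) gather, trade and grow over a 10-step lifetime. Per step
the plant gathers C equal to `X` and P equal to `αX`; the fungus
gathers P equal to `Y` and C equal to `βY` (`α`, `β` ∈ [0, 1] are the
nonspecialised uptake efficiencies). The heritable trading strategy
`(γ, ε)` ∈ [−1, 1]² then moves a share of each gathered specialised
pool — given to the partner if positive, taken from it (clamped to
what the partner gathered) if negative — and each organism grows by its
scarcer pool (Liebig's law of the minimum):

    X[n+1] = X[n] + min(αX[n] + εY[n], X[n](1 − γ))
    Y[n+1] = Y[n] + min(Y[n](1 − ε),  βY[n] + γX[n])

with `X₀ = Y₀ = 1`; final biomass is fitness. On top of this lifecycle
the package provides:

- **coupled fitness landscapes** over the `(γ, ε)` plane, with
  interaction-type (mutualism / parasitism / competition / neutral),
  extinction-zone, viable-range and resources-received layers;
- an **individual-based evolution model**: paired populations, random
  one-to-one pairing each generation, fitness-proportional
  reproduction with a no-growth exclusion, Gaussian mutation;
- a **stability sweep** over 231 uptake-efficiency combinations that
  detects candidate stable strategy areas from exploratory runs,
  stress-tests each with 36 replicates over 500 generations, and
  classifies every landscape as mutualism-stable,
  mutualism–parasitism, or lacking any stable strategy.

See `docs/methods.md` for the full procedure and its assumptions.

## Worked example

Characterise the stability of the strategy that evolves when the plant
is a poor P forager (`α = 0.1`) and the fungus cannot source its own C
(`β = 0`, the arbuscular-mycorrhiza-like case):

```sh
$ mycotrade stability --alpha 0.1 --beta 0 --seed 7
{
  "alpha": 0.1,
  "beta": 0.0,
  "category": "mutualism_stable",
  "stability": "stable",
  "replicates_remaining": 36,
  "n_replicates": 36,
  "center_gamma": 0.4513893748946897,
  "center_epsilon": 0.4629857488937836
}
```

Evolution converges on the plant donating ~45% of its C and the fungus
~46% of its P; all 36 replicate simulations founded there stay inside
the area for 500 generations, and the area lies entirely in the
mutualism zone — strongly interdependent partners settle into stable,
mutually beneficial trade. The same command at `--alpha 0.9 --beta
0.9` instead reports `"category": "none"`: near-independent partners
evolve escalating mutual taking and extinction.

Other entry points: `mycotrade lifecycle` (one paired lifetime),
`landscape` (grid files + JSON sidecar), `evolve` (one trajectory),
`sweep` (the full grid), `plot` (PNG maps), `fixtures` (reference
parameter sets with hand-computed expectations). Every run writes a
JSON manifest (config, seeds, version) sufficient to reproduce it
bit-for-bit; a flat YAML config file can stand in for flags
(`mycotrade evolve --config run.yaml`, flags override file values).

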