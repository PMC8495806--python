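# Methods

## Model and assumptions

`trophicflux` computes steady-state energy fluxes through a trophic
network under the metabolism-centred food-web energetics view. The
assumptions are:

1. **Steady state.** Each consumer's assimilated intake exactly balances
   its metabolic demand plus what its own consumers remove from it.
   There is no growth, reproduction surplus, or biomass turnover term;
   the result is the *minimum* flux consistent with the standing
   community being alive. Fluxes are therefore comparative quantities
   (across treatments, sites, scenarios), not absolute field rates.
2. **Energy only flows along declared links.** Topology is an input;
   nothing is inferred from traits or phylogeny.
3. **Basal nodes are pure sources.** Energy flowing *into* plants or
   detritus (photosynthesis, litter input) is outside the balance; basal
   metabolic demand is set to 0 and basal consumption G is 0.
4. **Diet composition is fixed by the preference matrix.** Consumers do
   not rewire or switch in response to the solution.

The balance over consumers is linear: with consumers-in-columns
preference matrix `W`, per-node demand `X`, and resource-level
efficiencies `e`, each consumer `c` satisfies
`ebar_c G_c − Σ_k W[c,k] G_k = X_c` with `ebar_c = Σ_r e_r W[r,c]`.
With consumer-level efficiencies `ebar_c` is replaced by `e_c` literally
— note the two conventions differ for mixed diets, since resource-level
weighting lets a detritus-heavy diet assimilate worse than a prey-heavy
one. Resource-level is the default, matching common practice.

The matrix solver assembles this system over consumer nodes only, which
keeps it nonsingular even though basal nodes receive no intake. Feeding
loops (mutual predation, down-weighted cannibalism) are handled by the
same linear solve. The sequential solver walks the acyclic
consumer→resource order top-down applying `G = (X + L)/ebar` directly;
it exists both as the pedagogical "by hand" method and as an independent
oracle against the matrix route, and it refuses cyclic webs.

Negative consumption has no physical meaning here and is reported as an
error naming the offending nodes rather than clamped — it indicates an
energetically infeasible configuration (typically strong cannibalism or
an efficiency too low to cover the self-loop).

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `e_a` per resource type | fraction of ingested energy assimilated | detritus 0.158, plant 0.545, animal 0.906 at 20 °C | literature means widely used for arthropod communities; shipped as an editable CSV |
| metabolic regression (`ln_x0`, `a`, `E`) | `ln X = ln_x0 + a ln M − E/(kT)`, per-capita rate | bundled placeholders (`a ≈ 0.71–0.75`, `E = 0.69 eV`) | functional form is standard; exact coefficients are taxon-specific and must come from primary sources, so the bundled table is marked as placeholder data with provenance columns |
| `k` | Boltzmann constant | 8.62e-5 eV/K, fixed | part of the regression contract |
| `fmr_multiplier` | scales basal (resting) rates towards field rates | 1.0 | field rates are typically ~3× basal; exposed as a single multiplier applied when losses are computed from body masses |
| `temperature_C` | ambient temperature | 20 °C | enters the Arrhenius term; converted to Kelvin internally, all interfaces take Celsius |
| perturbation half-width `v` | sensitivity noise level | user-set | uniform multiplicative noise on [1−v, 1+v] |

Units are opaque coherent tags carried on the web (mass, area, energy,
time); nothing is converted automatically, and the unit of the loss
terms fixes the unit of every flux. Losses may be provided per unit
biomass (multiplied by biomass before solving) or per node — an explicit
flag, mirroring how community datasets are usually delivered.

## Preferences and efficiencies

Realized diet shares combine active choice weights `w` with passive
(encounter-rate) availability proportional to resource biomass:
`W[r,c] = w_rc B_r / Σ w B`. Unspecified weights default to the
equal-weight null. A consumer whose resources all have zero biomass
falls back to its explicit active weights (warned) or is an error.
Cannibalistic self-links require an explicit active weight at build
time, because passive weighting would otherwise assign a biomass-sized
share of a node's diet to itself.

Temperature dependence of assimilation efficiency is exposed as a
pluggable hook `(base_e, ΔT) → e` (clamped to ≤ 1) with identity
default. No specific functional form is bundled on purpose: published
temperature responses are taxon- and dataset-specific, and a wrong
built-in default would be worse than none.

## Aggregation

`aggregate_nodes` merges nodes group-wise: biomass and abundance sum,
body-mass lists concatenate, per-node losses sum (per-unit-biomass
losses combine as a biomass-weighted mean, which conserves total
demand), and merged links combine active weights as
resource-biomass-weighted means (one of several defensible rules; it is
recorded in the output metadata). Merges are classified:

- **parallel** — members share identical resource and consumer sets
  outside the group; silent. For such merges, guild-level process fluxes
  are exactly invariant when members share efficiencies, because passive
  preferences aggregate linearly in biomass.
- **serial** — some member eats another; the internal link disappears
  into the merged node, the internal flux is no longer resolved, and a
  `SerialAggregationWarning` is emitted. The warning is deliberate:
  serially aggregated webs change flux results.
- **heterogeneous** — neither; warned, since preference shares shift
  when a consumer ate only part of the merged group.

## Sensitivity analysis

`perturb_and_recompute` draws factors `1 + v·u`, `u ~ U(−1, 1)`,
elementwise on the chosen parameter (losses per node, efficiencies per
node with clamping to ≤ 1 and clamp counting, or preferences per link
with column re-normalization), re-solves, and reports per-link and
per-node mean relative deviations and coefficients of variation.
Uniform multiplicative noise is a modeling choice; so is link-wise
(rather than node-wise) preference perturbation. Drawing `u` once per
draw and scaling by `v` makes the stress sequence nested in `v` on a
fixed seed, hence monotone mean deviations. Infeasible draws are counted
and excluded from statistics. All randomness flows through one
`numpy.random.default_rng(seed)`.

## Synthetic communities

The generator emulates a plot-scale census of a temperate grassland
arthropod community: plant and detritus basal pools (lognormal biomass
around 50 and 100 g fresh mass/m²), detritivore, herbivore, omnivore
and predator guilds with lognormal individual body masses (median 2–20
mg fresh) and abundances (20–200 ind./m²), a lognormal sub-sample of
8–25 measured individuals per node, biomass coherent with abundance ×
mean mass, and guild-rule links (e.g. predators eat herbivores,
detritivores and omnivores) with per-pair connection probabilities.
Every consumer is guaranteed ≥ 1 resource by resampling, and the guild
hierarchy is acyclic, so generated webs always validate and solve.

What the generator does **not** emulate: empirical topology statistics
(connectance distributions, niche-model structure), within-guild trait
correlations, sampling error in biomass or abundance, detection biases,
mobile species operating across plot borders, or loops. Tests passing on
generated webs therefore demonstrate the correctness and internal
consistency of the machinery — balance closure, solver agreement,
conservation, aggregation behaviour — not that flux estimates for any
real community are accurate; that hinges on real regressions,
efficiencies and topology.

## Numerical choices

- Linear solve via LAPACK (`numpy.linalg.solve`); singular systems raise.
- Balance residuals `|assimilated − X − L| / max(X, 1e-12)` are computed
  for every solution and asserted ≤ 1e-9 in tests; solver-vs-oracle
  agreement is asserted at 1e-10 relative.
- Consumption values below −1e-10 (relative to scale) are infeasibility
  errors; tinier negatives are rounding and clamped to 0.
- Topological order breaks ties by input node order
  (deterministic output).
- CSV floats are written with `%.17g` and read with round-trip
  precision, so write→read is the identity on the data model.
- Efficiency bounds are enforced strictly: values must lie in (0, 1];
  a temperature hook returning ≤ 0 is an error, > 1 is clamped.

## Problem sizes used in the shipped checks

The acceptance script runs 200 generated webs (default counts: 17 nodes,
6 guilds) for solver/oracle agreement, 20 for conservation, 5
full-connectivity webs for aggregation invariance, 200 draws for the
size-structure properties, and 50 sensitivity draws — desk-scale
problems that finish in seconds while exercising every code path. The
full-connectivity configuration for the aggregation check is what makes
within-guild nodes exactly parallel (identical outside link sets), i.e.
it instantiates the definition of a parallel merge.

## Known limitations

- No biomass-turnover (death-rate/production) flux variant; the balance
  is metabolism-centred only.
- No elemental/stoichiometric fluxes, no diet inference from molecular
  data, no trait-database integration.
- Bundled regression coefficients are placeholders; absolute flux values
  are meaningless until real coefficients are supplied.
- The into-consumer process convention keys on exact guild names
  (herbivore/detritivore/predator) and ignores omnivores' mixed diets;
  the out-of-resource convention is the default and always partitions
  the total flux.
- Consumer-level efficiency applies one `e_c` to a mixed diet literally;
  results differ from resource-level assignment and the difference is
  the user's modelling choice.
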