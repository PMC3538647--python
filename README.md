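# purineflux

Quantitative physiology of purine-pathway engineering in *Corynebacterium
glutamicum*: ¹³C metabolic flux analysis of the central carbon metabolism,
cofactor (NADH + FADH₂) balancing, growth kinetics and purine-pool
metabolome statistics — with synthetic-data generators standing in for
every wet-lab measurement, so the whole pipeline runs and is tested
without external data.

## The problem

Engineering *C. glutamicum* for IMP accumulation (deleting *purA*,
*guaB2*, deregulating *purF*, rerouting carbon with a *pgi* deletion)
perturbs both the purine pools and the distribution of carbon flux
between glycolysis, the pentose phosphate pathway (PPP) and the TCA
cycle.  Quantifying those fluxes requires ¹³C metabolic flux analysis
(MFA): cells grow on [1-¹³C] or [1,2-¹³C₂] glucose, the mass isotopomer
distributions (MDVs) of proteinogenic amino-acid fragments and secreted
trehalose are measured by GC-MS, and the intracellular fluxes **v** are
estimated by fitting simulated to measured labeling patterns,

```
min_v  Σ_i ( x_i^sim(v) − x_i^meas )² / σ_i²     s.t.  S v = 0,  v_irr ≥ 0
```

where `S` is the stoichiometric matrix of the balanced intracellular
metabolites and `x^sim(v)` follows from the network's carbon atom
transitions.  Fluxes are reported as molar percentages of the specific
glucose uptake rate q_S (uptake ≡ 100 %).

## What the package provides

- **network_model** — the central-metabolism network (glycolysis, both
  PPP branches over a lumped pentose pool, TCA cycle, one net
  anaplerotic PEP+CO₂↔OAA interconversion, glycine/trehalose secretion)
  with per-carbon atom maps, gene knockouts (`apply_deletion`),
  growth-rate-dependent anabolic precursor drains, and an exact
  null-space parameterization of the flux space.
- **label_sim** — steady-state MDV simulation via elementary metabolite
  unit (EMU) decomposition; `reference` holds an exhaustive positional
  isotopomer simulator used as an independent cross-check.
- **ms_correction** — natural-isotope-abundance correction of raw GC-MS
  patterns (TBDMS/TMS derivatization formulas bundled), by non-negative
  least squares.
- **flux_fit** — multi-start weighted least-squares flux estimation and
  a 100-run Monte Carlo resampling for per-flux standard deviations.
- **cofactor_balance** — XADH (NADH + FADH₂) formation from GAP-DH,
  Pyr-DH, AKG-DH, MAL-DH and SUCC-DH fluxes plus an anabolic NADH term
  of 3.2 mmol g_CDW⁻¹ scaled by the biomass yield.
- **growth_kinetics** — μ (ln-linear regression over the balanced-growth
  window), Y_x/s (CDW formed vs glucose consumed) and q_S = μ / Y_x/s,
  with OD₆₆₀ → CDW conversion (0.414 g CDW per OD unit).
- **metabolome_analysis** — fold/percent changes of purine pools, pareto
  scaling (center, divide by √SD), PCA with scores/loadings/explained
  variance, and the two-group strain partition.
- **synthetic_data / scenarios** — generators for noisy MDV datasets,
  growth curves and 4-replicate metabolome tables under the four strain
  scenarios (wild type, Δ*pgi*, Δ*purA* Δ*guaB2*, quadruple mutant),
  each embedding the reported flux landmarks as ground truth.
- **cli / pipeline** — `purineflux simulate|correct|fit|montecarlo|xadh|
  growth|metabolome|make-fixtures|pipeline` subcommands over the library.

## Worked example

Simulate a wild-type [1-¹³C] tracer experiment at typical GC-MS noise
(0.004 per mass fraction), refit the fluxes from 10 random starts and
attach Monte Carlo uncertainties:

```python
from purineflux import label_sim, scenarios, synthetic_data as sd, flux_fit, cofactor_balance

setup = scenarios.build_scenario("wild_type")
fragments = label_sim.load_fragments()
system = label_sim.decompose_emus(setup.network, fragments)
meas, truth = sd.generate_mdv_dataset(
    setup.network, system, setup.true_fluxes, setup.tracer,
    setup.scenario.mu, setup.scenario.q_s, seed=1)
est = flux_fit.fit_fluxes(setup.network, system, meas, setup.demand, n_starts=10, seed=1)
mc = flux_fit.monte_carlo(setup.network, system, meas, setup.demand, base=est, n_runs=100, seed=2)
for rxn, label in [("zwf", "oxidative PPP"), ("cs", "TCA cycle"), ("ppc", "anaplerosis")]:
    print(f"{label:14s} {mc.flux.net[rxn]:6.1f} +/- {mc.sd[rxn]:.1f} %  (truth {truth['fluxes'].net[rxn]:.1f})")
rep = cofactor_balance.compute_xadh(mc.flux, setup.scenario.mu, setup.scenario.mu/setup.scenario.q_s)
print(f"XADH surplus   {rep.total:6.1f} %")
```

prints

```
oxidative PPP    57.8 +/- 1.5 %  (truth 55.2)
TCA cycle        46.5 +/- 0.5 %  (truth 47.3)
anaplerosis      27.1 +/- 0.0 %  (truth 27.1)
XADH surplus    351.8 %
```

i.e. at this noise level the PPP split is recovered to ~2 % of uptake
and the TCA flux to well under 1 %; the anaplerotic net flux carries no
Monte Carlo spread because, in this network topology, it is fixed by the
anabolic C4/C5 demands.  The one-seeded-start warning that a random
start landed on a zero-flux (singular) labeling system is expected —
that start is discarded and refitting proceeds from the rest.

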