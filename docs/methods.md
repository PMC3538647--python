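# Methods

## Network model

The bundled network (`data/network_cg_central.txt`) represents glucose-grown
*C. glutamicum* central metabolism at the granularity of the classical flux
map: glycolysis, the oxidative PPP (G6P → P5P + CO₂), the non-oxidative PPP
as two transketolase and one transaldolase reactions over a *lumped* pentose
pool (no distinction between ribose/ribulose/xylulose 5-phosphate), pyruvate
dehydrogenase, the full TCA cycle with succinate/fumarate symmetry handled
by equal-weight atom-map scrambling variants, one net anaplerotic
PEP + CO₂ ↔ OAA interconversion with an exchange parameter, glycine and
trehalose secretion, and CO₂ balanced explicitly with an outflow.  The
glyoxylate shunt and malic enzyme are omitted (glucose-grown convention;
neither appears in the flux map being modeled).  Atom maps use letter
notation (`G6P(abcdef) -> P5P(bcdef) + CO2(a)`); the parser enforces that
every substrate carbon maps to exactly one product carbon.

Anabolic precursor drains are modeled as fixed fluxes
`drain_i = demand_i · μ / q_S · 100` (% of uptake) from bundled demand
coefficients (mmol per g CDW, representative coryneform biomass
composition, editable).  Adenine/guanine supplementation spares only the
3-phosphoglycerate demand (glycine plus two formyl units per de novo
purine ring, 0.26/0.24 mmol g⁻¹); the P5P/PRPP demand is *not* spared
because salvage synthesis still consumes PRPP.  An accumulating IMP pool
adds its ribose moiety to the P5P demand (`imp_pool_correction`, mmol g⁻¹).

With uptake fixed at 100 and the ten drains fixed, the balance system has
exactly three net degrees of freedom.  A consequence of this topology is
that the net anaplerotic flux equals the anabolic OAA + AKG demand — it is
not independently adjustable.  The free coordinates are therefore chosen
deterministically as {oxidative PPP entry (zwf), trehalose secretion,
glycine secretion} (or the feasible subset after knockouts), and every flux
vector is produced through an exact null-space parameterization, so node
balances hold to machine precision by construction.

Exchange (bidirectional) fluxes exist for pgi, the three non-oxidative PPP
reactions, malate dehydrogenase and anaplerosis; they are stored as bounded
parameters x ∈ [0, 1) with exchange flux 100·x/(1−x) (% of uptake) and
floored at 10⁻⁶ to keep labeling systems nonsingular.  Upper glycolysis
(aldolase, triose phosphate isomerase, GAPDH, enolase) is treated as
effectively irreversible: its exchange is barely identifiable from the
measured fragment set and including it would only inflate the parameter
count.

## Labeling simulation

The forward model decomposes the network into elementary metabolite units
(EMUs) reachable backward from the measured fragments and solves one linear
system per EMU size, in increasing size order; condensation reactions enter
as convolutions of smaller EMUs.  Measured fragments are defined as
convolutions of precursor EMUs using the standard bacterial biosynthesis
assignments (Ala ← Pyr; Gly ← 3PG C1–C2 via Ser; Ser ← 3PG; Val ← Pyr{1-3}
⊗ Pyr{2,3}; Thr ← OAA; Phe ← PEP{1-3} ⊗ PEP{2,3} ⊗ E4P; trehalose ←
G6P ⊗ G6P).  Tracer inputs model 99 % positional enrichment and carry
natural ¹³C (1.07 %) on unlabeled positions.

`reference.py` contains an independent cross-check: an exhaustive
positional-isotopomer simulator (2ⁿ states per metabolite) solved by
fixed-point iteration.  One numerical subtlety: the unit-mass manifold of
that iteration is unstable — bimolecular balances add the mass
perturbations of both substrates, so rounding errors grow and the
iteration can drift to a spurious mass-deficient fixed point.  Each pool is
therefore renormalized to the simplex every sweep, which is exact at the
true solution.  EMU and enumeration agree to ~10⁻¹³ on the full network;
the enumeration is exponential in carbon count and is used only on small
problems and in tests.

## GC-MS natural-abundance correction

For each fragment, the isotope patterns of all atoms outside the tracer
carbon skeleton (H, N, O, Si, S and non-skeleton C of the TBDMS/TMS
derivatives; IUPAC abundances bundled as data) are convolved into a single
mass-shift pattern, placed in every column of a (n+1+k) × (n+1) shift
matrix (k = 4 retained overflow shifts).  Correction solves the matrix
equation by non-negative least squares and renormalizes — NNLS rather than
matrix inversion so noisy spectra cannot produce negative fractions.
Natural ¹³C *within* the tracer carbons is deliberately not removed: the
forward simulation already accounts for it through tracer purity and
natural abundance, and removing it in both places would correct it twice.
Deconvolution amplifies measurement noise by the row norms of the matrix
pseudoinverse (≈1.5× for amino-acid [M−57] ions, ≈4× for per-TMS
trehalose); the pipeline propagates that amplification into the per-fraction
SDs used as fit weights.

## Flux fitting and Monte Carlo

The estimator minimizes Σ((sim − meas)/σ)² over the free net fluxes and
exchange parameters, using bounded trust-region least squares
(`scipy.optimize.least_squares`, trf).  Measured secretion rates enter as
additional weighted residuals; irreversibility is enforced by a steep
linear penalty on negative dependent fluxes (the free coordinates
themselves are box-bounded).  Start values are drawn uniformly over the
parameter box from the run seed ("statistically varied" initial values);
starts that land on zero-flux singular labeling systems are redrawn, and a
start failing mid-optimization is recorded and skipped.  Iteration over
starts stops early once a start reaches SSR < 10⁻⁸, which cannot be
improved meaningfully.  The fit is declared a global minimum when the two
best starts agree within 0.1 %.  Default per-fraction MDV SD is 0.004
(typical GC-MS precision); zero SDs are allowed and mean "exact/unperturbed"
(a floor of 10⁻⁶ is applied to the weights only).

Uncertainties come from a measurement-resampling Monte Carlo (default 100
runs): every measured quantity is perturbed by Gaussian noise at its SD,
refit from the base solution, and per-flux means and SDs are taken over
runs; more than 20 % failed runs aborts with an error.

## Strain scenarios and synthetic data

The four scenarios (wild type; Δpgi; ΔpurA ΔguaB2; the quadruple mutant
ΔpurA ΔguaB2 purF^K348Q Δpgi) carry their reported growth parameters
(μ, q_S), knockouts, supplementation state, IMP-pool correction and tracer
choice — [1-¹³C] glucose normally, [1,2-¹³C₂] for pgi-deleted strains,
whose [1-¹³C] labeling would be nearly uninformative (C1 is quantitatively
lost as CO₂ in the oxidative PPP).  Each scenario's ground-truth flux
vector embeds the reported flux landmarks exactly (TCA 47.3 / 45.7 / 88 %;
oxidative PPP 29.3 / 98.0 %) by solving the affine map from free
coordinates to fluxes, with remaining freedom at realistic secretion priors
(glycine ~0.3–2 %, trehalose ~0.2–4.5 % of uptake) and exchange parameters
{pgi 0.3, TKT/TAL 0.3, MDH 0.5, anaplerosis 0.4}.

Generators are bit-reproducible per seed.  MDV noise is additive Gaussian
(truncated at 0, renormalized to the simplex); rates carry 2 % relative
noise with a floor of 0.05 % of uptake on the attached SD; metabolome
replicates use mean-preserving lognormal noise at 12 % CV (the stated
quantification precision), four replicates per strain.  What the generators
do **not** emulate: chromatographic/spectral artifacts, inter-batch drift,
biological replicate correlation, or deviations of the real network from
the bundled topology — so passing recovery tests demonstrates correctness
and identifiability of the estimator under the stated error model, not
robustness to model misspecification.

## Growth kinetics

μ is the least-squares slope of ln(CDW) vs time over the balanced-growth
window, selected as the longest span with ln-linear R² ≥ 0.995 (≥3 points).
Y_x/s is the negative slope of CDW vs glucose (same estimand as a
through-origin regression of the differences, but without anchoring on the
noisy first sample); q_S = μ / Y_x/s.  Y_x/s is interpreted as g CDW per
mmol glucose throughout — the only unit reading under which μ / Y_x/s
reproduces the reference q_S column.  Accurate yield recovery needs curves
sampled until glucose is substantially consumed; the synthetic designs use
~25-fold biomass growth.

## Metabolome statistics

The strain × metabolite matrix uses, for the two single-deletion strains
with transient pools, the second-phase concentrations; below-detection
cells become 0 and metabolites not determined in every strain are dropped
column-wise (no imputation).  Pareto scaling divides centered columns by
√SD with the sample (n−1) SD.  PCA is an SVD of the scaled matrix; loading
signs are fixed so each component's largest-magnitude loading is positive.
On the bundled reference matrix PC1+PC2 explain 93.0 % of the variance,
driven by hypoxanthine (PC1) and the IMP/AMP/GMP axis (PC2).

The two-group strain partition is defined as proximity to the reference
(wild-type) strain in the PC1/PC2 score plane: distances to the reference
are split at their largest gap.  A single-axis PC1 threshold cannot
reproduce the observed grouping because the unperturbed strains separate
from the single-deletion mutants along PC2 but from the double/quadruple
mutants along PC1.  A replicate-level mode (4 synthetic replicates per
strain, 95 % confidence-ellipse parameters per strain) is provided for
score-plot-style analyses.

## Numerical choices and limitations

- Balance residuals are zero by construction (null-space parameterization);
  validation uses 10⁻⁸ tolerances.
- EMU blocks raise a descriptive error on singular systems (zero-flux
  pools or zero-net reversible cycles) instead of returning garbage.
- Fold/percent changes support the reporting roundings (integer, nearest
  5, nearest 10, one decimal); a zero reference concentration is an error
  (report absolute values instead).
- Problem sizes in tests and the acceptance script (10 fit starts, 100
  Monte Carlo runs, 200-seed steady-state sweeps) match the analysis
  defaults; the whole suite runs in under two minutes.
- Exchange fluxes are only weakly identified by the fragment set and are
  not asserted in recovery tests; net fluxes are.
- The XADH report's absolute percentages depend on the full flux map
  (including drains), so cross-strain comparisons are meaningful within
  one network/demand configuration only; the reproduced property is the
  strain ordering (double > quadruple > wild type > Δpgi), not the
  absolute totals.
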