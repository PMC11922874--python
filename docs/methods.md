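# Methods

## Model

`succdyn` simulates an anaerobic batch culture of *Actinobacillus
succinogenes* growing on glucose. The model is *process-based*: instead
of a genome-scale flux network it tracks seven lumped processes — three
glycolytic steps (glucose → G3P → PEP → pyruvate), succinate production
from PEP (the C4 branch, via PEP carboxylation), two acetate/formate
productions from pyruvate (the C3 branch), and growth from pyruvate —
and a two-pool adenylate balance that regulates all of them.

### States and units

| symbol | meaning | unit |
|---|---|---|
| G, SA, AA, FA | extracellular glucose and acids | mol L⁻¹ |
| G3P, PEP, P | intracellular glycolytic intermediates | mol molX⁻¹ |
| X | biomass (monomer CH₂O₀.₅N₀.₁₈, MW 24.55) | molX L⁻¹ |
| ATP, ADP | adenylate pools | dimensionless |

Observables are reported in g/L as state × molecular weight. The
adenylate pools are scaled so that their sum per gram of biomass is
`s_ATP` = 1 g⁻¹; the *energy charge index* ATP/(X·MW_X) ∈ [0, 1] drives
the regulation. At t₀ the pools are split evenly:
ATP₀ = ADP₀ = s_ATP·X₀·MW_X/2.

### Regulation

Each process rate is Michaelis–Menten in its substrate, first order in X,
and multiplied by logistic gates:

* **RC_ATP** = σ(k₃·(ATP/(X·MW_X) − ATP_mid)) gates ATP-consuming steps
  (the first glycolytic step and growth); **RC_ADP** = 1 − RC_ATP gates
  the ATP-producing fermentative steps. This complementary pair is the
  homeostat: a high energy charge lets uptake and growth run while
  throttling regeneration, and vice versa.
* **RC_v1** = 1 − a₁·σ(k₁·(G − G_mid1/MW_G)) up-regulates uptake when
  glucose is scarce and cuts it to 1 − a₁ = 0.12 above ≈51 g/L — the
  high-glucose uptake shutoff.
* **RC_v2** = a₂ + (1 − a₂)·σ(k₂·(R_mid − ln(G/X))) throttles uptake
  while glucose is in large excess over the population (floor a₂ = 0.18),
  opening as biomass catches up with its substrate. At G = 0 the
  analytic limit 1 is used (no ln(0) is evaluated).
* **RC_G** = σ(k₄·(G − G_mid2/MW_G)) shuts growth down when glucose
  falls below ≈2 g/L.
* **RC_SA/AA/FA** = σ(k·(acid − mid/MW)) scale the ATP cost of exporting
  each acid against its concentration gradient; with coefficients
  n_SA, n_AA, n_FA they are the route by which product accumulation
  drains the energy budget.

The intracellular pools carry saturation brakes 1 − (pool·MW_pool)/(cap·MW_X)
(caps `G3P_max`, `PEP_max`, `P_max` in g gX⁻¹), clamped at 0 from below:
the caps are brakes on the forward rate, never reverse fluxes.

### Mass balances

Extracellular balances are extensive (mol L⁻¹ h⁻¹); intracellular flux
balances are divided by X because those pools are carried per molX.
dX/dt = η_X·ν_X·GROWTH − SECRETION, with SECRETION ≡ 0 by default (cell
death is not modelled; the term is an extension hook). The adenylate
balances collect the ATP invested in uptake (ν_ATP1 = 2 per glucose),
recovered in lower glycolysis and fermentation (ν_ATP2..5), spent on
growth (η_X·n_X·ν_X per growth flux) and on gated acid export, with every
ATP term mirrored with opposite sign in the ADP balance. A growth
correction term `dilution_factor·(pool/X)·dX/dt` is added to both pools;
summing the balances, all stoichiometric terms cancel and

    d(ATP+ADP)/dt = dilution_factor · (ATP+ADP)/X · dX/dt,

so the total pool grows as X^dilution_factor. The default
`dilution_factor = 1` is the unique choice under which the total
adenylate per gram of biomass stays at its assumed constant s_ATP — with
factor 3 (available through `ModelOptions`) the per-gram pool grows as
X² and the ADP-gated fermentative chain deadlocks as soon as the
population roughly doubles. The X³ conservation law of the factor-3
variant is still verified by the test suite as an algebraic property.

### Unit conventions for the half-saturation constants

The calibrated constants are stored exactly as tabulated but the table
mixes mass- and mole-based conventions (its unit labels are not fully
self-consistent; e.g. PEP half-saturations labelled in pyruvate moles).
`model.effective_molar_constants` fixes the reading used everywhere:

* `k_Gly1` is grams of glucose per litre (like the logistic midpoints
  `G_mid1`, `G_mid2`, `SA_mid`, `AA_mid`, `FA_mid`, all in grams):
  read as mol via k/MW_G. The molar reading would put half-saturation at
  7205 g/L glucose and cap specific uptake ~10× below what any batch
  requires.
* `k_P1`, `k_P2`, `k_P3`, `k_G` are grams of substrate per gram of
  biomass: read as mol/molX via k·MW_X/MW_substrate. The molar reading
  of `k_G` caps the specific growth rate at ≈0.08 h⁻¹, too slow for the
  observed 30–40 h growth phase.
* `k_Gly2`, `k_Gly3` are used as printed (mol molX⁻¹). Keeping `k_Gly3`
  molar preserves the PEP partition between the succinate branch and
  lower glycolysis that yields the observed ≈3:1 SA:AA product ratio.

These assignments were fixed once, from dimensional analysis plus the
batch phenomenology the calibrated values encode (full consumption at
≤22 g/L initial glucose on the observed schedule, succinate titres near
30 g/L at ≈43 g/L loading, arrest at higher loadings), and are not
tuning knobs.

## Simulation

`scipy.integrate.solve_ivp` with the BDF stiff integrator,
rtol = 1e-8, atol = 1e-10, dense output, reporting grid 0.1 h
(all configurable via `SolverOptions`). Halving the tolerances moves
terminal observables by far less than 0.1%. States that undershoot zero
beyond ~100·atol abort the run; sub-tolerance undershoots are clipped to
zero in reported observables only. The packaged experiments G1–G5 use
initial glucose 0.03/0.12/0.24/0.37/0.45 mol L⁻¹ (5.40–80.70 g/L),
inocula 5.6×10⁻⁴–1.9×10⁻³ molX L⁻¹ and horizons of 60 h (G1) or 100 h.

The initial-glucose sweep repeats the batch simulation over a grid of
initial glucose values at a fixed inoculum (default 10⁻³ molX L⁻¹,
within the experimental range) and records each run's peak biomass and
final succinate. Its default horizon is the 100 h of the batch
experiments it extends; the deep-crisis state is not absorbing (uptake
trickles at RC_ATP ≈ 0.01), so "run to steady state" is not well defined
and longer horizons shift the apparent optima upward.

## Calibration

The objective is SSE = Σ_exp Σ_var Σ_t (C_data − C_sim)²/C_data,max with
C_data,max the per-variable, per-experiment maximum of the measured
values (first power — the normalisation is a scale weight, not a
variance), simulated values interpolated from dense output at the
observation times, and missing cells contributing nothing. Failures of
the integrator at proposed parameter sets return +∞ rather than raising,
so the simplex can route around infeasible regions. Nelder–Mead runs in
log-parameter space, which enforces positivity without constraints; the
returned point is never worse than the start. Which parameters are free
is caller-chosen: small subsets are reliably identifiable, the full
38-parameter joint fit is expressible but not a test surface.

## Sensitivity

One-at-a-time ±5% perturbations; for each parameter the standardised
elemental effect averages the squared deviation of the perturbed biomass
and succinate trajectories from the baseline over a 101-point regular
time grid, normalised by the baseline's max–min range per output, and
scaled by 1/n with n the number of parameters analysed. The inner sum is
reported as a per-grid-point mean so the measure is independent of grid
density (a constant rescaling on any fixed grid; rankings unchanged).
The baseline trajectory supplies both reference values and
normalisation. Ranking is by total variation (+5% and −5% effects
summed) within each experiment. Under the default parameterisation the
energy-gate parameters (`ATP_mid`, `k₃`) rank at or near the top in all
experiments, with the uptake-shutoff depth `a₁` dominating the
high-glucose ones — the model's behaviour pivots on when the energy
crisis begins.

## Synthetic data

The generator simulates the calibrated model at the experiment
conditions, samples the five g/L observables on an assay-like grid
(every 2 h to 24 h, every 4 h thereafter) and applies multiplicative
Gaussian noise value·(1 + cv·z), cv = 5% by default — typical of
HPLC/OD measurements and appropriate because the observables span orders
of magnitude within a run, which additive noise would swamp at early
biomass values. Draws that land negative are reported at a detection
floor (0.01 g/L), a small documented bias confined to near-zero
measurements. A fixed seed makes datasets bit-reproducible. What the
generator does *not* emulate: instrument-specific autocorrelated error,
sampling-volume effects, pH/CO₂ chemistry, or any structural mismatch
between model and organism — parameter-recovery tests on these data
therefore validate the inference machinery, not the model's adequacy for
real cultures.

## Known limitations

* The location of the *biomass* optimum along the initial-glucose axis is
  not an interior maximum in this implementation: peak biomass rises
  slowly and monotonically up to the uptake-shutoff boundary (~60 g/L)
  before collapsing, rather than peaking at 20–30 g/L. The succinate
  optimum (50–60 g/L) is robust.
* The simulated G1 batch leaves ≈0.7 g/L of its 5.4 g/L glucose at 60 h
  (slow tail of uptake), and the G2 biomass continues to creep for
  ~8% after its growth phase while residual glucose is consumed.
* The NADH/NAD⁺ redox balance, lactate/ethanol by-products, pH and
  CO₂/MgCO₃ chemistry, and osmotic-stress mechanisms are outside the
  model's scope; fed-batch and continuous operation are not implemented.
* Inhibitor accumulation in the medium is not modelled; the biomass
  secretion/death term exists only as a zero-default hook.
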