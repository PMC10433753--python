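# Methods

## The model

`gsiskit` implements a kinetic model of glucose-stimulated insulin secretion
(GSIS) in the pancreatic β-cell: glycolysis from glucose uptake to pyruvate,
with lactate export and mitochondrial pyruvate transport as exit branches, an
ATP-consumption load closing the energy balance, and a phenomenological
insulin-release flux coupled to the cellular energy state.

The census is fixed: 3 compartments (external/blood, cytosol,
mitochondrion), 25 species, 21 reactions, and a 91-entry parameter ledger
that decomposes as 49 Km + 16 Keq + 16 Vmax over the sixteen
modular-rate-law reactions (GLUT, HEX1, PGI, PFK1, PFK2, FBP26, FBA, TPI,
GAPDH, PGK, PGM, ENO, PK, LDH, LACT, PYRT), 2 constants each for the
saturable ATP load (ATPCONS) and the redox-closure reaction (NADHOX), the
adenine-pool adjustment rate, and 5 insulin-release constants. All
non-pseudo reactions are element- and charge-balanced (water and protons are
carried explicitly for bookkeeping; `check_balances` verifies this from
species formulas and charges).

### Rate laws

Every enzymatic reaction and transporter uses the modular rate law

ν = Vmax · Π aᵢ · (1 − Γ/Keq) / ( Π(1+aᵢ) + Π(1+bⱼ) − 1 ),

with aᵢ = Sᵢ/Km_s,i, bⱼ = Pⱼ/Km_p,j and the mass-action ratio
Γ = ΠPⱼ/ΠSᵢ in raw concentrations. Numerically the thermodynamic factor is
expanded to Π aᵢ − Π Pⱼ/(Π Km_s · Keq), which is finite when a substrate
concentration is zero (where Γ itself is undefined). For the two
irreversible transport steps (lactate export, mitochondrial pyruvate
uptake) the reverse term is dropped but product saturation is kept in the
denominator. For one substrate and one product the law reduces exactly to
reversible Michaelis–Menten kinetics (property-tested).

Insulin release is the sum of two phases,

ν_IRS = kd_fp·m/(m+Km_fp) + Vmax_sp·rⁿ/(rⁿ+Km_spⁿ), m = max(dATP/dt, 0),
r = ATP/ADP,

a dynamic first phase driven by the rate of ATP accumulation and a
sustained second phase given by a Hill function of the ATP/ADP ratio.
dATP/dt is computed symbolically inside the right-hand side as the net
signed ATP production rate over all reactions (including the pool
adjustment), not by differentiating the ATP trajectory — this keeps the ODE
system well defined and exactly self-consistent.

Total adenine nucleotides change with glucose; a pseudo-reaction relaxes
ATP+ADP toward the glucose-dependent target curve ATPtot(glc) at first-order
rate f (default 0.15/min):  ν = f·(ATPtot(glc) − ATP − ADP).

### Rules and boundaries

Phosphate, NAD and NADH are governed by degree-3 polynomial assignment
rules in external glucose (fit by least squares to mean steady-state
curves), clamped to the 1–35 mM dose domain. External glucose and lactate,
mitochondrial pyruvate, water and protons are boundary species. Secreted
insulin accumulates in the external compartment and is reported through the
release flux (nmol/min/ml β-cell volume); concentrations are mM and time is
minutes throughout. Both rule governance and the pool adjustment can be
switched off, which restores exact conservation of ATP+ADP and NAD+NADH
(moiety tests); NADHOX exists to close the redox loop in that mode.

### Default parameterization

Km and Keq values are median-style assignments from standard literature
ranges (GLUT2 transport ~17 mM, glucokinase ~4–8 mM, downstream enzymes
0.01–10 mM; equilibrium constants from standard transformed values, with
the aldolase constant carrying concentration units). The Vmax defaults are
the package's own calibration, chosen so the default model expresses the
canonical GSIS phenomenology and is a well-posed reference for synthetic
data generation:

- the energy design keeps maximal upper-glycolysis input below the maximal
  ATP-consumption capacity at every dose, so the adenine pool always finds
  a stable interior balance (no collapse at low glucose, no runaway at
  high glucose);
- all steady states are monotone non-decreasing in glucose over 1–35 mM,
  and the ATP/ADP ratio rises ~11-fold between 2.8 and 30 mM;
- after a basal→stimulating glucose step the glycolytic intermediates
  settle (5% criterion) in ≈22 min, set mainly by the adenine-pool
  adjustment rate and the FBP pool turnover;
- each Vmax sits within a small multiple (~2–5×) of the flux its reaction
  carries, so every Vmax is practically identifiable from concentration
  time courses — a deliberately well-conditioned inverse problem. An
  earlier parameterization with several near-equilibrium "fast" enzymes
  (10–25× flux) produced broad compensatory valleys in the calibration
  objective and was replaced for this reason.

Initial concentrations are the model's own basal (3 mM glucose) steady
state; initial external glucose is 3 mM.

## Simulation

Protocols mirror islet experiments: a pre-incubation phase (default 60 min)
at one glucose dose, then incubation at another, with the full state handed
over and rule-governed species re-evaluating instantly at the switch.
Integration is LSODA via `scipy.integrate.odeint` on a numba-compiled
right-hand side with a compiled finite-difference Jacobian callback;
reporting runs use rtol 1e-8 / atol 1e-10 with 0.1-min dense output.
Steady states are found by chunked long integration (sup-norm of dx/dt
below 1e-8 mM/min, horizon 10⁴ min) with an optional Newton polish that is
kept only when it does not worsen the residual. The settling time of a
trajectory is the earliest time after which every glycolytic intermediate
stays within a relative tolerance (default 5%) of its final value; a
deviation persisting into the final grid step flags the trajectory as
unsettled.

## Normalization

Heterogeneous measurements are merged per metabolite in a fixed order:
unit normalization (registered factors; islet contents convert via the
2 nl/islet water volume), fold→absolute conversion (basal from the mean
absolute curve at the experiment's pre-incubation dose, falling back to the
metabolite's Km), iterative steady-state normalization, then time-course
anchoring. The per-curve scale factor minimizing the squared offset to the
weighted mean curve has the closed form f = Σ C·C̄ / Σ C²; passes of
(recompute mean → rescale all curves) repeat until the factors agree with
their common (geometric-mean) scale to within 1e-6 (cap 100 iterations,
non-convergence flagged).  The common scale is a gauge freedom of the
objective: under per-point noise the raw factors keep a tiny shared
multiplicative component that never vanishes, so convergence is judged on
their dispersion around it.  Because the objective is squared distance to
the mean rather than the coefficient of variation itself, small noisy
panels can show a marginal CV increase for individual metabolites even
though study-level biases are removed. Mean curves use
equal curve weights on the union dose grid, shape-preserving piecewise
cubic (PCHIP) interpolation for ≥3 points and linear interpolation for 2,
with clamping outside the observed range. Time courses are scaled so their
final point matches the mean steady-state curve at the incubation dose.
Negative measurements are rejected at load.

## Synthetic data

The generator emulates the statistical structure of the curated islet
literature: per-study multiplicative reporting bias (log-normal, median 1,
σ_log 0.5), multiplicative log-normal measurement noise (CV 0.10),
absolute- versus fold-reporting, common doses {1, 2.8, 5, 10, 16.7, 20,
30} mM and 0–60 min time grids at 5-min steps. Ground truth (noise-free
curves from the reference model, bias factors, true Vmax) is retained for
recovery tests. It does **not** emulate missing data, censoring,
study-specific dose spacing, reporting heterogeneity beyond one bias per
study, or inter-individual biological variability — so passing recovery
tests demonstrate correctness of the pipeline's math under its own
assumptions, not robustness to every pathology of real curated data.

The canonical calibration dataset is noise-free: time courses of cytosolic
glucose, the 12 glycolytic intermediates, ATP and ADP at two protocols
(3→16.7 and 3→30 mM), 13 samples each over 60 min. Rule-governed cofactors, derived
ratios/sums and insulin data are excluded from the glycolytic residual;
insulin-release parameters are fitted in a separate decoupled stage against
insulin dose-response data with glycolysis frozen.

## Calibration

The objective is the unweighted sum of squared residuals between
observations and condition-specific predictions (60-min pre-simulation at
the pre-incubation dose, then incubation, sampled at observed times);
steady-state observations enter as late-time (120 min) observations of a
constant-dose protocol. Integrator failures score +∞.

The hybrid optimizer searches in log10 space (bounds [1e-2, 5000] span
nearly six decades):

1. **Global:** restarted (μ,λ) evolution strategy, population 20, μ=5,
   self-adaptive per-coordinate step sizes (log-normal update, initial
   σ=0.5 decades), intermediate recombination of two parents, one elite
   survivor. The initial population samples half its members uniformly on
   the natural scale and half log-uniformly, covering both the
   fast-kinetics and slow-kinetics corners of the box. Default desk-scale
   profile: 10 restarts × 2000 evaluations, fully seeded.
2. **Local:** a cascade of Hooke–Jeeves pattern searches.  Because the
   objective's curvature spans several orders of magnitude across
   parameters, per-coordinate poll steps are seeded from a one-pass
   sensitivity probe and then halved jointly.  Short probes (3000
   evaluations) start from the three best global candidates; the two that
   descend furthest are refined to convergence (9000 evaluations each,
   with the textbook step-reset restart after each inner convergence).
   Candidates are ranked by probe descent rather than by raw global cost:
   the objective has compensatory local basins (e.g. re-routing the
   pyruvate exit between lactate export and mitochondrial transport)
   whose bottoms the global stage cannot tell apart, and the deepest
   global point frequently polishes into such a basin while a slightly
   worse one funnels to the optimum.  Early stop once the cost falls
   below 1e-4, far inside the recovery tolerance on noise-free data.
   Steady-state reachability at basal glucose is verified on the final
   parameters.

During fitting the integrator runs at rtol 1e-5 / atol 1e-8; the resulting
cost floor at the true parameters (~1e-8) is many orders below the cost of
a 20% single-parameter perturbation (≥3e-3), so fit accuracy is limited by
the optimizer, not the integrator.

## Sensitivity analysis

Scaled local sensitivities of the steady-state insulin-release flux,
S = [(IRS(p·1.1) − IRS(p))/IRS(p)]/0.1, use one-sided forward differences
at a 10% perturbation (a central-difference oracle backs the tests; for
ultra-sensitive parameters such as hexokinase Vmax the two differ by
curvature, which is expected). Parameters producing less than a 1% insulin
response change for a 10% perturbation at every dose are flagged filtered
but kept in the result. An option evaluates cumulative secreted insulin
over a protocol instead of the steady-state flux. Display labels follow
the conventional report names (ATPconsumption_Vm, HEX1_Vm, IRS_Katp_ratio,
IRS_hillKatp_ratio).

## SBML

Models export to SBML Level 3 Version 1 core (compartments, species with
boundary flags, the 91 ledger entries as global parameters, assignment
rules and kinetic laws as MathML, identifier cross-references as
RDF/bqbiol:is controlled-vocabulary terms). A compact machine-readable
kinetics annotation in the package's own namespace makes the round trip
lossless; the importer validates structurally (unique ids, resolvable
references, required attributes) before rebuilding the model. Round-tripped
models reproduce trajectories bit-for-bit given identical solver settings.

## Numerical choices and degenerate inputs

- Concentrations are clamped at zero inside rate-law evaluation; boundary
  species are bit-identical across a phase.
- The modular-law thermodynamic term is evaluated in product form to avoid
  0/0 at zero substrate.
- Assignment-rule polynomials and the ATPtot curve clamp outside the
  1–35 mM dose domain; positivity over the domain is asserted at build.
- Zero ADP makes the ATP/ADP ratio (and the insulin flux) undefined and
  raises; an all-zero measurement curve cannot be scale-normalized and
  raises.
- Median aggregation of duplicate ledger rows; an empty slot fails the
  build naming the slot.

## Known limitations

- Mitochondrial metabolism (TCA cycle, oxidative phosphorylation), calcium
  electrophysiology, granule dynamics and incretin effects are outside the
  model; the ATP load and the pool-adjustment flux are their aggregate
  surrogates.
- The cofactor assignment rules make phosphate/NAD/NADH instantaneous
  functions of glucose; transient cofactor dynamics are not represented.
- The basal ATP/ADP ratio of the default parameterization (~0.2 at 2.8 mM)
  sits below typical measured islet values; the dose-dependent *fold*
  changes, which drive the insulin response, are in the observed range.
- Local sensitivities are one-sided and first-order; strongly curved
  responses (hexokinase) are reported as finite-difference values, not
  derivatives.
- The 2-parameter and 16-parameter recovery results hold for the noise-free
  synthetic conditions stated above; identifiability under realistic noise
  and sparse sampling is weaker.
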