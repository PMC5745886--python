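# Methods

`gutbiofilm` simulates a three-species bacterial biofilm attached to the
intestinal mucosa — *Bacteroides thetaiotaomicron* (Bt),
*Faecalibacterium prausnitzii* (Fp) and *Escherichia coli* (Ec) —
with intracellular metabolism described by flux balance analysis (FBA)
and the extracellular environment by one-dimensional reaction-diffusion
transport. The purpose of the model is to ask whether low (sub-micromolar
to micromolar) oxygen levels at the gut wall are sufficient to push a
healthy community composition into the dysbiotic pattern seen in
inflammatory bowel disease: loss of the butyrate producer Fp and
expansion of the facultative anaerobe Ec.

## Model structure

### Geometry, fields and boundary conditions

The biofilm occupies a fixed depth `[0, L]` with `L = 40 um`; `z = 0` is
the mucosa (intestine) boundary and `z = L` the stool boundary. Twenty-six
fields are tracked: three biomass densities `X_i(z, t)` (g/L), fifteen
nutrients `S_j` (four monosaccharides, ten amino acids, oxygen; mM) and
eight byproducts `P_k` (acetate, propionate, butyrate, ethanol, formate,
lactate, succinate, CO2; mM):

    dX_i/dt = D_X d2X_i/dz2 + (mu_i - k_death,i) X_i
    dS_j/dt = D_j d2S_j/dz2 + sum_i v_ij X_i
    dP_k/dt = D_k d2P_k/dz2 + sum_i v_ik X_i

Exchange fluxes `v` (mmol/gDW/h, uptake negative) times biomass (g/L)
give mM/h directly. All boundaries are Robin (mass-transfer)
conditions, `-D dC/dz = k (C - C_bulk)` oriented outward: nutrients
enter at the stool side against the diet bulk concentrations and leave
at the mucosa side against zero bulk; byproducts leave at both
boundaries against zero bulk; biomass is eroded at the stool side
against zero bulk and has a zero-flux mucosa boundary (erosion is the
only biomass sink, which is what allows nontrivial steady states).
Parameters are held in `ParameterSet` in their tabulated units
(cm^2/s, cm/s, um) and converted exactly once to the internal
hour/cm/mM/(g/L) system.

### Metabolism: lexicographic FBA with kinetic bounds

At every grid node and time each species solves a linear program:
maximize growth subject to stoichiometric steady state and flux bounds,
with local nutrient availability imposed as Michaelis-Menten uptake
bounds `v_max C / (K_m + C)` on the exchange reactions (class-wise
kinetics: carbohydrates 10/0.5, amino acids 1/0.1, oxygen 20/0.003,
byproducts 10/0.5 in mmol/gDW/h and mM). Because the growth-optimal
flux vector is generally degenerate, exchange fluxes are made unique by
lexicographic optimization: after the biomass optimum is fixed, every
exchange flux is maximized in a fixed metabolite order (sugars, amino
acids, oxygen, SCFAs, then the remaining organic byproducts, each group
alphabetical). Maximizing an exchange flux minimizes uptake magnitude
and maximizes secretion in a single uniform rule. Each stage objective
is a single flux, so "fixing the previous optimum" reduces to clamping
one column, and the whole cascade runs on a persistent warm-started
GLPK problem (~20 stages, ~0.2 ms). An infeasible LP (maintenance
demand unsatisfiable at the local concentrations) returns zero growth
and zero fluxes; biomass then declines only through transport or
antibiotic death. Concentrations below 1e-12 mM are clipped to zero
before bound evaluation; solutions are memoized on the bound vector
quantized at 1e-4 mmol/gDW/h, which also makes repeated evaluations
bit-identical.

### Reduced metabolic networks

The three species are represented by lumped-pathway networks (~30
reactions each) rather than genome-scale reconstructions, so the whole
pipeline runs and is testable without downloads; genuine
reconstructions can be loaded from SBML and dropped in. Design
principles:

- All catabolism funnels into a common six-carbon unit (`g6`); every
  lumped reaction closes exactly in carbon (CO2 included), and the
  biomass reaction fixes 40 mmol C per gDW, so whole-community carbon
  balance is exact by construction.
- Species differ in pathway ATP yields, which is what competition acts
  on. Bt is the efficient carbohydrate generalist (4 ATP per g6 through
  a redox-balanced branched fermentation co-secreting acetate,
  propionate and succinate); Ec is the protein specialist (full
  amino-acid carbon recovery plus a deamination ATP bonus) whose main
  anaerobic route is mixed-acid fermentation with fixed
  acetate:ethanol:formate = 1:1:2 — the ethanol output is the
  cross-feeding supply to Bt; Fp ferments g6 to butyrate and carries
  capped acetate/succinate co-utilization pathways (1.5 mmol/gDW/h
  each), its unique income from the byproducts of the other two.
- Fixed product ratios matter: if secretion routes are left as free
  alternatives, the LP always picks the single highest-yield route and
  the cross-feeding topology silently dies. The committed networks
  encode redox constraints as fixed ratios so that acetate, propionate,
  succinate, ethanol and formate actually flow.
- Oxygen enters through respiration (Bt 14, Ec 40 ATP per g6 + 6 O2)
  and, for Fp, only through an extracellular flavin/thiol electron
  shuttle worth 0.4 ATP per O2 that requires riboflavin and a thiol in
  the medium; knocking the shuttle out (bound to zero) removes Fp's
  only oxygen sink. Respiration yields set the aerobic displacement
  strength and are exactly orthogonal to the anaerobic calibration.
- The finite cross-feeding caps control how collapsible Fp is: its
  capped income is an abundance-independent refuge, so large caps make
  Fp unconditionally persistent while small caps make its anaerobic
  share knife-edged. The committed value (1.5) leaves the anaerobic
  coexistence smoothly tunable by maintenance costs yet allows oxygen
  to displace Fp completely.

### Maintenance calibration

With every non-growth ATP maintenance (ATPM) flux at the published
8.43 mmol/gDW/h, Bt excludes both partners — its nutritional
superiority makes it the sole survivor. `calibrate_atpm` therefore
lowers the Fp and Ec maintenance values (Bt stays fixed) by alternating
damped-secant searches until the anaerobic high-CHO community reaches
the healthy 60:30:10 Bt:Fp:Ec split; each species' fraction decreases
monotonically in its own maintenance cost. The committed calibration is
`ATPM_Fp = 5.2`, `ATPM_Ec = 3.9`, giving 60.0:30.3:9.7. The published
tuned values (4.75/5.5) remain the network defaults but belong to the
genome-scale models and do not reproduce the healthy split on the
reduced networks. An analogous log-scale search (`calibrate_scfa_mtc`)
tunes the butyrate and propionate mass-transfer coefficients toward an
acetate:propionate:butyrate split of 60:20:20; a larger coefficient
removes that SCFA faster and lowers its share monotonically.

### Scenario battery

Every perturbation starts from the anaerobic steady state of its diet
(computed from a spatially homogeneous 10 g/L start). Diets are
specified on a six-carbon basis (high-CHO 5.0/1.5, high-protein
1.5/5.0, equal 3.25/3.25 mM CHO/protein), the carbohydrate pool split
40% glucose and 20% each arabinose/fructose/galactose, protein split
equally over the ten amino acids, and each nutrient corrected by
`actual = C6 * 6 / carbons`.

- Fixed oxygen: the stool-side oxygen bulk is set to a value in
  [0, 5e-3] mM and the response integrated to steady state; the default
  sweep uses 11 evenly spaced values.
- Host feedback: the oxygen bulk is a state function,
  `O_b = O_pert + (5e-3 - O_pert) (1 - Fp_mean/Fp_anaerobic)` clamped
  to [O_pert, 5e-3], evaluated continuously inside the integrator from
  the biofilm-averaged Fp biomass. This encodes the positive loop in
  which Fp (butyrate) loss raises mucosal oxygen.
- Antibiotic: a spatially uniform first-order death term
  `kill_constant * level` on every species, with feedback active and no
  direct oxygen perturbation, so oxygen rises only because the drug
  depresses Fp. Kill constants are configuration (default 0.04 1/h per
  unit level for all species — the main text of the source work gives
  none); the qualitative collapse occurs mid-range of the normalized
  [0, 1] level (persists at 0.3, collapses at 0.7).

### Behavior of the calibrated community

On the committed networks the battery reproduces the qualitative
oxygen-dysbiosis phenomenology: abundances are nearly insensitive to
bulk oxygen below 1e-3 mM (Fp retains >90%), decline gradually through
2-3e-3 mM, and collapse at 4-5e-3 mM (Fp eliminated, Ec roughly 3-4x
its anaerobic biomass, Bt mildly up); steady-state oxygen stays
confined to the top few microns (peak below ~1000 nM, biofilm average
below ~40 nM). Host feedback shows threshold behavior — perturbations
up to ~1.5e-3 mM settle with Fp intact while 2e-3 mM triggers a
runaway to full collapse — and the feedback collapse unfolds over
several-fold more simulated hours than the fixed-oxygen response to the
same perturbation, because oxygen only rises as fast as Fp declines.

## Numerics

### Integrator

The method of lines uses a uniform grid (default N = 20, i.e. 520
ODEs), second-order central differences, and ghost-node Robin closures;
with trapezoidal quadrature the discrete transport operator telescopes
exactly to the boundary fluxes, which is what makes the steady-state
carbon balance close to rounding error.

Stiffness comes from diffusion (boundary exchange rates ~1e4/h against
community dynamics of ~0.1/h), while the embedded LPs make the
right-hand side expensive and non-smooth, so a generic stiff integrator
with finite-difference Jacobians is impractical. The production
integrator is an adaptive linearly-implicit scheme: diffusion, boundary
exchange, biomass death and nutrient consumption (rewritten exactly as
a first-order loss `|v| X / C`) are implicit — one vectorized
tridiagonal solve per field per step — while growth and secretion are
explicit. The implicit part is an M-matrix, so positivity is preserved
unconditionally; fixed points of the scheme are exact steady states of
the semi-discrete system regardless of step size. The step size adapts
to a relative-change target (8% per step against scale floors of
0.02 g/L and 1 mM), is capped at `2/max(mu)` for the explicit growth
term, and any step changing a field by more than 100% is rejected and
retried smaller. Because the implicit consumption realizes uptake
scaled by `C_new/C_old` within a step, the corresponding carbon
shortfall is debited from the applied growth rate node by node; the
applied fluxes therefore stay exactly carbon-closed and the
steady-state boundary carbon balance closes to the drift tolerance
(measured ~3e-6 relative on the refined anaerobic state).

### Discontinuous right-hand sides and steady-state detection

The LP flux field switches discontinuously when the optimal basis
changes with concentrations (e.g. between substitutable sugars), which
makes trajectories chatter around sliding surfaces instead of settling.
Two mechanisms handle this:

- A first-order lag (time constant 0.5 h) filters the flux field before
  it enters the balance equations — physically a metabolic
  readjustment time, numerically a regularization whose fixed points
  coincide with the unlagged ones away from switching surfaces and are
  the Filippov sliding equilibria on them. When window drift is far
  below per-step chatter the lag constant anneals upward, capped at
  50 h so that it can never freeze a slow transient into a spurious
  steady state (an earlier uncapped version did exactly that).
- Steady state is declared on time-window averages: consecutive window
  means (500 h in scenario runs) must drift slower than `tol` (1/h)
  relative to per-field scale floors, twice in a row; the reported
  state and flux field are the final window averages. The anaerobic
  community has a genuine small-amplitude limit cycle of the
  cross-feeding loop (~1% in biomass, ~8% in acetate), and the window
  average over it is the reported steady state.

Scenario runs use `tol = 1e-5`/h, which reproduces steady summaries to
about four digits. The operation-level default is stricter (1e-8/h)
and is reachable only for non-chattering configurations. Because the
community also carries a slow competitive eigenmode (~1e3 h), runs that
must agree to better than ~1% — the initial-condition-independence
check — tighten to `tol = 2e-6` with 2000 h windows, after which
different homogeneous starts agree to ~2e-4 relative.

### Problem sizes and scaled-down choices

Default runs use N = 20 nodes (the grid-convergence check against
N = 40 shows abundance shifts below 2 percentage points) and
integration horizons of up to 6e4 h, reached adaptively with steps
capped at 25 h. The maintenance calibration evaluates its search
iterates on a 12-node grid — justified by the same grid-convergence
property — with warm-started equilibrations, re-seeding extinct species
at 0.5 g/L so they can re-invade under new maintenance values.

## What the synthetic networks do and do not show

The reduced networks are designed artifacts: their pathway yields were
chosen so that the community reproduces the *structure* of the studied
system — Bt-only collapse at equal maintenance, a smoothly tunable
60:30:10 coexistence, oxygen-graded dysbiosis with the correct ordering
of aerobic benefits (Ec >> Bt > Fp > Fp-without-shuttle = 0), realistic
oxygen penetration, feedback thresholds and antibiotic analogies.
Passing tests on them demonstrates that the pipeline — kinetic-bounded
lexicographic dFBA, transport, protocol, calibrations and summaries —
behaves correctly and that the oxygen-dysbiosis mechanism needs nothing
beyond metabolic differences. They do not reproduce the quantitative
figures of genome-scale reconstructions (per-species flux magnitudes,
exact SCFA splits, the published tuned maintenance values), and no such
agreement should be inferred from green tests. Loading the real SBML
reconstructions through `load_sbml_model` is the supported path to
quantitative work.

## Known limitations

- One spatial dimension, fixed biofilm thickness, no
  attachment/detachment or planktonic phase.
- No oxygen toxicity or growth inhibition: oxygen acts only through
  respiration benefits. At the oxygen levels studied (biofilm average
  below ~100 nM) this is defensible, but it removes one mechanism of
  obligate-anaerobe decline.
- The antibiotic is a spatially uniform first-order kill with
  configuration-chosen constants; no pharmacokinetics or diffusing drug
  field.
- Steady states are sliding/cycle averages; pointwise instantaneous
  residuals at LP switching nodes do not vanish, and quantities derived
  from single nodes at single instants inherit the chatter amplitude
  (~1% biomass).
- The feedback law is the stated linear phenomenology; nothing
  mechanistic about host colonocytes is modeled.
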