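# Methods

## The core metabolic model

The model is a deliberately small, single-compartment stoichiometric
network of methanotrophic C1 metabolism, built to expose one question:
what happens to redox and carbon balance when methanol oxidation hands
its electrons to a cytochrome pool and part of the formaldehyde is
oxidised onward to formate before it can be assimilated.

Carbon path: CH₄ →(PMMO)→ CH₃OH →(MXA or XOXF)→ HCHO, which either
enters a lumped RuMP assimilation step (3 HCHO + ADP + Pi + NAD →
pyruvate + ATP + NADH) or is oxidised to formate by the lumped
H4MPT route (NADH-yielding) or — in the La configuration — by the
cytochrome-linked `MXALa` reaction (HCHO + H₂O + 2 cytₓ_ox → HCOOH +
2 cytₓ_red). Formate is oxidised to CO₂ by formate dehydrogenase
(NADH-yielding) or reclaimed to formaldehyde by a lumped
tetrahydrofolate route at the cost of one ATP and one NADH.

Redox bookkeeping uses explicit carrier pairs: the quinone pool (qh2
feeds pMMO), NAD(H), and separate MxaFI- and XoxF-associated cytochrome
pools. Respiration is lumped into three ETC reactions with P/O-style
ATP stoichiometries: `po_nadh` ATP per NADH (default 1.5) and `po_cyt`
ATP per cytochrome pair (default 1.0). Biomass synthesis consumes one
pyruvate plus β ATP and γ NADH (γ = 0.3); β is the calibration handle
(see below). Protons are folded into these lumped parameters; pseudo
species (ATP/ADP/Pi, carriers, biomass) carry only the hydrogens they
ferry so that every non-lumped reaction closes for C, H and O, and every
non-exchange reaction — lumped ones included — closes for carbon.

### Reverse electron flow from the methanol dehydrogenases

`CYTM_Q`/`CYTX_Q` (2 cyt_red + q → 2 cyt_ox + qh2) let methanol-derived
electrons reduce the quinone pool that feeds pMMO, and are active by
default. This is a deliberate design choice with a stoichiometric
rationale: without it, every methanol oxidised deposits one cytochrome
pair whose only sink is the terminal oxidase at 0.5 O₂, which pins the
O₂:CH₄ ratio at ≥ 1.5 for any growth state — well above the 1.1–1.3
ratios measured in Ca-grown methanotroph chemostats. With direct
coupling the model's achievable ratio spans ≈1.12–2.0, bracketing the
observed values. Thermodynamics (this is reverse electron flow) is
outside the model's scope, as is any compartmentalised proton-motive
force; the coupling reaction should be read as "pMMO can be fed by
methanol-derived electrons", a standing hypothesis for pMMO electron
supply. Set `EnzymeConfig(direct_coupling_active=False)` to explore the
uncoupled variant.

### FBA conventions

- CH₄ uptake is fixed (both bounds) during simulations and growth is
  maximised. The default uptake, 11.67 mmol gDCW⁻¹ h⁻¹, is the
  wild-type O₂ consumption rate divided by its O₂:CH₄ ratio
  (13.77/1.18); a fixed uptake also reproduces the constant
  o2_rate/ratio quotient across scan rows.
- Solver: scipy's HiGHS interface. Among alternate optima the reported
  flux vector minimises Σ|v| at the fixed optimum (two-stage LP with a
  positive/negative split). Feasibility tolerance 1e-9; rendered tables
  round to 2 decimals.
- The branch constraint is a single extra linear row
  v_MXALa − φ·v_XOXF = 0: φ is the fraction of XoxF-processed methanol
  whose formaldehyde is carried on to formate. φ = 0 recovers the plain
  XoxF model; φ = 1 with the formate reclaim disabled abolishes growth
  (no formaldehyde reaches assimilation).
- `calibrate_energetics` bisects β (biomass ATP cost) until the
  wild-type solved ratio matches an observed ratio to 1e-3. The ratio
  is monotone non-decreasing in β (more ATP demand → more respiration),
  which the routine verifies on the bracket before bisecting. The
  package default β = 2.7 is the value this calibration returns for a
  1.18 target, rounded to one decimal.

### What the core model is not

It is not the published genome-scale reconstruction; absolute Table-3
style numbers from that model are reproduced only qualitatively here
(monotone ratio increase with φ, wild type at the minimum, ratios in
(1, 2)). The SBML(+fbc) reader exists precisely so a genome-scale model
can be dropped in when available.

## Chemostat physiology

At steady state μ = D. Gas consumption is the inlet−outlet percentage
drop times the gas flow, converted at 22.414 L mol⁻¹ (0 °C, 1 atm; the
"standard litre" convention adopted here). CH₄ molar mass 16.04 g mol⁻¹.
Yield is biomass production D·X·V over CH₄ consumption in g h⁻¹;
specific rates divide by standing biomass X·V. The steady-state window
is supplied by the caller — there is no automatic steady-state
detection. Culture volume is always an explicit input: published
chemostat tables are sometimes internally consistent only for an
effective volume differing from the vessel's nominal one, so no default
is guessed in the calculators.

## Synthetic data

The generators emulate a two-condition (Ca vs La) chemostat experiment
with two RNA replicates and three proteomics/metabolomics replicates.

- **Off-gas** (`simulate_offgas`): condition presets use the study's
  chemostat settings (D = 0.05/0.07 h⁻¹ at optimal gas supply, biomass
  0.64/0.75 g L⁻¹, yields 1.2/0.64 g g⁻¹, planted O₂:CH₄ ratios
  1.12/1.28) with the physical apparatus scale (0.25 L culture, 1 sL h⁻¹
  gas, 5%:5% or 2.5%:10% CH₄:O₂), which keeps implied outlet
  percentages positive. Noise is multiplicative Gaussian on the outlet
  readings (`noise_sd_pct` is analyzer precision as percent of reading,
  default 1%), sampled every 0.5 h for 24 h.
- **RNA counts** (`simulate_counts`): negative binomial with dispersion
  0.05 (variance μ + 0.05 μ²; 0 reduces to Poisson), background means
  log-uniform over ~4 decades around the depth scale (default 300).
  The wide dynamic range is what real transcriptomes show and is what
  makes pairwise replicate log–log Pearson correlations exceed 0.98 at
  this dispersion, matching the reproducibility reported for the real
  replicates. Registry features sit at the depth-scale mean so even the
  70× effect is expressible.
- **Spectral counts** (`simulate_spectral_counts`): Poisson at mean 30,
  three replicates. Planted protein effects: the MxaFIG subunits at
  1/20 (the printed magnitude of their collapse is not stated; 1/20 is
  a parameterised default), XoxF at the reported twofold, Fae2 up
  (magnitude unprinted; default 4×), XoxG4 unchanged.
- **Metabolites** (`simulate_metabolites`): log-normal abundances,
  replicate SD 0.25 on the log2 scale, planted shifts ±1 log2 unit for
  the "down" (sugar phosphates, PEP, 3PG, citrate, aconitate) and "up"
  (TCA-derived amino acids, ectoine, glycerate, agmatine) groups and 0
  for the flat group (fumarate, malate, succinate).

What the generators do **not** emulate: library-size differences and
GC/length biases in RNA-seq, peptide-level missingness and shared
peptides in spectral counting, batch effects, correlated features, or
drift/autocorrelation in off-gas series. Passing recovery tests
therefore demonstrates that the calculators invert the stated noise
models — not that the pipeline is robust to every artefact of real
multi-omics data.

The DE p-values used to close the loop on synthetic counts come from a
Welch t-test on log2(count+1) (`welch_de_table`). With two replicates
this test is deliberately simple and conservative; count-model DE
estimation (negative-binomial shrinkage as in dedicated DE tools) is
out of scope, and the decision rules consume any externally produced
log2FC + p table.

## Decision rules

- DE call: BH-adjusted p < 0.05 **and** |log2FC| ≥ 1.5. The fold
  threshold is exposed because the source conventions differ between a
  1.5-fold change (≈0.58 on the log2 scale) and a 1.5 log2-unit change
  (≈2.8-fold); the stricter log2 reading is the default.
- Spectral counts: replicate-averaged fold change with a pseudocount of
  1 added to both condition means (zero handling is otherwise
  undefined); significant if FC > 2 or < 0.5.
- Concordance categories are a pure function of the two calls
  (concordant_up/down, discordant, protein_only, rna_only, ns) over the
  outer join of the feature spaces.
- Metabolite zeros are replaced by half the smallest positive value in
  the table before log-ratios; all-zero rows are dropped with a warning.
- Spearman correlation uses average ranks for ties; for n ≤ 8 the
  two-sided p-value is computed by exact permutation enumeration,
  otherwise by the t approximation.

## Numerical and testing notes

- LP correctness is cross-checked two ways: a brute-force vertex
  enumeration oracle on small toy networks, and an independent cobrapy
  rebuild of the core model solved with its own LP stack.
- BH adjustment is checked against both a literal step-up brute force
  and statsmodels' `fdr_bh`.
- Simulation-based checks (effect recovery, replicate realism, off-gas
  ratio recovery) run over 20 fixed seeds; problem sizes (2000 genes,
  500 proteins, 24 h series) keep the full suite in a few seconds while
  leaving estimator noise well inside the asserted tolerances.

## Known limitations

- The core model's absolute fluxes depend on the lumped energetic
  parameters; only β is calibrated, and only against a single observable
  (the wild-type O₂:CH₄ ratio). Different (po_nadh, po_cyt, γ, β)
  combinations can produce the same ratio.
- The φ-scan's quantitative ratios depend on the reclaim route's cost;
  the qualitative ordering does not.
- Exact permutation p-values above n = 8 would be expensive (n!
  orderings) and are approximated; ties make the t approximation
  slightly anticonservative.
- The Welch DE stand-in has low power at two replicates; planted
  effects are recovered through their fold-change estimates, not
  through padj-significant calls.
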