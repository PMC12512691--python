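# Methods

## Scope and model

`leafgas` analyses dynamic leaf gas-exchange measurements of the kind
produced by a LI-6800-class infrared gas analyser running a stepped light
protocol, and relates them to stomatal anatomy. The pipeline is:

1. **Parsing and area correction** (`leafgas.io`). Exports carry a header
   block (group row, variable names, units row) and one record per logged
   minute. Units are normalised at the boundary (internal canon: s,
   mol m⁻² s⁻¹ for g_SW and E, µmol m⁻² s⁻¹ for A and PAR, µmol mol⁻¹ for
   CO₂ mole fractions). Because a grass leaf rarely fills the chamber
   aperture, per-area fluxes are rescaled by
   `chamber_area / (leaf_width × chamber_diameter)`. A leaf wider than the
   aperture covers it completely, so the factor is clamped to 1 (explicit
   override required). The chamber diameter is deliberately a required
   configuration input with no default: it is instrument-specific and
   silently assuming one would corrupt every flux.

2. **Phases and steady states** (`leafgas.timecourse`). The run is
   partitioned into constant-light phases either from a declared schedule
   (boundaries at cumulative durations) or by detecting relative jumps in
   incident light above 20% between consecutive records. Intervals are
   half-open with the boundary record assigned to the *new* phase — the
   light change takes effect at the log that follows the setpoint change.
   Steady states are means ± standard errors over the final 5 min of each
   phase (5 records at 60-s logging), the window anchored at the phase end.

3. **iWUE.** Intrinsic water-use efficiency is the pointwise quotient
   A/g_SW, and phase summaries average those pointwise quotients (mean of
   ratios), not the quotient of the phase means. The two differ whenever A
   and g_SW vary within the window; the mean-of-ratios convention matches
   how the quantity is defined per time point. iWUE is undefined below a
   conductance floor of 10⁻³ mol m⁻² s⁻¹ (darkness); undefined points are
   flagged, never errors, and excluded from window means.

4. **Kinetics** (`leafgas.kinetics`). Each light transition is fitted with
   the Gompertz-type sigmoid

       g(t) = g_i + (g_f − g_i)·exp(−exp((λ − t)/k)),

   t in minutes since the switch. λ (min) is the lag: the inflection point,
   where |dg/dt| peaks at |g_f − g_i|/(k·e). k (min) is the time parameter;
   because kinetics tables in the field often print the rate 1/k (min⁻¹),
   both are reported. Sl_max = (g_f − g_i)/(k·e), converted to
   mmol m⁻² s⁻² (×10³ mol→mmol, ÷60 min⁻¹→s⁻¹), carries the direction in
   its sign. One code path fits both opening and closing.

   Fitting is bounded trust-region least squares (scipy `curve_fit`,
   tolerances 10⁻¹⁵). Initialisation: g_i from the preceding phase's steady
   state, g_f from the last five points, λ₀ from the 10%-progress crossing,
   k₀ = (63% crossing − λ₀) floored at 0.5 min. Bounds: λ ∈ [0, window],
   k ∈ [0.1, 60] min. A trace whose conductance range stays below the
   response floor (default 0.01 mol m⁻² s⁻¹) is flagged `no_response`
   without fitting; non-convergence returns a flagged failure object so a
   cohort run never aborts on one bad leaf.

   Cross-individual summaries remove outliers per parameter with the
   1.5×IQR rule inside each (group, transition) cell before averaging. The
   rule is explicit and configurable, and removed values are listed in the
   output, never silently dropped. With cohorts of ~5 the rule is sharp
   (IQR can be 0 for tightly clustered fits); that is the documented cost
   of a distribution-free rule at small n.

5. **Anatomy** (`leafgas.anatomy`). Density uses the pooled estimator
   Σcount/Σarea per individual — fields share one objective and area, and
   pooling is the variance-minimal choice; per-field densities are reported
   for dispersion. The length/width ratio is computed per stoma then
   averaged, with the ratio of means also emitted because printed tables
   are typically built from rounded means. Anatomical maximum conductance
   follows the diffusion form

       g_smax = d·D_w·a_max / (v·(l + (π/2)·√(a_max/π)))

   with density d (m⁻²), water-vapour diffusivity D_w (default
   2.49×10⁻⁵ m² s⁻¹), molar volume v (default 0.0224 m³ mol⁻¹), maximum
   pore area a_max and pore depth l. How a_max and l derive from stomatal
   complex length and width is taxon-specific (graminoid dumbbell complexes
   differ sharply from kidney-shaped guard cells), so the estimators are a
   named registry (`scaled_ellipse`, `affine_product`,
   `rectangle_fraction`; depth: fraction of width/length or constant) that
   **requires** coefficients: shipping hidden defaults would fabricate a
   calibration this package does not own. Operational opening is
   100 × g_SW(high light)/g_smax, half-up rounded for table output with the
   unrounded value retained.

   Group statistics: two-sided Pearson correlation (density vs size),
   one-way ANOVA and Tukey HSD at α = 0.05 (statsmodels), with a
   deterministic compact-letter display built over maximal runs of mutually
   non-different groups sorted by descending mean.

## Synthetic data

The simulator reproduces the study conditions the analysis expects:
60-s logging through 20-min light steps at 1000 → 100 → 1000 → 0 PAR.
Default phase conductances (0.273, 0.082, 0.252, 0.018 mol m⁻² s⁻¹) and
transition parameters (λ = 1.24/1.44/1.05 min, k = 2.0/2.5/2.5 min) describe
a well-watered C3 grass leaf and yield maximum-slope magnitudes of
≈ −0.59/+0.42/−0.57 mmol m⁻² s⁻², the regime published for *Brachypodium
distachyon*. Transitions are chained continuously — each transition's g_i
is the realised conductance at the end of the previous phase, matching the
fitter's initialisation assumptions. Default measurement noise is i.i.d.
Gaussian (σ = 0.005 mol m⁻² s⁻¹ on g_SW, 0.1 µmol m⁻² s⁻¹ on A).

Assimilation coupling is selectable: linear A = c·g_SW (default c = 70,
which fixes iWUE ≡ 70 µmol mol⁻¹ — a strong end-to-end oracle) or
saturating A = A_max·g_SW/(g_SW + K). Ci = Ca − A/(1.6·g_SW) clipped at 0
and E ∝ g_SW are consistency bookkeeping, not a mechanistic leaf model: no
boundary-layer, energy-balance or biochemical (FvCB) component is included.
Consequently, passing tests demonstrate correct recovery of the stated
generative model under Gaussian noise — they do not validate the sigmoid
against real leaves, instrument drift, non-Gaussian artefacts (match/range
events), or humidity feedback on stomata.

The anatomy generator draws field counts from Poisson(density × 0.198 mm²)
over 3 fields per individual and 73–100 per-stoma sizes from truncated
normals, with an optional Gaussian-copula-style coupling between an
individual's density deviate and its mean stomatal length to emulate the
denser-means-smaller pattern.

## Numerical choices and degenerate inputs

* The sigmoid's inner exponent is clipped at ±745 to avoid overflow; the
  curve saturates to its asymptotes in floats a few k beyond λ.
* Identifiability: with 60-s logging and σ = 0.005, the Fisher information
  of a single 20-point transition bounds the per-fit scatter of λ at a
  relative sd of roughly 0.3 (k ≈ 0.1). Single-transition λ estimates are
  therefore reported with that caveat; recovery checks assert the median
  of recovered parameters across replicates (median bias), which is at the
  per-mille level for this estimator.
* Duplicate timestamps and non-increasing time are schema errors;
  remark/event rows interleaved in exports are skipped and counted.
* Steady-state SE uses ddof = 1; a single defined point yields SE 0 and
  n = 1 (iWUE in near-closed phases).
* Quartiles for the IQR rule use linear interpolation (numpy default).
* Rounding for table reproduction is half-up (integers for operational
  opening, 2 decimals for per-stoma conductances, 1 for ratios); machine
  outputs keep full precision.
* Per-stoma tables use the ÷density ×10³ convention of published per-stoma
  tables; the strict SI factor 1/(density × 10⁶) is recorded in run
  metadata because the printed unit labels are 10³-fold off strict SI —
  the convention is implemented, the label discrepancy documented, not
  resolved.

## Problem sizes

Tests and the acceptance script run: 80-record four-phase runs, cohorts of
2–5 simulated leaves, 100-replicate noise studies for kinetics recovery and
200 seeded replicates for the density estimator — sizes chosen so the full
suite executes in seconds while every estimator is exercised across its
operating range.

## Known limitations

* No mesophyll-conductance or energy-balance recomputation: instrument
  g_SW/A are trusted after area correction.
* Single-aperture chamber geometry only; no instrument control or
  calibration handling.
* The Gompertz family is the only kinetics model; responses with overshoot
  or biphasic behaviour will fit poorly (visible in the r² diagnostics).
* g_smax coefficients must be supplied; the package validates structure,
  not the biological plausibility of a calibration.
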