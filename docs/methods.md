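# Methods

## Denaturation schemes and their discrimination

Protein unfolding observed by DSC is modelled by three candidate
schemes. The reversible two-state model N ⇌ D assumes equilibrium is
reached instantly relative to the ramp, with

    K(T) = exp(−(ΔH_vH/R)(1/T − 1/T_m)),   α = K/(1+K),
    C_p^exc = ΔH_cal · α(1−α) · ΔH_vH/(R T²),

so the endotherm is the same at every scan rate. The kinetic models
make each step first-order and irreversible with the Arrhenius rate
k(T) = exp(−(E_a/R)(1/T − 1/T\*)); T\* (the temperature where
k = 1 s⁻¹) replaces the frequency factor A = exp(E_a/(R T\*)), which is
assumed constant over the narrow temperature window scanned. For a
one-step scheme the endotherm keeps its shape but its maximum moves
with scan rate according to the closed-form peak condition
k(T_m) = v E_a/(R T_m²) — equivalently, regressing ln(v/T_m²) on
1/T_m across scan rates has slope −E_a/R. For the two-step scheme
(N → I → D) both the position and the shape change with v. These three
signatures are what a multi-scan-rate experiment can discriminate and a
single scan cannot.

Assumptions: no heat-capacity difference between states (ΔC_p = 0;
inputs are taken to be buffer-subtracted, baseline-corrected excess
heat capacities), no aggregation-explicit terms, at most two sequential
transitions, and a catalytically inactive intermediate — so the
functional stability metric is the native-state half-life
t_1/2 = ln 2/k₁.

## Numerical integration of the ramp equations

Along a linear ramp the populations obey dx_N/dT = −k₁x_N/v and
dx_I/dT = (k₁x_N − k₂x_I)/v (v in K/s). Rather than a generic ODE
solver, the implementation exploits the sequential first-order
structure: x_N = exp(−(1/v)∫k₁ dT) by exact quadrature (cumulative
trapezoid), and x_I is propagated by an exponential-integrator
recurrence

    x_I(T+h) = x_I(T)·e^(−ΔE₂) + (h/2)·(g(T)·e^(−ΔE₂) + g(T+h)),

with g = k₁x_N/v and ΔE₂ = ∫k₂/v dT over the step. The decay factor is
exact, so the scheme is unconditionally stable in the stiff
late-transition regime where k₂/v reaches thousands per kelvin — the
regime where explicit steppers fail and adaptive implicit solvers spend
most of their work. Each output grid interval is internally refined to
≤ 0.02 K; rates are capped at 10¹² s⁻¹ to keep quadratures finite far
above T\*. Accuracy is verified against fixed-step Euler and RK4
oracles at 10⁵ steps (agreement < 10⁻⁴ on state fractions across 20
randomized parameter draws) and by conservation checks (state fractions
sum to 1 within 10⁻⁶; thermogram area equals ΣΔH_cal within 0.5 % when
the grid spans the transition). The inner recurrence is numba-compiled;
one model evaluation on a five-thermogram series costs well under a
millisecond, which is what makes global multi-start fitting and the
recovery experiments cheap.

The start-of-grid check (flux measure k₁(T₀)·span/v < 10⁻⁴,
warn-by-default and configurable) applies to the first transition only:
the native state is the sole populated reservoir at the scan start, so
the rate of a later step carries no flux there. Real scans that start
at 50 °C are not exactly flux-free; hence warn, not error.

The apparent T_m is the grid maximum refined by a quadratic through the
three surrounding points; exact ties resolve to the lower temperature
for determinism, and a maximum on the grid boundary is an error (the
transition is not contained in the scan window).

## Global fitting

All thermograms of a series are fitted simultaneously with one shared
parameter set, by trust-region least squares (unweighted by default;
per-thermogram weights are available). E_a and ΔH_cal are optimized in
log space for positivity; T\* is bounded to a 250–450 K plausibility
window. Starting values are data-driven: T\* from the apparent T_m of
the median-rate thermogram through the one-step peak condition with an
E_a seed of 300 kJ/mol, ΔH from the curve area (split 80/20 for the
two-step model, mirroring the typical dominance of the first
endotherm). A seeded multi-start loop (default 8 starts; T\* perturbed
by N(0, 1.5 K), log parameters by N(0, 0.15)) guards against local
minima and stops early once two starts agree on the best residual sum
of squares to 10⁻⁶ relative. Standard errors are linearized
(delta-method on the log-parameterization) from the SVD
pseudo-inverse of the Jacobian at the optimum.

Model selection ranks candidates by AICc
(n ln(rss/n) + 2k + 2k(k+1)/(n−k−1), k counting the residual
variance). Because the two-step model nests the one-step model, a fit
of one-step data by the two-step scheme recovers a χ²₃-sized residual
improvement by chance, which raw AICc mis-ranks in roughly a tenth of
trials; among models within ΔAICc ≤ 2 of the best — statistically
equivalent fits by the usual information-theoretic convention — the one
with fewest parameters is therefore selected. This realizes "the
simplest model that gives a satisfactory fit" as an explicit rule. A
residual ~5 % per-trial chance remains that a nested-truth fluctuation
exceeds the band; it is visible occasionally in the acceptance script's
model-recovery fraction and is reported as measured.

Deconvolution returns the per-transition heat-capacity components
ΔH₁k₁x_N/v and ΔH₂k₂x_I/v evaluated at the fitted optimum; their sum
is the fitted curve by construction and their areas equal the fitted
per-transition enthalpies.

Irreversible models are refused a single-scan-rate series as
unidentifiable (the scan-rate dependence *is* the kinetic information).

## Stability extrapolation

Fitted (E_a, T\*) pairs extrapolate k₁ and k₂ over any temperature
range (the default process window of interest is 65–72 °C). Derived
metrics: native-state half-life ln 2/k₁ (hours); percent lifetime loss
per +1 °C, 100(1 − k(T)/k(T+1)), which is dimensionless and in (0,100)
for any positive E_a; and the per-temperature percent excess
100(k_a/k_b − 1) between two variants, constant in T when the
activation energies are equal. A reporting helper rounds half-lives to
0.1 h and percentages to the nearest ten only for side-by-side
comparison with conventionally rounded literature values; machine
output keeps full precision. °C ↔ K conversion uses the exact 273.15
offset, once, at I/O boundaries.

## Depolymerization analytics

Monomer time courses carry TPA/MHET/BHET in either g/L or mM
(consistent per table; molar masses 166.13, 210.18, 254.24 g/mol), with
replicates aggregated as mean ± 1 SD. Conversion uses moles of
aromatic units released over moles of PET repeat units loaded
(M_repeat = 192.17 g/mol; % w/v loading → g/L as 10×). Initial rates
are ordinary least-squares slopes of total product over a window
(defaults: 8 h for plate assays, 12 h for bioreactor traces) with
replicates pooled and the intercept free. Fold changes are ratios of
replicate means at a shared timepoint with SD propagated in
quadrature; a missing timepoint requires an explicit opt-in to linear
interpolation. The pH-stat degree of hydrolysis counts **two** base
equivalents per fully hydrolyzed repeat unit (TPA is diprotic at the
reaction pH; ethylene glycol is neutral): %(t) = 100·V_cum·C_base /
(2·m_PET/M_repeat) — for 5.8 g PET in 6 M NaOH the 100 % volume is
10.06 mL. Partially hydrolyzed MHET contributes one acid equivalent,
so a reaction stalled at MHET under-reads on this scale; the package
reports the pH-stat and mass-loss metrics side by side and does not
attempt to reconcile them. Suspicious values are flagged, not
silently altered: conversions and retention fractions clip at 1.02
with a warning, hydrolysis > 102 % and residual mass above initial
(salt carry-over) warn and report as-is.

## Homolog site frequencies

Reference positions (1-based, ungapped) map bijectively onto alignment
columns by walking the gapped reference row. Frequencies are
percentages of the non-reference records; gaps count in the denominator
but never as matches, and a gap-excluded percentage is emitted
alongside, since the treatment of partial-coverage homologs is a
reporting choice rather than a fact of the data. Parsing is
case-insensitive; ambiguity codes (X, B, Z, …) are never matches and
are tallied separately.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of its parameters and a seed.

* **Thermograms** are forward-simulated at the acquisition conditions
  the analyses assume — five ramp rates 0.2/0.4/0.8/1.6/3.2 K/min over
  50–100 °C (0.2 K grid) — plus i.i.d. Gaussian noise scaled to 2 % of
  each curve's peak by default. The default two-step truth
  (E_a = 550/400 kJ/mol, T\* = 355.7/364 K, ΔH = 400/120 kJ/mol) is
  chosen so the printed observables of a thermophilic PET hydrolase are
  reproduced: k₁(65 °C) ≈ 6 × 10⁻⁵ s⁻¹ (half-life ≈ 3 h), ≈ 44 %
  lifetime loss per +1 °C, apparent T_m rising through the low-to-high
  70s °C across the scan rates, an endotherm dominated ~80/20 by the
  first transition, and two components separated enough to deconvolve
  into discrete peaks — which also makes all six parameters
  statistically determinable from the five-scan series (a nearly
  coincident second transition is unidentifiable for any fitter, and
  data like that could not have supported the per-transition parameter
  estimates this kind of study reports). Recovery experiments draw
  truths from ranges bracketing these defaults. Not emulated:
  baseline curvature, ΔC_p steps, aggregation exotherms, or correlated
  instrument noise — so passing recovery tests demonstrates correctness
  of the estimator, not robustness to un-modelled instrument artifacts.
* **Time courses** follow deactivation-limited release
  P(t) = (r₀/k_inact)(1 − e^(−k_inact t)) capped at the theoretical
  maximum, with a fraction of release appearing as MHET that matures to
  TPA first-order, and BHET zero by default (a transient minor
  species). Surface-erosion physics, crystallinity kinetics and product
  inhibition are not modelled.
* **Titration traces** are the exact stoichiometric inverse of the
  pH-stat computation (round trip identical to 10⁻⁹).
* **Alignments** realize queried site frequencies as exact counts (an
  unrealizable percentage raises an error naming the nearest realizable
  count); other columns mutate independently at a background rate.
  Real homolog alignments have phylogenetic correlation and gaps, which
  the generator does not imitate.

## Problem sizes and defaults

Recovery experiments use 10 trials (parameter recovery) and 10 trials
per model class (model recovery) at the full five-scan acquisition;
a full model-selection run on one series takes a few seconds on one
CPU, the complete test suite about three minutes, and
`scripts/acceptance.py` about one minute. Default multi-start seed
20250821; every command-line entry point accepts `--seed`.

## Known limitations

Buffer-composition effects on stability are not modelled (fits describe
the buffer in which the thermograms were recorded). Linearized standard
errors understate uncertainty near parameter bounds; a bootstrap is the
obvious extension and is deliberately out of scope. The AICc
equivalence band (Δ = 2) is a convention; nested-model selection at
2 %-of-peak noise retains a small per-trial error rate, quantified
above. The reversible model is fitted per series but shares no
information across scan rates beyond averaging, since its prediction is
scan-rate independent by construction.
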