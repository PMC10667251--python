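# Methods

## Scope and model

`fluxcohort` implements a steady-state ¹³C metabolic flux analysis (MFA)
pipeline for a patient-derived cell cohort (5 control / 7 sporadic-PD donors,
three replicates each), together with the surrounding assays: extracellular
exchange rates, mitochondrial stress-test bioenergetics, isotopologue-ratio
diagnostics, cohort statistics, and multi-block patient stratification.
Everything runs against a synthetic cohort with known ground truth, so every
stage can be verified end to end.

### Atom-transition network

The packaged TCA-toy network (`fluxcohort/data/tca_toy.tsv`) has 21 reactions:
lumped glycolysis (glucose → 2 pyruvate), lactate exchange, pyruvate
dehydrogenase and pyruvate carboxylase, the citric-acid cycle with a
reversible isocitrate-dehydrogenase step (reductive carboxylation), glutamine
entry via glutaminase, a reversible glutamate/α-ketoglutarate interconversion,
the GABA shunt, an unlabeled succinate dilution inflow, and four biomass
drains whose fluxes are fixed at growth rate × precursor coefficient
(default growth rate 0.001312 h⁻¹). Succinate and fumarate are rotationally
symmetric: every directed reaction producing them is expanded into both atom
orientations at half weight, which makes the pools positionally symmetric
irrespective of the consuming reaction's orientation.

The succinate dilution inflow matters: mass-isotopomer distributions are
intensive quantities, so in a linear chain they propagate unchanged no matter
the flux. A diagnostic such as M4-succinate/M5-α-ketoglutarate only responds
to the α-ketoglutarate-dehydrogenase (OGDHC) flux because a competing
unlabeled inflow (pre-existing pools, catabolism outside the model) claims a
larger share of the succinate turnover when OGDHC slows. The dilution flux is
a free parameter in fits, as is conventional for stationary models applied to
finite labeling times.

Reversibility follows identifiability: glucose uptake and the biomass drains
are irreversible; lactate and glutamate transport, isocitrate dehydrogenase,
fumarase, and the glutamate/AKG step are reversible with exchange fluxes.
Glutamine transport is modeled irreversibly because internal glutamine is fed
by a single fully-labeled source, making a transport exchange flux invisible
to the data. The glutamate/AKG exchange is fast (5.0 mM/h/mg DNA) — the
transamination equilibrium that justifies the field's use of glutamate
labeling as the AKG readout.

### EMU simulation and the brute-force oracle

Labeling is simulated by the elementary-metabolite-unit decomposition:
backward traversal from the observed fragments yields the minimal EMU set;
per size, a linear system balances EMU inflows against pool turnover, with
condensation reactions entering as convolutions of smaller, already-solved
EMUs. Reversible reactions carry forward flux `max(v,0)+e` and backward flux
`max(-v,0)+e` with exchange `e ≥ 0`; backward directions exist structurally
for *all* reactions so that the balance stays well defined when an optimizer
transiently drives a net flux negative (the bound penalty then pulls it
back). Pools whose turnover vanishes (a shunt pinned at zero during profile
continuation) are pinned to the unlabeled distribution — their MID is
ill-defined and irrelevant. Tracers are described by a per-carbon labeling
probability (U-¹³C at purity 0.99 by default; unlabeled co-substrates at 0
because the pipeline operates on natural-abundance-corrected MIDs).

An independent oracle solves the full positional-isotopomer balance by damped
fixed-point iteration over all 2ⁿ labeling states per pool (guarded at 2¹⁶
states total) and marginalizes to mass shifts. EMU and oracle agree to
≤ 10⁻¹² on the TCA-toy and on seeded random networks, which is the package's
primary correctness guarantee.

## Synthetic cohort: the study conditions

The generator's defaults are the study conditions and are not tuned per run:

| parameter | default | origin |
|---|---|---|
| cohort | 5 Ctrl / 7 sPD donors × 3 replicates | study design |
| tracers | 21.25 mM U-¹³C glucose; 1.25 mM U-¹³C glutamine (parallel) | labeling medium |
| glycolysis effect | ×0.75 on glucose uptake | reported fold change |
| TCA entry effect | ×0.81 on citrate synthase | reported 19% reduction |
| OGDHC effect | ×0.64 | reported 36% reduction |
| GABA shunt | ×1.5 | partial compensation (no printed value) |
| reductive IDH exchange | ×2.0 | increased reductive routing |
| respiration effect | ×0.77 on ATP-linked and maximal OCR | reported ATP fold |
| MID noise | σ = 0.01 mole fraction, truncated at 0, renormalized | conventional GC-MS figure |
| concentration noise | 0.02 mM on medium concentrations | analyzer precision |
| patient heterogeneity | lognormal scale, SD 0.05, per free flux | replicate < patient variation |
| clinical correlation | ρ(ΔH&Y) = −0.93, ρ(ΔUPDRS III) = −0.89, ρ(ΔADL) = +0.95, ρ(ΔL-Dopa) = −0.80 | reported correlations |

The sPD condition's flux map is derived from the Ctrl map by applying the
effect multipliers to the free fluxes and re-solving steady state; the
glutamate→AKG net flux then inverts as a consequence (net carbon efflux from
the cycle feeding the GABA shunt), not by construction. Patient-level maps
multiply each free flux by an independent lognormal factor. Clinical deltas
are linear transforms of the (standardized) true per-patient OGDHC flux plus
Gaussian noise calibrated so the expected Pearson correlation equals ρ; at
ρ = ±1 the sample correlation is exactly ±1. One sPD donor is emitted without
follow-up, mirroring the study's lost-to-follow-up case.

What the generator does *not* emulate: fragment-specific derivatization
artifacts, drift/batch structure, non-stationary labeling kinetics, clone
nesting deeper than one clone per donor (the keys exist; the default design
uses one), or realistic omics blocks (the stratification step uses generic
condition-shifted Gaussian blocks). Passing tests therefore validate the
computational pipeline under a clean measurement model, not instrument-level
robustness.

## Measurement model and flux estimation

A reported MID fraction is the true fraction plus Gaussian noise *truncated
below at zero* (the literal reading of truncated-Gaussian noise; it keeps
reported fractions nonnegative without an atom at zero), after which the
vector is renormalized to sum 1. Two consequences shape the estimator:

1. **Closure**: residuals of a MID vector sum to zero exactly — each vector
   carries m−1 independent residuals, and the noise is correlated within the
   vector.
2. **Truncation bias**: fractions within ~2σ of zero are reported with an
   upward bias, and the renormalization spreads the compensating bias across
   the vector.

A diagonal 1/σ² weighting is therefore mis-calibrated (its SSR is not
χ²-distributed). The fit instead compares the data to the *expected
measurement* of the simulated MID (truncated-normal mean, renormalized) and
whitens each vector's residual with the covariance of the truncation+closure
measurement model, estimated by Monte Carlo (4000 draws, fixed internal seed)
at a de-biased plug-in for the true fractions. After the first optimum is
found, the whitening is rebuilt once at the model prediction and the fit is
re-polished (one IRLS step), so the final weights do not adapt to the
realized noise. The reported σ is floored at 0.003 mole fraction per
measurement before weighting; pooled replicate means carry the per-measurement
σ for the bias model and σ/√n for the weighting.

Fitting itself is bound-constrained nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) from ≥5 seeded
random feasible starts (2 for the internal Monte-Carlo studies, where the
restart-to-restart agreement of the optimum was first verified; occasional
bad basins are caught by keeping the best restart). Steady state is exact by
construction: a spanning subset of net fluxes (glucose uptake, PDH, OGDHC,
glutamate secretion, GABA shunt, succinate dilution) acts as free
coordinates and the remaining net fluxes follow affinely; exchange fluxes are
optimized as log₁₀ on [10⁻⁴, 10⁴]; bounds of dependent fluxes enter as a
soft hinge penalty that is inactive at any feasible optimum. Both tracers are
fitted jointly; measured exchange rates enter the residual with their SDs
(floored at 10⁻⁶); biomass effluxes are fixed, not fitted.

Degrees of freedom use a redundancy analysis: the rank of the residual
Jacobian at the optimum (relative threshold 10⁻⁶) counts the *effective*
parameters, excluding structurally flat directions — on the TCA-toy, the
fumarase exchange between the two symmetric pools is invisible and absorbs no
degree of freedom. Goodness of fit is a one-sided upper-tail χ² test of the
SSR at these dof. The χ² reference is an asymptotic-regularity result;
weakly identified, saturating exchange parameters absorb slightly less than
one degree of freedom each, so the SSR null is approximate at the level of
1–2 SSR units — visible only across hundreds of replicate fits.

Confidence intervals come from parameter continuation: the target flux is
stepped away from its optimum (fixed exactly, not penalized, when it is a
free coordinate) while all other parameters are re-optimized warm-started;
the 95% bound is where the profiled SSR crosses SSR_min + 3.84, located by a
curvature-guided first jump and secant refinement to ~10⁻³ of the flux scale.
Directions that never cross within 10× the flux scale are reported open
(non-identifiable), and such fluxes are flagged not-reliably-determined in
condition comparisons.

Internal calibration studies (see `tests/test_acceptance.py`) use
replicate-pooled datasets — the same estimator the pipeline applies to real
cohort tables — at the default noise σ = 0.01: 200 datasets for CI coverage,
500 for the SSR-distribution check, 50 seeded cohorts for effect-size
recovery, and 1000 null cohorts for test calibration. These sizes balance
Monte-Carlo error in the checked bands against runtime.

## Other numerical choices

- **Natural-abundance correction** inverts the binomial ¹³C contamination
  matrix (abundance 0.0107) by nonnegative least squares with
  renormalization; only backbone carbons are corrected (derivatization-atom
  correction would need fragment formulas). It is the exact inverse of
  forward contamination on noise-free data.
- **Fractional contribution** defaults to the mass-weighted convention
  Σᵢ i·Mᵢ / n (a fully labeled metabolite scores 1); the labeled-fraction-sum
  convention Σᵢ≥₁ Mᵢ / n remains selectable (`mode="as_stated"`) for literal
  reproduction.
- **Ratio diagnostics** are tracer-specific (M4/M2 citrate under glucose;
  M3/M5 glutamate, M5 citrate/M5 glutamate, M4 succinate/M5 AKG under
  glutamine); zero denominators propagate as missing and are excluded
  pairwise. Under the default conditions the noise-free OGDHC ratio falls in
  sPD and the reductive ratio rises; the citrate cycling ratio *rises* in
  sPD because anaplerosis and reductive exchange gain share relative to PDH —
  ratio diagnostics report routing, not throughput.
- **Group comparison of replicate-level values** fits a linear mixed model
  with a fixed condition effect and a random intercept per patient (the
  nesting unit the generator induces), Wald χ² on the fixed effect; when the
  random-intercept variance collapses to the boundary the comparison falls
  back to a two-sample t-test on patient means, flagged in the result.
- **Cohort conventions**: clone means within (patient, replicate), then
  replicate means, give one value per individual; two-group tests dispatch
  t-test vs Mann-Whitney on per-group Shapiro-Wilk at α = 0.05 (the dispatch
  rule's normality test is a choice); multi-group comparisons use one-way
  ANOVA with Šidák-adjusted planned contrasts 1−(1−p)ᵐ; multiplicity across
  features uses Benjamini-Hochberg uniformly.
- **Stress-test reduction**: basal/leak/maximal are segment means (before
  port A; after A; after B) minus non-mitochondrial OCR (mean of the last two
  points after rotenone/antimycin; one point for DA-neuron traces), divided
  by mg DNA; negative corrected basal respiration is flagged, never clipped.
  mitoATP = (basal − leak) × 2 × P/O with P/O = 2.75.
- **Multiple-factor analysis**: active blocks are column-standardized
  (population SD; a constant column is an error naming the variable), scaled
  by their first singular value, and concatenated for a global SVD.
  Eigenvalues are squared singular values, so one active block gives exactly
  λ₁ = 1 and a duplicated block exactly 2. Supplementary groups are projected
  (categorical ones as coordinate barycenters with per-level covariance, the
  numerical form of a confidence ellipse) and contribute nothing to the axes.
  Reported percent variance counts active blocks only.
- **Progression correlogram**: pairwise-complete Pearson correlations of
  per-patient features with clinical deltas, two-sided p, flagged at p < 0.1;
  cells with fewer than 3 complete pairs are marked not computable.

## Known limitations

- The stationary EMU model treats a 24 h labeling window as isotopic steady
  state; unlabeled-dilution inflows absorb the leading deviation but true
  non-stationary kinetics are out of scope.
- The SSR χ² null and CI coverage are exact only under regularity; partially
  identifiable exchange fluxes make both slightly approximate (quantified in
  the calibration tests).
- Per-patient flux fits at 3 replicates carry estimation error comparable to
  the 5% patient-level flux spread, so patient-resolved flux-vs-clinical
  correlations are strongly attenuated at n = 6; the acceptance script
  reports both the fitted-flux and true-flux versions of that correlation.
- The network is deliberately minimal (identifiability over completeness);
  it is a test harness for the method, not a curated genome-scale model.
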