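# Methods

## The assay and its data

`hepatoclear` analyses substrate-depletion experiments in pooled primary
human hepatocyte suspensions.  A chemical is incubated at a test
concentration C_test (1 µM by default) with ~0.5 × 10⁶ viable cells/mL, and
triplicate samples are drawn over a 0–240 min window.  Each sample yields a
mass-spectrometric response — a peak area, or peak-area ratio to an
isotope-labelled internal standard — for the parent compound.  Matched
negative controls (medium only, or heat-inactivated hepatocytes) isolate
non-metabolic ("abiotic") loss such as hydrolysis or volatilisation, and
external calibration standards at known nominal concentrations tie response
to concentration.  Responses below the limit of quantitation (LOQ) are
left-censored, not missing.

All internal concentrations are µM and times are minutes; molecular weight
enters only at the IVIVE boundary.

## Point estimation

Under first-order kinetics the parent concentration is
C(t) = C_test · e^(−kt), so ln C is linear in t with slope −k.  The point
pipeline is:

1. **Calibration.** Zero-intercept least squares of calibration responses on
   nominal concentration gives the response factor RF = Σxy/Σx²
   (maximum-likelihood for a proportional response with homoscedastic error
   through the origin).  The residual sd is reported on the log scale to
   match the multiplicative error model used in the Bayesian stage.
2. **Quantification.** conc = response / RF; values below the LOQ are
   flagged censored and retained.  Censored values are *excluded* from the
   frequentist regression — ordinary least squares has no censoring
   mechanism; only the Bayesian model treats them properly.  This asymmetry
   is deliberate and documented.
3. **Regression.** OLS of ln(conc) on time.  Natural logs are used (the
   slope is then the first-order rate constant directly).  A perfectly flat
   series is returned as slope 0 with p = 1 rather than as a 0/0 t-statistic.
4. **Gate and conversion.** A chemical is called cleared when the slope is
   negative and the directional (one-sided, depletion) p-value is below
   α = 0.05; otherwise Cl_int = 0.  The directional gate gives a 5%
   false-positive rate on stable chemicals, which is what the α = 0.05
   convention is meant to deliver; gating on the two-sided p-value *and* a
   negative slope would halve that to 2.5%.  The two-sided p-value is always
   reported, and the tail is configurable.  For significant chemicals,
   t½ = ln 2 / k and Cl_int = k × 1000/density µL/min/10⁶ cells — the volume
   of incubation medium per million cells in suspension is 1000/density µL,
   so at 0.5 × 10⁶ cells/mL, Cl_int = k × 2000.
5. **Abiotic assessment.** The same regression on the pooled control rows;
   the headline Cl_int reports *total* depletion with controls assessed
   separately, while `clint_corrected` = max(0, k_cells − k_abiotic) ×
   1000/density is emitted alongside.

`ClintEstimate.clint_raw` is the ungated estimate max(0, −slope)×1000/density.
Recovery studies use it: at Cl_int = 1 under the default noise the gate has
roughly 50% power, so the median *gated* estimate is a degenerate measure of
accuracy, while the continuous estimate is median-unbiased to within Monte
Carlo error.  The gate's own operating characteristic (type-I rate) is
checked separately on flat panels.

Panel summaries count chemicals gated to zero, report the median over
significant chemicals only, and compute percentiles over all chemicals using
linear interpolation between order statistics (configurable).

## Bayesian measurement model

The observed response is modelled as lognormal around RF times the true
concentration:

    y ~ LogNormal(ln(RF · C(t)), σ)
    cells:     C(t) = C_test · exp(−(z_bio k_bio + z_abio k_abio) t)
    controls:  C(t) = C_test · exp(−z_abio k_abio t)
    standards: C    = nominal concentration

Priors: z_bio ~ Bernoulli(0.5) (clearance is a priori a coin flip),
z_abio ~ Bernoulli(0.05) (abiotic degradation is rare), and
k_bio, k_abio ~ Uniform(0, k_max) with k_max = −ln(LOQ/C_test)/t_max — the
steepest decline distinguishable from an immediate drop to the LOQ over the
assay window.  The bound is stated in the literature without a time
normalisation; dividing by t_max is our interpretation that makes it
dimensionally a rate.  ln RF carries a Normal prior with sd 1 centred on a
calibration-based point estimate (weakly informative; empirical centring
makes the k posterior exactly invariant to rescaling all responses), and σ a
half-normal prior with scale 0.3, widened to 1.0 when responses lack an
internal standard (recovery variation cannot be normalised away).  The error
family (lognormal) and the censoring treatment (lognormal CDF at RF·LOQ for
flagged rows) are our documented choices; rows are flagged censored once at
model build using the calibration RF so the likelihood stays continuous in
the sampled RF.

**Sampler.**  Metropolis-within-Gibbs, vectorised across chains: Gaussian
random walks for k_bio and k_abio (bounded by the prior), ln RF and ln σ
(with the Jacobian term), and exact full-conditional flips for the two
indicators.  Step sizes adapt toward ~40% acceptance during burn-in only and
are frozen afterwards, so the retained chain satisfies detailed balance.
When an indicator is off, its rate is refreshed from a *pseudo-prior* — a
truncated normal centred on a crude OLS rate estimate fixed at model build —
and the flip odds carry the prior/pseudo-prior density ratio (Carlin–Chib).
The pseudo-prior cancels from the marginal posterior of the indicators, so
inference is exact, while proposals land in the data-supported rate region
and chains cross between the on/off sub-models freely.  (A refresh from the
flat prior is also exact but mixes so poorly at weak signal that indicator
probabilities are badly underestimated at practical chain lengths; we
verified the pseudo-prior sampler against direct numerical integration of
the RF-marginalised posterior.)

Defaults: 5 chains, 10 000 iterations, 2 000 burn-in, overdispersed starts
(rates stratified over the prior range, RF and σ offset around their prior
centres).  Simulation studies in `hepatoclear.studies` use 2 500/500, which
leaves Monte-Carlo error on indicator probabilities and interval endpoints
well below the effects being measured.  Convergence requires the
Gelman–Rubin PSRF, √(((n−1)/n·W + B/n)/W), to be below 1.1 for every
continuous parameter; chains that are constant to float rounding count as
converged (PSRF 1), constant-but-different chains as divergent (+∞).
A posterior with PSRF ≥ 1.1 is never marked converged.

The Cl_int posterior is summarised by the median and the equal-tailed 95%
interval of the pooled z_bio·k_bio × 1000/density draws; p_cleared is the
posterior mean of z_bio.  Reports call a chemical "metabolised" when
p_cleared > 0.95 — deliberately stricter than the frequentist gate.

**Calibration caveat.**  Equal-tailed credible intervals from this
spike-and-slab model are *not* calibrated frequentist intervals for weak
effects.  At Cl_int = 1 under the default design (≈1.75σ depletion signal)
the posterior often concentrates on z_bio = 0, the 97.5th percentile of the
Cl_int draws then falls below truth, and frequentist coverage is ≈75%; at
Cl_int ≥ 5 coverage is ≈95%.  This is a property of the exact posterior
(confirmed by numerical integration), i.e. the price of the Occam penalty
that also makes the method conservative about declaring clearance.

## IVIVE and reverse dosimetry

Forward chain at a continuous dose rate D (default 1 mg/kg/day):

* f_ub = f_up / R_b (fraction unbound in blood; clipped to 1 with a warning,
  and R_b defaults to 1 when unknown);
* Cl_int,whole = Cl_int × hepatocellularity × liver mass × 60 × 10⁻⁶ L/h;
* Cl_h = Q_h f_ub Cl_int,whole / (Q_h + f_ub Cl_int,whole) — the
  well-stirred liver model with restrictive (unbound-only) clearance, capped
  at hepatic blood flow;
* Cl_renal = GFR × f_ub (passive glomerular filtration);
* C_ss = (D·BW/24) / (Cl_renal + Cl_h) in mg/L, converted to µM by MW.

Default physiological scalars (all overridable via `PhysioParams` or a YAML
config): BW 70 kg, GFR 6.7 L/h, hepatic blood flow 90 L/h, liver 1800 g,
hepatocellularity 110 × 10⁶ cells/g — standard adult human IVIVE values.
Because published steady-state concentrations depend on study-specific
scalars and blood:plasma values that are not always reported, the package
anchors its reference-panel check on the scalar-free identity
AED × C_ss = POD × D rather than on reproducing absolute C_ss from f_up
alone.

The point of departure is the 5th-percentile AC50 (linear-interpolation
quantile, configurable) across bioactivity curves surviving two filters:
fewer than four caution flags and hitcall ≥ 0.9.  No surviving curve means
no POD and no AED — absence is a value, rendered as the literal `NA` in the
combined table.  Reverse dosimetry uses the linearity of C_ss in dose:
AED = POD / C_ss(at unit dose) × D.  Monte-Carlo propagation pairs
intrinsic-clearance posterior draws with fraction-unbound samples,
recomputes C_ss and AED per draw, and reports medians with central 95%
intervals, deterministically per seed.

Steady-state dosimetry is a deliberate simplification: for highly
bioaccumulative chemicals that take years to approach steady state the
C_ss here understates long-run exposure, and no dynamic PBTK simulation or
renal transporter reuptake is attempted.

## Synthetic data

The generator emulates the assay design: grid {0, 15, 30, 60, 120, 240} min
(a plausible instantiation of the 0–240 min window; configurable),
triplicates, C_test 1 µM, density 0.5 × 10⁶ cells/mL, LOQ 0.01 µM, a
5-level calibration series in duplicate, matched controls, multiplicative
lognormal noise (sd 0.1 by default — typical LC-MS replicate scatter).
Cells rows decay at k_bio + k_abio, controls at k_abio.  Panels make
round(fraction_stable × n) chemicals exactly stable (default 35 of 54,
matching the landscape the package targets) and draw the rest's Cl_int from
a lognormal with median 4.5 and log-sd 1.0 truncated at 50 µL/min/10⁶ cells,
spanning the observed spread of PFAS clearance values; 5% of chemicals get
a small abiotic loss (0.002/min).  Everything is deterministic given the
seed, including byte-identical CSV output.

What the generator does *not* emulate: chromatography artifacts, extraction
recovery, matrix effects, run-to-run calibration drift, heteroscedastic
noise, or saturation (Michaelis–Menten) kinetics.  Passing tests therefore
demonstrate correctness of the estimators under the stated measurement
model, not robustness to instrument pathologies.

## Numerical and design choices

* Quantile convention everywhere: linear interpolation between order
  statistics (numpy's default), configurable.
* `category_pivot` never aggregates silently: duplicate (CF2, category)
  cells raise unless an explicit reduction is requested.
* The depletion CSV carries three dataset-level metadata columns
  (`c_test_uM`, `cell_density_millions_per_mL`, `loq_uM`) after the seven
  per-measurement columns so that write→read is the identity; readers fall
  back to defaults when they are absent.
* Degenerate regressions (flat series) return p = 1; degenerate PSRF cases
  follow the conventions above; f_ub > 1 is clipped with a warning; a
  chemical with no elimination pathway (zero total clearance) is an error
  rather than an infinite C_ss.
* Master seeds spawn per-dataset seeds from a single generator stream; all
  derived seeds stay below 2³¹.

## Known limitations

Single-concentration first-order depletion only; no saturation kinetics.
The suspension assay cannot resolve clearances much below ~2 µL/min/10⁶
cells, so "no significant depletion" is a censored statement, not evidence
of zero metabolism.  Credible intervals undercover for weak true effects
(see the calibration caveat).  Steady-state IVIVE understates exposure for
chemicals with multi-year accumulation half-lives.
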