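# hepatoclear

In vitro hepatic clearance analysis for PFAS (and other slowly metabolised
chemicals): substrate-depletion regression to intrinsic clearance, a
Bayesian measurement model that separates metabolic from abiotic loss with
full MCMC uncertainty, and in vitro–in vivo extrapolation (IVIVE) down to
administered equivalent doses.

## Who this is for

Toxicokineticists and computational toxicologists who run hepatocyte
suspension depletion assays and need to turn raw LC-MS time courses into
defensible clearance estimates — including honest statements of "no
measurable clearance" — and then translate in vitro bioactivity screens into
external dose estimates for risk prioritisation.

## The science in brief

A chemical incubated at C_test = 1 µM with pooled primary human hepatocytes
(0.5 × 10⁶ cells/mL) and sampled in triplicate over 0–240 min depletes, under
first-order kinetics, as C(t) = C_test·e^(−kt).  The slope of ln C against
time gives the elimination rate, the half-life t½ = ln 2/k, and the
intrinsic clearance

    Cl_int = k × 1000 / density   [µL/min/10⁶ cells]

with a significance gate (α = 0.05, directional) setting Cl_int = 0 for
chemicals whose depletion cannot be distinguished from noise.  A Bayesian
measurement model works on the raw instrument responses instead:

    y ~ LogNormal(ln(RF·C(t)), σ),
    C(t) = C_test·exp(−(z_bio·k_bio + z_abio·k_abio)·t)   (live cells)
    C(t) = C_test·exp(−z_abio·k_abio·t)                   (negative controls)

with Bernoulli indicators z_bio ~ Bern(0.5), z_abio ~ Bern(0.05), uniform
rate priors on [0, −ln(LOQ/C_test)/t_max], left-censoring at the LOQ, and a
shared response factor RF tied down by calibration standards.  Five MCMC
chains are run and convergence requires the Gelman–Rubin PSRF < 1.1; the
posterior yields P(cleared), the Cl_int median and its 95% credible
interval.  IVIVE then scales Cl_int to the whole liver, applies the
well-stirred liver model and passive renal filtration, computes the
steady-state concentration C_ss at 1 mg/kg/day, and inverts it against a
bioactivity point of departure (5th-percentile AC50 over filtered positive
curves):

    AED = POD / C_ss × 1 mg/kg/day.

See `docs/methods.md` for assumptions, priors, defaults and limitations.

## Worked example

```python
from hepatoclear import (SimulationTruth, clint_to_k, simulate_depletion,
                         estimate_clint, bayes_clint, ChemicalRecord,
                         BioactivityCurve, ivive_pipeline)

# a synthetic chemical with true Cl_int = 5 µL/min/10⁶ cells
truth = SimulationTruth("DEMO", k_bio_true=clint_to_k(5.0),
                        noise_sd_true=0.1, seed=7)
dataset, _ = simulate_depletion(truth)

est = estimate_clint(dataset)
print(f"point:  Cl_int = {est.clint:.2f} uL/min/1e6 cells  "
      f"(t1/2 = {est.half_life_min:.0f} min, p = {est.p_value:.1e})")

post = bayes_clint(dataset, n_iter=4000, n_burn=1000, seed=8)
print(f"bayes:  median = {post.clint_median:.2f}  "
      f"95% CI = ({post.clint_ci95[0]:.2f}, {post.clint_ci95[1]:.2f})  "
      f"p_cleared = {post.p_cleared:.2f}  converged = {post.converged}")

record = ChemicalRecord("DEMO", "demo chemical", mol_wt=300.0, cf2=4,
                        oecd_category="PFSAs", fup=0.0128)
curves = [BioactivityCurve("DEMO", ac50_uM=6.22, hitcall=0.95, n_flags=0)]
res = ivive_pipeline(record, est.clint, curves)
print(f"ivive:  Css = {res.css_uM:.2f} uM at 1 mg/kg/day, "
      f"POD = {res.pod_uM:.2f} uM, AED = {res.aed_mg_per_kg_day:.2f} mg/kg/day")
```

Output:

```
point:  Cl_int = 5.20 uL/min/1e6 cells  (t1/2 = 267 min, p = 5.6e-10)
bayes:  median = 4.84  95% CI = (4.05, 5.61)  p_cleared = 1.00  converged = True
ivive:  Css = 11.19 uM at 1 mg/kg/day, POD = 6.22 uM, AED = 0.56 mg/kg/day
```

The point estimate (5.20) and posterior median (4.84) bracket the true value
of 5; the credible interval quantifies what the triplicate design can
actually resolve.  The chemical reaches a steady-state blood concentration
of 11.2 µM per 1 mg/kg/day of continuous exposure, so an in vitro AC50-based
POD of 6.22 µM corresponds to an external dose of 0.56 mg/kg/day.

The same workflow is available from the shell:

```bash
hepatoclear simulate --n 54 --stable-fraction 0.648 --seed 11 --out sim/
hepatoclear point  --input sim/depletion.csv --out clint_results.csv
hepatoclear bayes  --input sim/depletion.csv --chains 5 --iter 10000 --seed 17
hepatoclear ivive  --chemicals chemicals.csv --clint clint_results.csv \
                   --curves curves.csv
hepatoclear report --indir sim/ --out results/
```

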