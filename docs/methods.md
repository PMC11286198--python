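# Methods

This note documents the models, conventions and numerical choices behind
`beescape`, and what the synthetic-data tests do and do not demonstrate.

## Units and conventions

* Energies are stored internally in calories per *counting unit* and
  reported at patch/landscape level in megacalories (1 Mcal = 10⁶ cal).
* The counting unit is species-specific: a single flower by default, a
  capitulum for Asteraceae, a whole inflorescence for a few species whose
  flowers are not meaningfully countable one by one.  Unit labels travel
  with density and energy values and are checked for agreement when they
  are multiplied; a mismatch is an error, never a silent conversion.
* Areas are m² internally; patch areas are accepted in hectares
  (1 ha = 10⁴ m²).  All interchange is plain CSV (comma or tab separated);
  outputs are written with fixed float formatting so re-runs are
  byte-identical.

## Floral energetics

Nectar energy per counting unit is Σ_s m_s · c_s over the three dominant
nectar sugars, with c_s = ΔH°c,s / MW_s (heat of combustion, kcal/mol,
over molecular weight, g/mol — numerically cal/mg).  The default
thermochemical constants (fructose 675.6/180.16, glucose 669.9/180.16,
sucrose 1349.6/342.30) come from standard combustion tables and are
ordinary config inputs, not measured quantities.  Pollen energy is pollen
mass × a mean calorific content; the default 4.11 cal/mg can be replaced
by the mean of a bomb-calorimetry table (species means first, then an
unweighted grand mean).

Missing sugar or pollen masses are imputed hierarchically: mean of
measured congeners, else mean of measured confamilials, else a configured
literature value, else an error.  Imputation averages **masses**, not
energies, and the tier used is recorded as provenance.  A species with a
partial nectar measurement (some sugars only) treats the unmeasured sugars
as zero mass rather than imputing across species.

The pollen–nectar energy correlation is reported as Pearson r on log10
energies, excluding species scored per inflorescence (their counting unit
makes them incommensurable); a raw-scale option exists.

## Networks and landscape scaling

Site networks are bee × plant matrices of summed interaction events;
the regional metaweb is their cell-wise sum after label alignment, and a
bee's partner set is its positive metaweb row.  Species order is
lexicographic everywhere for determinism.  Bees never observed
interacting are excluded from the metaweb but kept in the modelling grid
with zero energy availability (their partner set is empty, which is
flagged, not an error).

Flower density per land-use class is pooled counts over pooled transect
area; a transect's area counts once however many species were seen on it.
Network plants missing from every transect of a class receive a nominal
density of **half the smallest surveyed density in that class** —
the species occurs regionally but below detection.  Energy per m² for a
bee in a class is Σ over partner plants of density × energy per unit;
patch energy multiplies the woodland value by remnant area, landscape
energy multiplies each matrix class value by its buffer area and sums.
Woodland inside the buffer reuses the remnant density table (no separate
matrix-woodland surveys are assumed).  The ~3% of buffer cover outside
the three modelled classes contributes zero energy.

## The abundance model

Counts y_ij for species i at site j follow an NB2 (variance μ + μ²/θ)
or Poisson GLMM with log link:

    log μ_ij = log(effort_j) + x_ij'β + u_i,   u_i ~ N(0, σ²)

Continuous predictors are mean-centred and divided by **two** standard
deviations (sample sd, ddof = 1), making the output sd exactly 0.5 and
coefficients comparable across continuous and binary inputs.  Interaction
columns are products of the standardized mains and are not
re-standardized.  An optional zero-inflation component is a single
intercept-only logit mixture applied per observation conditional on u.

The marginal likelihood integrates u out by **adaptive Gauss–Hermite
quadrature**: per group, damped Newton locates the integrand mode and
curvature (the integrand is log-concave in u for both families), and the
Hermite rule is centred and scaled there.  One node is exactly the
Laplace approximation; the default is 15 nodes, and 7- vs 25-node fits
agree to < 1e-4 in the coefficients at study scale.  Optimization is
L-BFGS-B on (β, ln σ, ln θ, logit π) with gradient tolerance 1e-8 and
seed-controlled restarts from perturbed starts (default three runs);
starting β comes from a fixed-effects Poisson GLM.  Because the NB2
likelihood is monotone but nearly flat along θ → ∞ when the data are
equi-dispersed, the fit explicitly checks the Poisson-limit boundary
(ln θ = 25) so that NB2 never scores below its nested Poisson special
case; at such θ the log-gamma difference is evaluated as an exact sum of
logs to avoid catastrophic cancellation.  Wald standard errors come from
a central-difference Hessian of the negative marginal log-likelihood.

AICc = AIC + 2k(k+1)/(n−k−1) with n = number of species × site cells and
k counting every estimated parameter (fixed effects + σ + θ + π).
All-subsets selection enumerates the term subsets of the global model
that respect marginality (an interaction requires both mains; 26
candidates for the 4-main/2-interaction global model, intercept-only
included), ranks them by AICc, and calls 'best' the candidate with fewest
parameters within 2 AICc units of the top, ties broken by lower AICc.
Candidates that fail to converge are excluded and flagged.  VIF screening
(mains only, threshold 3.0) runs before selection.

Nakagawa R²: marginal = var(x'β̂) / (var(x'β̂) + σ² + σ²_obs), conditional
adds σ² to the numerator.  The observation-level variance uses the
trigamma method, ψ₁((1/μ̄ + 1/θ)⁻¹) for NB2 and ψ₁(μ̄) for Poisson, with
the lognormal approximation ln(1 + 1/μ̄ + 1/θ) as an option; μ̄ is the
mean marginal expectation exp(offset + x'β̂ + σ²/2) averaged over rows,
and the offset is excluded from var(x'β̂).

Effect translation: capture rate is count per survey hour per cell; the
fitted effect of a predictor is reported as 100 × (predicted rate at its
observed max − at its observed min) / (max − min observed rate), with
other covariates at their means (0 on the standardized scale), the random
effect at 0, and ln mass held at its mean or ±1 sd (±0.5 on the 2-SD
scale).  p-values are Wald and labelled as such.

## The synthetic-data generator

The generator emulates the structure of a fragmented-woodland pollination
study at its default dimensions — 23 sites, 53 bee species, 56 plant
species, three dominant land-use classes (woodland, cleared, pine)
covering 97% of each 1-km buffer — with every parameter explicit:

* per-unit nectar/pollen energies are bivariate log-normal with log-scale
  correlation 0.79; nectar energy is split into three sugar masses by
  Dirichlet shares; ~41% of species lack nectar and ~36% lack pollen
  measurements (at least one measured species per family is kept so
  imputation is always possible);
* flower densities are long-tailed log-normals with class log-means
  chosen to give mean densities near 0.39 / 0.36 / 0.09 m⁻² for
  woodland / cleared / pine and class presence probabilities 1.0 / 0.54 /
  0.32 (mirroring the richness gradient across land uses); 23.2% of
  plants are absent from every transect, exercising the nominal-density
  rule;
* bee specimen lengths are log-normal with a female-biased dimorphism
  gap; true dry masses follow the configured allometry exactly, and
  calibration masses add log-normal residual noise (sd 0.15);
* the metaweb is Bernoulli with link probability increasing in plant
  energy and bee mass; site networks realize metaweb links independently
  and draw per-link event counts;
* abundance counts are NB2 (gamma–Poisson) from the true GLMM
  (β defaults include landscape effect 1.313 and mass × landscape
  interaction 1.235 with null patch effects, σ = 0.5, θ = 2) with
  ln(effort) offsets, effort uniform on 5–10 h.

Crucially, the linear predictor uses covariates computed by the
pipeline's **own** stages on the generated tables (allometry fit on noisy
calibration masses, imputed energetics, realized metaweb, nominal
densities, availability scaling), so the fitted model is exactly
correctly specified with respect to the generator and parameter-recovery
tests are clean tests of the estimator, not of covariate reconstruction.

What the generator does **not** emulate: spatial structure and
autocorrelation, flowering phenology and temporal turnover, detection
error in transects and hand-netting, nectar secretion dynamics, and
non-caloric rewards.  Passing recovery tests therefore demonstrates the
correctness of the estimation machinery under the stated model, not
robustness of the scientific conclusions to violations of it.  One
visible consequence: the pollen–nectar correlation of the *imputed*
resource table (~0.4–0.5) is attenuated relative to the generating 0.79,
because genus/family-mean imputation shrinks both energies toward common
values; the configured correlation is checked on the generator's measured
energies.

## Problem sizes and determinism

A single integer seed drives everything; per-stage RNG substreams are
spawned deterministically so partial re-runs reproduce bit-identically,
and repeated pipeline runs produce byte-identical CSVs.  The replicated
simulation studies use 50 replicates at full study scale (23 × 53 cells
per fit); the recovery study fits the true model with 5 quadrature nodes
and one optimizer start, and the selection study fits its 26 candidates
with the Laplace approximation and one start — settings whose coefficient
differences from the 25-node reference are below 1e-4, as the quadrature
stability test verifies.

## Known limitations

* The random-effects structure is a single scalar intercept; no random
  slopes, no crossed site effects, no spatial covariance.
* Zero-inflation is intercept-only by design; covariate-dependent ZI is
  out of scope.
* The Conway–Maxwell–Poisson family is not implemented; NB2 and Poisson
  (with/without ZI) cover the model set actually selected.
* Model-averaged coefficients are not provided; inference reports the
  most parsimonious model within the AICc window.
* Allometry coefficients must either be supplied or fit from calibration
  masses; no built-in trait database is shipped.
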