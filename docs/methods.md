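# Methods

## Scope and model overview

`stressorweave` implements a spatially explicit Bayesian state-space model of
individual health, survival, calving and somatic growth for a long-lived,
wide-ranging marine population exposed to three interacting stressors —
entanglement in fixed fishing gear, vessel strikes, and variation in prey
availability — together with a forward population-projection tool. The
package is organised around the pathway exposure → health → vital rates →
population dynamics:

1. **Occupancy.** The range is collapsed into a small set of regional
   polygons (seven by default: SEUS, MIDA, SNE, CCB, NEUS, GSL, MAR) and four
   quarterly seasons. An individual's proportional presence `z[t, l]` is a
   simplex over regions. Two formulations are supported: a data-driven
   Dirichlet compositional model on per-individual sighting fractions,
   stratified by demographic class × quarter × era (v1), and a model-based
   version proportional to an external relative-density surface rescaled by
   the class composition of sightings (v2). A non-spatial formulation (v3)
   assigns every individual the population-average distribution. The era
   break (default 2010) captures a documented distribution shift; density
   surfaces are assumed available from 2003, with earlier steps backfilled by
   the 2003–2009 mean and data-poor (Canadian) regions filled by a
   sightings-to-abundance ratio against a reference US region.

2. **Exposure.** Per step, entanglement probability is
   `p_e = ι₁ Σ_l z_l G_l ẽ_l` with `G` the unit-rescaled gear-risk surface and
   `ẽ` a landings-trend multiplier extrapolating risk backward in time
   (ẽ ≡ 1 from 2015 on). Regional strike probability is anchored to the
   vessel-traffic surface in 2019 and extrapolated backward linearly on the
   logit scale, `logit p_r = logit(ι₂·AIS_l) + ṽ(2019 − y)`; an individual's
   strike probability is the occupancy-weighted mean. Experienced prey is the
   occupancy-weighted prey concentration, averaged within a year and
   standardised by the mean and SD over all annual means. Risk surfaces are
   rescaled to [0, 1] by their global maximum, which preserves relative
   spatiotemporal structure; the conversion coefficients carry constrained
   supports so every emitted probability is a probability — out-of-support
   values raise rather than clip.

3. **Health.** Latent health lives on (0, 100] (the scale of the visual-health
   literature) and follows a bounded random walk with deterministic drift.
   A new entanglement of severity s contributes its immediate effect plus
   *one* step of the prolonged gear-carrying effect (the prolonged effect is
   deliberately absent as a separate term in the event step, which breaks the
   confounding between immediate and prolonged effects); carrying gear
   contributes the prolonged effect per step, as a binary state regardless of
   the number of gear sets; strikes contribute by injury class; the prey
   effect enters once per year, in the Jun–Aug step. Combined effects are
   additive on the health scale — each pairing adds γ·prey_std to the
   corresponding main effect — and one hypothesis is active per fitted model.
   Positive coefficients mean improved health. Increment densities are
   truncated Gaussians on [floor, 100] with floor 0.01; the simulator clamps,
   which coincides with the truncated density everywhere except exactly at
   the boundary (immaterial at the fitted scales).

4. **Vital rates.** Survival is written in hazard form,
   `λ(h) = exp(a_s − b_s h)`, `ϑ = exp(−λ)` per quarter — exactly the
   complementary log-log link, stated through the hazard so the projection
   tool reuses the identical λ; annual hazards sum over quarters. Calving for
   available adult females is logistic in mean health over the gestation
   (previous) year and length at the start of the calving year, centred at
   h_ref = 70 and L_ref = 13 m. Availability requires maturity (default 9
   years) and at least two full calendar years since the last calving.

5. **Growth.** Length follows a von-Bertalanffy-type curve
   `L(a) = A_i − (A_i − L0)e^{−k a}` with shared k and L0 and individual
   asymptotes `A_i ~ Normal(A₀ + trend·(birth_year − 1980) + Xβ_A, σ_A)`
   truncated above L0. Asymptote covariates implement the length-level
   combined-effect hypotheses (early-life prey/entanglement windows of 15,
   10, 5, 2 or 1 years; maternal health and entanglement during lactation).
   The covariates act on the asymptote, matching the "reduced asymptotic
   length" interpretation; males' lengths are modelled too since they inform
   the population trend.

6. **Observation.** Sightings are Bernoulli with detection probability
   varying by region × quarter (not by individual), weighted by occupancy;
   ordinal visual-health scores use monotone cutpoints on the health scale
   with per-variable noise (four variables × three categories by default);
   photogrammetric lengths are Gaussian with platform-specific SDs (occupied
   aircraft 0.25 m, drone 0.10 m); carcasses are recovered with fixed
   probability, making unrecovered deaths cryptic.

7. **Cryptic mortality.** Each unrecovered individual carries latent
   discrete states over a post-last-sighting tail window (8 quarterly steps by
   default): a death step τ, at most one unobserved terminal entanglement and
   one unobserved terminal strike. These are sampled within the MCMC: the
   death-step conditional combines the hazard along the current health
   trajectory with the evidence of not being sighted while alive; the
   terminal-event conditionals combine per-step exposure probabilities, the
   categorical severity/injury priors, and the health increments of the tail
   (an imputed entanglement carries gear to the end of the tail). Without
   these latents, censoring at the last sighting removes exactly the
   low-health exposure steps that precede unobserved deaths and biases the
   survival slope upward — the tail machinery removes that bias. A standalone
   prior-predictive imputation operation with an exposure-weighted event-time
   distribution is also provided for dataset augmentation outside the MCMC.

## Inference

The joint posterior is sampled with a purpose-built Metropolis-within-Gibbs
engine (no gradient-based probabilistic-programming engine is used; the
model's discrete latents and bounded latent field make a structured Gibbs
scheme the natural fit):

* **Health field** — single-site updates in a four-colour schedule (t mod 4).
  Sites four steps apart are conditionally independent given their
  neighbours, and the four steps of a year never update together, which keeps
  the annual calving coupling exact. Each site proposes from the truncated
  Gaussian implied by its neighbouring increments (or the initial-health
  prior at the left edge) and accepts on the local observation terms
  (ordinal scores, survival/death, calving through the annual mean) plus the
  truncation-normaliser correction of the outgoing increment.
* **Asymptotes** — conjugate Gaussian proposals given length measurements
  and the population prior (length is linear in A_i), accepted on the
  calving-length term.
* **Discrete latents** — terminal events and death steps by exact enumeration
  of their finite supports, every sweep. Terminal events enter the drift
  through the same design columns as observed events, so parameter updates
  see them consistently.
* **Scalar parameters** — component-wise adaptive random-walk Metropolis
  (Robbins–Monro adaptation toward 0.44 acceptance during warmup), each
  parameter evaluating only the likelihood components it enters. Sign
  constraints (adverse main effects ≤ 0, b_s ≥ 0, c₂ ≥ 0) are enforced by
  the prior support; interaction coefficients are unconstrained.

Occupancy enters as a plug-in (stratum means for v1), and prey
standardisation constants are recomputed from the data being fitted; both
choices mirror how the exposure covariates would be constructed for real
data and introduce a realistic errors-in-variables attenuation in
interaction coefficients. Convergence is summarised by split-R̂ and bulk ESS
(arviz); a run with any monitored R̂ > 1.1 is flagged non-converged in its
metadata.

Priors are weakly informative: Normal(0, 15²) truncated ≤ 0 for adverse
health effects, Normal(0, 5²) for prey and interaction coefficients,
Normal(0, 0.2²) on the survival slope's positive half-line, Normal(13, 3²)
for the asymptote intercept, half-ranges wide enough that the data dominate
at the fitted scales. Conversion coefficients ι₁, ι₂ are uniform on supports
chosen so all probabilities stay in [0, 1].

## Synthetic data

The generator forward-simulates the full generative model and is the study
condition for every recovery experiment. Defaults: 3 regions × 30 years
(1990–2019, era break 2010) × 40 founding individuals plus births (~145
individuals over the period); seasonal surfaces with entanglement risk
elevated in northern regions, vessel traffic elevated in the south, prey
peaking in the northern summer with a 30 % post-2010 decline in northern
regions and lognormal inter-annual noise; true occupancy drawn from
class × quarter × era Dirichlet concentrations with a post-2010 northward
shift. Health effects (on the 0–100 scale): severities −2/−8/−15, gear
−2 per quarter, strikes −2/−6/−15/−20, prey +3 per SD, gear × prey
interaction +1.5; survival a_s = −1.5, b_s = 0.05 (quarterly survival
≈ 0.996 at health 80); calving c₀ = −1.2, c₁ = 0.04, c₂ = 0.8; growth
A₀ = 13.5 m, k = 0.3 yr⁻¹, L0 = 4.5 m, σ_A = 0.5 m, birth-year trend
−0.03 m yr⁻¹, maternal-entanglement effect −0.4 m. Observation: detection
0.45 per quarter, visual scores on 70 % of sightings, lengths on 8 %,
carcass recovery 0.4, event detection 0.85 (entanglement) and 0.6 (strike).
These values are chosen to be biologically plausible for a small, heavily
monitored baleen-whale population; they are set once and used unchanged by
tests and the acceptance script.

What the generator deliberately does not emulate: heterogeneous survey
effort (detection varies by region/quarter but sightings are otherwise
missing at random), mid-life cryptic events (all pre-disappearance events
are detectable at the stated rates), within-region habitat structure, and
gear-configuration detail. Passing recovery tests therefore show the
estimator is consistent with its own generative assumptions at desk scale —
not that those assumptions hold in any real monitoring programme.

## Projection

The projector runs annually. Health follows a mean-reverting AR(1) anchored
at the uninjured-health mean (ρ = 0.7 by default) instead of the fitted
random walk, which has no mechanism to constrain its forward trend; stressor
insults (annual entanglement/strike events with class-specific effects, gear
cost scaled by an expected carrying duration) and a prey-regime term are
superimposed. Survival uses the identical hazard λ summed over four
quarters; calving uses the fitted health + length model; newborn asymptotes
follow the scenario's length regime (decline at the current rate to a 10 m
floor, stabilise at ~11.8 m, or recover toward ~14.0 m). The demonstration
grid is {100 %, 50 %, 0 % entanglement risk} × {historical, low prey} ×
{decline, stabilise, recover}; vessel-strike reduction exists as a lever but
is outside the default grid. Parameter uncertainty propagates by running one
trajectory per parameter draw (1000 by default). Every result carries a
demonstration-grade flag: projections inherit all the retrospective model's
assumptions and are not management advice.

## Numerical choices and problem sizes

* Time steps are 0-based internally; Dec–Feb belongs to the year containing
  January; the "previous two years" event window is 8 quarterly steps with an
  inclusive boundary.
* Missing surface cells are filled by region-season climatology, recorded in
  the result's metadata; a cell with no observed year in its region-season
  is an error.
* Dirichlet fitting uses the digamma fixed-point maximum-likelihood
  iteration with moment-matching initialisation; sighting compositions use
  additive smoothing (+0.5 per region) because true zero presence is not
  identifiable from sparse sightings; a zero-variance stratum falls back to
  a concentrated vector at its mean composition, and unfitted strata to the
  symmetric prior α = 1.
* Desk-scale experiment sizes: recovery experiments use the generator's
  default conditions with 1000 MCMC sweeps (350 warmup) per fit and 10
  replicates in the test suite (5 in the acceptance script); projection
  checks use 100–1000 draws over 10–50-year horizons. These sizes keep a
  full run on one CPU in the tens of minutes while leaving the Monte-Carlo
  error well inside the asserted tolerances.

## Known limitations

* Only detected events enter the event-rate likelihood before the last
  sighting, so the conversion coefficients ι₁, ι₂ are attenuated by the event
  detection probability; interaction and vital-rate estimates are not
  affected by this thinning in any way the recovery experiments detect.
* Plug-in occupancy (rather than sampling z inside the chain) attenuates
  prey-mediated coefficients slightly; the sign-recovery experiments remain
  comfortably calibrated.
* Health-derived length covariates (the prolonged-health windows) are built
  from a score-anchored plug-in health trajectory rather than resampled with
  the latent field, another plug-in approximation alongside occupancy.
* Whales never sighted at all are absent from the fitted data, a mild
  survivorship selection on the earliest life stage.
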