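# stressorweave

Combined effects of multiple stressors on a long-lived, wide-ranging
population, estimated through a spatially explicit Bayesian state-space model
of individual health, survival, calving and somatic growth — with a
synthetic-data generator for recovery experiments and a scenario-based
population-projection tool.

The package targets the situation of the critically endangered North Atlantic
right whale (*Eubalaena glacialis*): a small, heavily monitored population
threatened simultaneously by entanglement in fixed fishing gear, vessel
strikes and climate-driven changes in prey availability, where the question
is not whether each stressor harms individuals but how their effects
*combine* along the pathway exposure → health → vital rates → population
dynamics.

## The model

Space is collapsed into a few regional polygons and four quarterly seasons.
An individual's occupancy `z_{t,i,l}` (the proportion of step *t* spent in
region *l*) comes from a Dirichlet compositional model of sighting fractions
(formulation v1), from an external relative-density surface (v2), or is
population-wide (non-spatial v3). Occupancy converts the stressor surfaces
into individual exposure:

    p^e_{i,t} = ι₁ Σ_l z_{t,i,l} G_{l,t} ẽ_{l,t}                (entanglement)
    logit p^r_{l,t} = logit(ι₂ AIS_{l,t}) + ṽ (2019 − y_t)      (strike, by region)
    p^v_{i,t} = Σ_l z_{t,i,l} p^r_{l,t}
    prey′_{i,t} = Σ_l z_{t,i,l} prey_{l,t}

Latent health `h_{i,t} ∈ (0, 100]` is a bounded random walk whose drift
collects intrinsic costs (weaning, lactation), event effects (entanglement by
severity plus a prolonged gear-carrying cost, strikes by injury class),
a standardised annual prey effect, and one active combined-effect term
(e.g. gear × prey: the cost of carrying gear worsens when prey is scarce).
Health drives survival through a hazard, `λ = exp(a_s − b_s h)`,
`ϑ = exp(−λ)` — the complementary log-log link written so the projection
tool reuses the identical hazard — and, with length from a von-Bertalanffy
growth curve, drives annual calving through a logistic model. Observations
(sightings, ordinal visual-health scores, photogrammetric lengths, event
records, carcasses) connect the latent states to data; unrecovered whales
carry latent death times and up to one unobserved terminal entanglement and
strike after their last sighting, capturing cryptic mortality.

Inference is Metropolis-within-Gibbs: a four-colour single-site scheme for
the health field, conjugate proposals for individual length asymptotes,
exact enumeration for the discrete cryptic-death latents, and adaptive
random-walk Metropolis for scalar parameters. Combined effects are reported
the way practitioners read them: posterior median, 95 % credible interval,
sign, and whether the interval overlaps zero.

The projection tool (`stressorweave.pva`) carries the estimates forward 100
years under scenarios crossing entanglement-risk reduction (0/50/100 %),
prey regime (historical vs persistently low) and the trend in asymptotic
length (decline to 10 m, stabilise at ~11.8 m, recover toward ~14 m),
propagating parameter uncertainty with one trajectory per posterior draw.
Projections are demonstration-grade by construction and flagged as such.

## Worked example

```python
import numpy as np
from stressorweave import SimulationConfig, generate_dataset
from stressorweave.inference import (ModelSpec, build_joint_model,
                                     GibbsSampler, summarize_parameters)

config = SimulationConfig()            # 3 regions x 30 years, gear x prey = +1.5
data = generate_dataset(config, seed=1)
print(len(data["records"]), "individuals,",
      len(data["observations"].sightings), "sightings,",
      len(data["observations"].entanglements), "observed entanglements")

spec = ModelSpec(formulation="v1", hypothesis="health:gear_prey")
model = build_joint_model(spec, data["records"], data["observations"],
                          data["surfaces"], config.frame)
draws = GibbsSampler(model, seed=2).run(1000, 350)
table = summarize_parameters(draws, ["gamma_gear_prey", "b_s", "k", "A0"])
print(table.round(3).to_string(index=False))
```

Output:

```
120 individuals, 3277 sightings, 183 observed entanglements
      parameter  median  ci_low  ci_high  sign  ci_overlaps_zero
gamma_gear_prey   0.787   0.377    1.099     1             False
            b_s   0.055   0.037    0.075     1             False
              k   0.302   0.292    0.313     1             False
             A0  13.513  13.353   13.638     1             False
```

The gear × prey interaction is recovered with the correct (positive) sign —
poorer prey conditions worsen the per-step cost of carrying gear — and the
survival slope, growth rate and asymptote intercept bracket their generating
values (0.05, 0.3, 13.5). The interval on the interaction sits below the
generating value of 1.5, the documented attenuation from plug-in occupancy
and imperfect event detection.

A thin CLI exposes the pipeline stages (`stressorweave simulate`,
`validate-data`, `occupancy`, `exposure`, `fit`, `project`); every stage is
byte-deterministic given its seed.

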