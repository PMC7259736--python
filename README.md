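# nutcracker-occupancy

Hierarchical Bayesian site-occupancy modelling for Clark's nutcracker
(*Nucifraga columbiana*) habitat-use surveys, built around the survey
design used in the southern Greater Yellowstone Ecosystem: repeated
point counts (three sequential ten-minute counts per visit) at random
sites across five stages of the nutcracker annual cycle — breeding, early
summer, late summer, fall seed harvest and post-harvest — scored at two
detection radii (≤100 m and unlimited).

The package is aimed at quantitative ecologists and whitebark pine
(*Pinus albicaulis*) managers who need occurrence estimates that are
corrected for imperfect detection and tied to habitat covariates: cone
crop density, stand importance values from point-quarter sampling, and
landscape areas of whitebark pine (within 32.6 km, the maximum known
seed-harvest flight) and Douglas-fir (within 3.2 km, the median breeding
home-range diameter).

## Model

Each survey unit *i* (one site × stage × year detection history
*h<sub>i</sub>* ∈ {0,1}³) has a latent use state and conditional
detections,

```
z_i  ~ Bernoulli(ψ_i)
h_it ~ Bernoulli(z_i · p_i),   t = 1, 2, 3

logit ψ_i = α_s(i) + u_site(i) + Σ_j I_{j,s(i)} β_{j,i} x_{ij}
logit p_i = μ_p + ε_{y(i),s(i)} + η_i
```

with site effects *u* ~ N(0, σ²_site), year-stage detection effects *ε*
around a single hyper-mean μ_p, an observation-level effect *η* per
survey unit, and optionally year-varying coefficients
β<sub>j,s,y</sub> ~ N(μ<sub>j,s</sub>, σ²_j). Because cone density and
importance values are extremely zero-inflated, each enters as a paired
binary (absent) + continuous (z-scored positive part) term that is
selected in or out of the model as a unit.

Covariate structure is chosen by **cross-product Bayesian model
selection**: a latent categorical indicator I<sub>s</sub> picks among an
enumerated per-stage candidate model set each MCMC iteration; its
posterior frequencies are the model probabilities, and summarizing a
coefficient over only the draws in which its term is included yields
model-averaged ("conditional") estimates. A global screening phase uses
independent Bernoulli(0.5) inclusion indicators per covariate and drops
any term whose posterior inclusion probability is ≤ 0.5 (the
median-probability-model rule). Fit is checked with a Bayesian
MacKenzie–Bailey test: the detection-history chi-square discrepancy is
compared between the observed data and posterior-predictive replicates,
and the model is adequate when the 95% credible interval of
T<sub>rep</sub> − T<sub>obs</sub> includes 0.

Everything is sampled by a seeded Metropolis-within-Gibbs sampler
(explicit data augmentation for *z*, adaptive random-walk updates frozen
after burn-in, prior-as-pseudoprior moves for coefficients excluded from
the current model), so identical seeds give bitwise-identical chains.

The package also ships the field-metric calculators (belt-transect area,
cone density per hectare, Cottam–Curtis point-quarter density / frequency
/ basal area / importance value), occurrence-prediction curves with
habitat-area thresholds, the two previously published cone-crop
comparator models (a linear and a beta regression on the squared-log
cone-production index) with Spearman / one-tailed Wilcoxon comparison
machinery, and a seeded synthetic-data generator that emulates the whole
survey design with known ground truth.

## Worked example

Simulate a two-stage, two-year survey with known truth (cone presence
drives late-summer use; cone presence plus whitebark landscape area
drives fall-harvest use), fit with cross-product selection, check fit,
and extract a management threshold:

```python
import numpy as np
from nutcracker_occupancy import (
    MCMCSettings, SimScenario, build_occupancy_data, final_candidate_sets,
    generate_detections, posterior_predictive_gof, predict_psi, run_mcmc,
    summarize_selection, threshold_area,
)

scenario = SimScenario(
    n_sites=150, years=(2012, 2013), stages=("late_summer", "fall_harvest"),
    coef={
        "fall_harvest": {"cone_density_absent": -2.0, "wbp_landscape_area": 0.9},
        "late_summer": {"cone_density_absent": -1.5},
    },
    sigma_site=0.5, sigma_p=0.4, sigma_obs=0.3, seed=7,
)
sim = generate_detections(
    scenario,
    true_model={"fall_harvest": ["cone_density", "wbp_landscape_area"],
                "late_summer": ["cone_density"]},
)
data = build_occupancy_data(sim.units, sim.design)

draws = run_mcmc(
    data,
    MCMCSettings(n_chains=3, n_iter=3000, n_burnin=1000, seed=1),
    selection=final_candidate_sets(data.stage_names),
)

summary = summarize_selection(draws)
print(summary.model_probabilities.round(2).to_string())

gof = posterior_predictive_gof(draws, data, seed=1)
print(f"GOF: 95% BCI of T_rep - T_obs = "
      f"({gof.d_lower95:.2f}, {gof.d_upper95:.2f})")

curve = predict_psi(draws, "fall_harvest", "wbp_landscape_area")
print(f"75% threshold: {threshold_area(curve, 0.75):,.0f} ha")
```

Output:

```
               M1    M2   M3    M5
late_summer   0.0  0.93  0.0  0.07
fall_harvest  0.0  0.00  0.0  1.00
GOF: 95% BCI of T_rep - T_obs = (-9.86, 25.07)
75% threshold: 33,633 ha
```

The indicator chain concentrates on the data-generating model in each
stage (M2 = cone pair only; M5 = cone pair + whitebark landscape area),
the posterior-predictive interval includes 0 so the fitted model is
consistent with its own data, and the mean prediction curve crosses 75%
occurrence at ≈34,000 ha of whitebark pine habitat within 32.6 km —
the kind of landscape-composition target the analysis is designed to
produce for managers.

A command-line interface wraps the same pipeline:
`nutcracker-occupancy simulate | fit | gof | predict | compare`
(see `--help` on each subcommand).

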