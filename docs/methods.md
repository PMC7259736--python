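# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices inside the sampler, and the design decisions taken
where more than one reasonable convention exists.

## The occupancy model

One survey unit is a detection history: three sequential ten-minute
counts at one site, in one stage of the Clark's nutcracker annual cycle,
in one year, at one detection radius. The model is a single-season
site-occupancy model with imperfect detection,

- `z_i ~ Bernoulli(ψ_i)` — latent use state. Because nutcracker home
  ranges are large relative to a point count, "occupancy" is read as
  *use* of the area around the point, and detection as "available and
  detected".
- `h_it | z_i ~ Bernoulli(z_i p_i)` — three conditionally independent
  counts sharing one per-unit detection probability.

Occurrence: `logit ψ_i = α_s + u_site + Σ_j I_{j,s} β_{j,i} x_{ij}` with
stage intercepts α_s, site effects `u ~ N(0, σ²_site)` (sites are
revisited across years and stages), and standardized covariates.
Detection: `logit p_i = μ_p + ε_{ys} + η_i` with year-stage effects
`ε ~ N(0, σ²_p)` around a single hyper-mean and an observation-level
effect `η ~ N(0, σ²_obs)` that absorbs unit-level extra-binomial
variation. The observation effect attaches to the survey unit, not to
each ten-minute count: its purpose is to soak up unit-level lack of fit,
and a per-count version would be unidentifiable from three binary
outcomes. No detection covariates are included by default (they are
screenable by the same machinery as occurrence covariates).

With several years of data, coefficients can vary by year around
covariate- and stage-specific hyper-means (`β_{j,s,y} ~ N(μ_{j,s},
σ²_j)`); with one year, or when `ModelConfig.year_varying_coefficients`
is off, the stage-level mean is used directly. Each random-effect layer
can be disabled independently, which fixes its sd at zero — simulated
single-stage datasets are fitted with all layers off.

### Zero-inflated covariates

Cone density and the importance values are mostly zero across sites, so
each enters as a *pair*: a binary term coded 1 where the resource is
absent, plus the z-score of the strictly positive values, set to 0 at
absent sites. The pair is selected in or out of a model as one unit
("each form only appears if the other does"). This lets the occurrence
intercept shift with presence/absence while the magnitude slope acts
only where the resource exists, and it is why the reported binary
coefficients are negative when presence raises occurrence (absent = 1).
Plain continuous covariates (landscape areas, tree density) are z-scored
with the sample (n−1) standard deviation.

## Priors

- Logit-scale intercepts (α_s) and the detection hyper-mean μ_p:
  Normal(0, 10²) — effectively flat over the plausible probability range.
- Covariate coefficient (hyper-)means: Normal(0, 2.5²). Covariates are
  standardized, so ±5 on the logit scale per sd of the covariate already
  spans any realistic effect. A much wider coefficient prior would both
  distort model selection (the Bayes-factor penalty for an extra term
  grows with the prior width, pushing all posterior mass to the smallest
  models) and cripple between-model mixing, because excluded
  coefficients evolve under this prior and must propose credible values
  when a model move switches them on.
- All standard deviations: Uniform(0, 10) on the sd scale.

Sensitivity to these diffuse choices should be checked when the exact
original prior specification matters; the calibration suites in
`tests/test_acceptance.py` verify interval coverage under these priors.

## Sampling

A Metropolis-within-Gibbs sampler with explicit data augmentation:

- `z_i` is drawn from its Bernoulli full conditional (`z_i = 1` whenever
  any count detected; otherwise posterior odds `ψ(1−p)³ : (1−ψ)`).
  Sampling `z` explicitly makes every other update a Bernoulli-GLM
  conditional and makes the model-indicator full conditional a cheap
  categorical draw. The marginal (z-integrated) unit likelihood is kept
  separately for oracle tests and the goodness-of-fit statistic.
- Location parameters use random-walk Metropolis with per-block proposal
  scales adapted toward 44% acceptance in batches of 50 iterations
  during burn-in only, then frozen (preserving detailed balance).
  Disjoint blocks (site effects, year-stage cells, observation effects)
  are updated as vectorized independent Metropolis moves.
- Standard deviations are updated by random-walk on the log scale with
  the Jacobian correction, against their Uniform(0, 10) support.
- Hyper-means of year-varying coefficients use the conjugate
  normal-normal Gibbs update.

Default chain geometry is desk-scale — 3 chains × 4,000 iterations with
1,000 burn-in — which the calibration studies show is sufficient for the
simulated problem sizes (300 units, a few covariates);
`MCMCSettings.paper_scale()` (3 × 60,000, burn-in 20,000, thin 1)
reproduces the original analysis scale for full multi-stage, multi-year
fits. Convergence is reported as split-R̂ and effective sample size per
parameter (via ArviZ), flagging R̂ > 1.1; chains are bitwise-reproducible
given a seed.

## Model selection

Two phases share one mechanism:

1. **Screening** — every candidate term gets an independent inclusion
   indicator with a Bernoulli(0.5) prior, entering the linear predictor
   as `I_j β_j x_j`. Terms with posterior `P(I_j = 1 | y) ≤ 0.5` are
   dropped; the threshold is deliberately "≤", so a coin-flip covariate
   is excluded.
2. **Cross-product selection** — per stage, a latent categorical
   indicator with a uniform prior selects among the final candidate
   models (intercept-only; cone pair; whitebark landscape area;
   Douglas-fir landscape area; cone pair + whitebark area; whitebark +
   Douglas-fir area — with stage-specific availability reflecting
   nutcracker phenology). Model probabilities are indicator frequencies;
   conditional (model-averaged) coefficient summaries use only draws
   where the term is included; a covariate's importance is its posterior
   inclusion probability, which equals the summed probability of the
   models containing it.

Coefficients excluded under the current model evolve under their prior —
the simplest Carlin–Chib pseudoprior choice, under which the pseudoprior
factors cancel from the indicator's full conditional. Mixing depends on
prior draws occasionally proposing credible coefficient values, which
the Normal(0, 2.5²) width makes routine; indicator switch rates are
directly visible in the stored `model_index` chain.

## Goodness of fit

The MacKenzie–Bailey discrepancy is computed per posterior draw:
detection histories are cross-tabulated into the 8 possible patterns
within each year-stage stratum, expected counts come from the marginal
history probabilities under that draw's ψ and p, cells with expected
count < 2 are pooled into a remainder cell (a remainder with zero
expectation is dropped with a warning), and `T = Σ (O−E)²/E`. A
replicate dataset is simulated from the same draw's generative model and
scored identically; the fit verdict is "adequate" exactly when the 95%
credible interval of `T_rep − T_obs` includes 0, with
`P(T_rep ≥ T_obs)` reported as a Bayesian p-value. By default the check
runs on an evenly thinned subset of at most 500 draws. The stratification
and pooling rule are stated conventions of this implementation; the
verdict rule (interval includes 0) is the published one.

## Prediction and thresholds

Prediction curves evaluate `ψ` on a grid of one covariate in original
units, per posterior draw, holding all other covariates at their means
(standardized 0), random effects at zero (a typical site in a typical
year), and — when selection was active — zeroing coefficients excluded
by that draw's model indicator, i.e. fully model-averaged curves. The
pointwise mean and 2.5/97.5 percentiles form the curve; grids default to
200 points over the observed covariate range, and points beyond that
range are flagged as extrapolation. The habitat threshold for a target
occurrence probability is the smallest grid value whose mean curve
reaches the target, linearly interpolated between bracketing points;
non-monotone curves return the smallest crossing with a warning.

The comparator cone-crop models are fixed published formulas on the
squared-log cone-production index: `y = −0.449 + 0.019x` (linear,
returned unclipped with clipping left to the caller) and
`y = expit(−1.5165 + 0.03883x)` (beta regression). The index uses the
natural log by default (the published descriptions do not name the
base); `log10` is available via an argument. Comparator evaluation
filters mirror the original protocol — infinite-radius surveys, cone
density > 0, same-day cone count, dates July 15 – September 15 — and
agreement is measured by Spearman rank correlation plus a one-tailed
Wilcoxon signed-rank test of underprediction (zero differences dropped,
mid-ranks for ties; all-zero differences reported as undefined).

## Field habitat metrics

- Belt transects: sampled area `Σ width×length − Σ width×discard`; the
  standard layout (four 10 × 50 m transects, first 5 m of the east and
  west transects discarded for overlap) gives 1,900 m².
- Cone density: cone-bearing trees per hectare × mean cones per tree.
- Point-centred quarter (Cottam–Curtis): stand density `10,000/d̄²`
  trees/ha from the mean point-to-tree distance over occupied quadrants;
  per-tree basal area `circumference²/(4π)`; importance value = relative
  density + relative frequency + relative dominance, summing to 300 over
  species. Empty quadrants (no tree within 200 m) are excluded from the
  distance mean but kept in the frequency denominator — the standard
  sparse-stand correction. Importance values above 300 are flagged:
  the bound is structural, and field tables exceeding it indicate an
  upstream calculation or transcription issue.

## Synthetic data

The generator emulates the study design: ~238 sites, 5 years × 5 stages,
three counts per unit, one radius class per dataset. Covariates mirror
the field distributions — cone density zero at ~65% of sites with a
lognormal positive part (right-skewed, mean ≫ median, mean ≈ 900
cones/ha among cone-bearing sites), importance values zero-inflated and
capped at 300, whitebark landscape area ≈ N(45,000, 20,000²) ha
truncated positive, Douglas-fir area lognormal with median ≈ 230 ha.
Detection and occurrence hierarchies match the model above, and the
truth sidecar stores every latent quantity so ψ and p are exactly
recomputable per unit.

What the generator does *not* emulate: spatial autocorrelation between
sites (sites are independent given covariates, as in the analysis
model), unbalanced visit schedules (every site×year×stage unit is
generated; real effort varies), observer identity, and within-season
covariate dynamics (cone counts change across visits in the field).
Passing calibration tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness
to these unmodeled features.

## Problem sizes in the shipped studies

The calibration suites use 300-unit single-stage datasets with
desk-scale chains: 50 replicates for parameter recovery (bias and 95%
interval coverage over the occurrence intercept and slope), 25 for
model-selection correctness (true model generated from the cone pair,
effect 1.5), 25 for screening calibration (one strong, one pure-noise
covariate), and 25 + 11 for goodness-of-fit calibration and power (the
misfit scenario draws per-site detection from a {0.1, 0.9} mixture).
These sizes give binomial standard errors of a few percent on the
reported rates while keeping the full suite in the minutes range.

## Known limitations

- The sampler is plain random-walk within Gibbs; for very large designs
  (all stages × years at the original survey size with paper-scale
  chains) it is CPU-minutes to hours, and no gradient-based alternative
  is provided.
- The Uniform(0, 10) sd priors are weakly informative only by range;
  with very few year-stage cells the detection-sd posterior is largely
  prior-driven.
- Conditional coefficient summaries are undefined when a term is never
  selected; they are reported as unavailable rather than zero.
- The comparator index log base and the clipping convention for the
  linear model's out-of-range predictions follow this package's stated
  defaults; both are configurable because the original descriptions are
  ambiguous.
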