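# Methods

`emaconn` links two measurement domains: resting-state functional
connectivity summarized per person through individual-specific network
mapping, and ordinal ecological momentary assessment (EMA) ratings of
motivation and pleasure modeled with Bayesian hierarchical cumulative-logit
regression. This note documents the models, the synthetic data the package
generates to validate them, and the numerical and design choices that were
genuinely open.

## Individual-specific network mapping

Each participant contributes a vertices × frames signal matrix on a shared
surface with a per-frame censor mask (True = retained). Cleaning follows the
standard resting-state sequence: coefficients for an intercept, a linear
trend, and any nuisance regressors are fit on retained frames only and their
fitted waveforms subtracted everywhere; censored frames are then replaced by
linear interpolation over retained neighbors so that motion-contaminated
samples cannot bleed through the filter; finally a 2nd-order Butterworth
band-pass (default 0.01–0.1 Hz at TR = 0.8 s) is applied forward–backward
over the full frame axis. Only participants with at least 375 retained
frames enter the analysis.

Template matching proceeds per vertex: the dense Pearson correlation matrix
is computed over retained frames, each vertex's row (self-connection
excluded) is binarized at its top 5% of connections, and the binary map is
scored against every a-priori network template with the Dice coefficient
2|A∩B|/(|A|+|B|). The vertex joins the network with the highest Dice;
all-zero Dice leaves it unassigned. Contiguous same-network patches with
surface area strictly below 30 mm² are unassigned, and the surviving
assignment is parcellated into connected components. The default template
set holds eight networks: default mode, cingulo-opercular, dorsal attention,
ventral attention, salience, fronto-parietal, and dorsal/ventral
somato-motor.

Decisions the mapping rules do not pin down, fixed here once:

- The top-fraction cut keeps exactly `floor(fraction · (n−1))` entries;
  ties at the cut break by ascending vertex index and are counted. Floor is
  conservative and deterministic.
- Dice ties break to the lowest network index and are counted in the
  assignment's `tie_count`.
- Dice of two empty maps is defined as 0, so a vertex with no template
  overlap stays unassigned rather than being assigned on no evidence.
- No sign filter is applied to correlations before the top-5% cut; negative
  correlations can enter only when fewer than 5% of a row's entries are
  positive.
- The 30 mm² rule is a strict inequality (a patch of exactly 30 mm² stays),
  and removed vertices become unassigned, not reassigned to the runner-up
  network.
- Contiguity is the surface's declared adjacency — 4-neighborhood on the
  synthetic lattice, mesh edges on a real surface.

## Network-level metrics

Parcel time series are unweighted means over member vertices (retained
frames only). Parcel-pair Pearson correlations are clipped to ±(1−1e−7) and
Fisher-Z transformed (atanh). Within-network connectivity is the mean Z over
parcel pairs inside a network (missing when a network has fewer than two
parcels); between-network connectivity is the mean Z over pairs spanning two
networks. The participation coefficient is computed on binary graphs
thresholded at tie densities 1%–25% in 1% steps, where density d keeps the
top `floor(d · P)` of the P parcel pairs by signed Z (ties by ascending pair
index): node PC is 1 − Σₛ(k_is/k_i)², isolated nodes contribute 0, node PCs
are averaged across the first ten densities (1%–10%) and then across each
network's parcels. "First 10% of tie densities" is read as the 1%–10%
subgrid — ten of the twenty-five graphs; the alternative reading (10% of a
25-element list) is incoherent. Spatial extent is the number of vertices
assigned to a network. For eight networks the metric table carries 8
within-network, 28 between-network (all unordered pairs), 8 PC, and 8
spatial-extent columns; model specifications select the subsets they use.

## EMA processing

Participants answer four prompts per day for 14 days; each prompt carries a
motivation and a pleasure question for both the anticipatory and the
consummatory construct, on a 1–5 scale. Participants who respond to at
least 33% of issued prompts are retained (inclusive comparison, threshold
0.33 read literally as the stated fraction, configurable). Question type is
coded 0 = motivation, 1 = pleasure. Numeric predictors (age, mean framewise
displacement, network metrics) are standardized using one value per
participant — so participants with more observations do not dominate the
scale — then broadcast to observations; diagnosis is dummy-coded with the
control group as reference, and metric × diagnosis interaction columns are
products of the standardized metric with the dummies. Within-prompt partial
responses are retained as single rows.

## Hierarchical ordinal model

For response Y ∈ {1..5},

    P(Y ≤ k) = logistic(τ_k − η),  k = 1..4
    η = xᵀβ + u_participant + u_day(participant)

with ordered thresholds τ and independent participant and
day-within-participant random intercepts. Priors are weakly informative on
the standardized scale: β ~ Normal(0, 2.5), τ_k ~ Normal(0, 5) on the
threshold scale with an ordering transform, and half-Normal(1) on both
random-intercept SDs; all are configurable. Sampling uses the package's
No-U-Turn sampler over a non-centered parameterization with analytic
gradients (the likelihood is collapsed to unique design cells with category
counts, so a gradient evaluation is O(cells) rather than O(observations); a
numba-compiled iterative NUTS with binary-counter subtree merging runs each
chain, and a pure-Python recursive NUTS is kept as an independent reference
implementation that tests compare against). Defaults are 4 chains × 1000
post-warmup draws after 1000 warmup iterations; split-R̂ < 1.01 and bulk
ESS > 400 are enforced on every reported parameter unless explicitly
disabled, and runs are bit-reproducible under a fixed seed.

Effect summaries: posterior-median odds ratio e^β with an equal-tailed 95%
credible interval; probability of direction (PD) as the percent of draws
strictly greater than zero, with the symmetrized convention
max(p, 100−p) reported alongside (published tables in this literature
follow the symmetrized convention — an odds ratio of 0.28 with "PD 99.7%"
can only be the symmetrized number); percent of draws inside the closed
ROPE [−0.10, 0.10] on the log-odds scale; and a significance flag when the
odds-ratio CI excludes 1 (equivalently the β CI excludes 0 — asserted as an
internal consistency check). PD is read as a statement about posterior
draws of the coefficient. Simple slopes report per-group conditional
effects β_metric (+ β_metric×group) for models with diagnosis interactions;
secondary models place a set of between-network predictors jointly in one
subgroup-restricted model and additionally mark "notable" effects by the
symmetrized PD > 90 convention.

Further choices: credible intervals are equal-tailed percentile intervals;
ROPE bounds are closed; random effects are intercepts only (the nesting
described is participants and days, with no basis for random slopes);
thresholds are always estimated on the full 5-level support even when a
subgroup leaves categories empty; rows with missing metric predictors are
dropped with a warning before fitting (within-network connectivity is
undefined for single-parcel networks).

## Synthetic data generator

The generator is the test bed: every downstream stage runs against planted
ground truth.

- **Surface**: a rows × cols lattice with 4-neighborhood adjacency and unit
  (configurable) vertex area stands in for a cortical mesh; 40 × 40 (1600
  vertices) by default. Area thresholds scale with `vertex_area`. It
  preserves exactly the properties the algorithms consume — adjacency,
  contiguity, area — and nothing else.
- **Templates**: K contiguous patches grown from farthest-point-sampled
  seeds by first-passage (randomized-distance) growth, giving balanced,
  irregular, contiguous patches. Individual topography perturbs a fraction
  of boundary vertices to a neighboring patch's label.
- **BOLD**: vertex v with network s(v) gets
  √ρ_w·L_s(t) + √ρ_b·G(t) + √(1−ρ_w−ρ_b)·ε_v(t) with independent
  standard-normal latents, so within- and between-network correlations are
  ρ_w+ρ_b and ρ_b by construction. Two 460-frame runs at TR = 0.8 s by
  default. No hemodynamic convolution — template matching consumes only
  correlation structure; an optional AR(1) coefficient adds temporal
  autocorrelation without changing the spatial structure. Censoring is
  independent Bernoulli per frame; mean framewise displacement is a
  lognormal draw (mean 0.15 mm, SD 0.08 mm) used purely as a covariate,
  deliberately not coupled to the censoring process.
- **EMA**: responses are drawn from the same hierarchical cumulative-logit
  model the inference stage fits, with configurable thresholds (default
  −2, −0.5, 0.5, 2), fixed effects (defaults plant a positive
  schizophrenia-group effect, a positive age effect, and a pleasure >
  motivation offset, echoing the diagnostic-group pattern the design
  targets), σ_participant = 0.5, σ_day = 0.3, and missingness that is
  independent Bernoulli per prompt (MCAR, default 25%). Real EMA
  missingness is unlikely to be MCAR; nothing here validates robustness to
  informative missingness.
- **Cohort**: default 144 participants (40 CON, 38 BD, 37 MDD, 29 SZ) with
  group-specific age distributions (means ≈ 33–36, SD ≈ 8) and
  female/non-binary rates (0.41–0.66). The EMA generator consumes a planted
  per-participant standard-normal latent metric recorded in the manifest,
  rather than a pipeline-estimated imaging metric — this keeps the ordinal
  recovery target exact and independent of mapping noise; estimated metrics
  come from running the mapping stage on the same bundle and are attenuated
  by estimation error relative to the planted values. All stage seeds
  derive from one master seed via `SeedSequence.spawn` and are recorded in
  the manifest; identical seeds give bit-identical bundles.

What passing synthetic tests does **not** show: robustness to hemodynamic
and vascular structure, spatially correlated noise, non-MCAR missingness,
real surface geometry, or template sets that mismatch the true individual
topology in structured ways.

## Validation experiments and problem sizes

`emaconn.validate` defines the experiments the acceptance checks run, at
sizes chosen to be informative on a single CPU:

- Template recovery: 40 × 40 lattice, 8 networks, ρ_w = 0.9, 920 frames —
  ≥ 99% of vertices recovered; with ρ_w = 0.999 (noise variance → 0),
  recovery is exact.
- Oracle equivalence: 50 seeded instances (≤ 50 vertices / ≤ 30 parcels)
  comparing the vectorized assignment and PC code with exhaustive
  brute-force recomputations, to 1e−12.
- Connectivity calibration: ρ_w = 0.5, 2000 frames, 5 seeds, with
  vertex-level units (each vertex its own parcel) so the within-network
  Fisher-Z average is directly comparable to atanh(0.5); every within
  estimate must beat every between estimate and sit within ±0.05 of
  atanh(0.5). Parcel-mean units would not target atanh(ρ_w): parcels of
  one network share their latent factor, so parcel pairs correlate near 1
  regardless of ρ_w.
- Ordinal recovery and null calibration: 120 participants (30 per group),
  14 days × 4 prompts × 2 questions, σ_p = 0.5, σ_d = 0.3; 20 replicates
  with a planted 0.5 per-SD effect (pooled posterior median within ±0.15,
  95% CI coverage ≥ 17/20) and 20 with no effect (significance flag fires
  in ≤ 3). Replicate fits use one chain of 400 draws after 300 warmup
  iterations — posterior medians and 95% bounds are stable at that size,
  and the experiment stays tractable on one CPU; single production fits
  default to 4 × 1000 with full diagnostics.
- Analytic PD/ROPE: one million Normal(0.3, 1) draws against the normal
  CDF, to 0.3 percentage points.

## Known limitations

- The lattice surface has no curvature, no vertex-area heterogeneity, and a
  degree-4 adjacency; real fsLR meshes differ in all three.
- The BOLD factor model has a single global factor and no spatial noise
  correlations, so between-network correlation structure is exchangeable.
- The sampler is a general-purpose NUTS without within-chain
  parallelization; models far larger than this design (many thousands of
  group levels) would benefit from specialized software.
- The day-level random-intercept SD is the slowest-mixing parameter; at the
  reduced replicate settings its ESS can drop to a few dozen while fixed
  effects remain well above it. Production settings with full diagnostics
  are the default everywhere else.
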