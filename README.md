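# emaconn

**Individual-specific resting-state network mapping and Bayesian ordinal
modeling of ecological momentary assessment (EMA) data.**

Negative symptoms — reduced motivation and pleasure (MAP) — cut across
schizophrenia, bipolar disorder, and depression, but clinic-based scales
measure them coarsely and retrospectively. A stronger design samples
experience in daily life (EMA: brief smartphone prompts, four times a day
for two weeks, each rating current and anticipated motivation and pleasure
on a 1–5 scale) and asks whether those ratings track *person-specific*
resting-state network organization rather than group-atlas summaries.

`emaconn` implements that analysis end-to-end for researchers in psychiatric
neuroimaging:

1. **Individual-specific network mapping** — each surface vertex's
   connectivity map (top 5% of its correlations, binarized) is matched to
   a-priori network templates by Dice coefficient, D = 2|A∩B|/(|A|+|B|);
   patches under 30 mm² are removed and the result parcellated into
   contiguous same-network parcels.
2. **Graph metrics** — within/between-network mean Fisher-Z connectivity,
   participation coefficient PC_i = 1 − Σ_s (k_is/k_i)² on binary graphs
   thresholded across 1–25% tie densities (averaged over the first ten),
   and per-network spatial extent (vertex counts).
3. **Hierarchical ordinal inference** — P(Y ≤ k) = logistic(τ_k − η) with
   η = xᵀβ + u_participant + u_day(participant); posterior odds ratios e^β
   with 95% credible intervals, probability of direction (PD), %ROPE on
   [−0.10, 0.10], simple-slopes contrasts per diagnostic group, and joint
   secondary models of between-network connectivity. Sampling is a
   numba-compiled No-U-Turn sampler with analytic gradients; a pure-Python
   reference sampler and a maximum-likelihood oracle back it in the tests.
4. **A synthetic cohort generator** — block-correlated BOLD-like signals on
   a lattice surface with planted network topography, individual boundary
   perturbations, frame censoring, covariates, and EMA responses drawn from
   the same cumulative-logit model the inference stage fits — so every
   stage is validated against known ground truth.

## Worked example

Simulate a small cohort, map networks, build the metric table, and fit one
ordinal model of anticipatory MAP on a network's spatial extent:

```python
from emaconn import RunConfig, run_all, report

cfg = RunConfig.from_dict({
    "seed": 7,
    "n_per_group": [4, 4, 4, 4],
    "surface_shape": [16, 16],
    "n_networks": 4,
    "min_patch_area": 4.0,
    "min_frames": 300,
    "bold": {"frames_per_run": 460, "n_runs": 2, "within_corr": 0.6},
    "ema": {"n_days": 14},
    "fits": [{"kind": "extent", "network": "VAN",
              "construct": "anticipatory"}],
    "sampler": {"chains": 2, "draws": 500, "warmup": 400,
                "check_convergence": False},
})
manifest = run_all(cfg, "results/demo")
print(report("results/demo"))
```

Output (abridged):

```
== extent_VAN_anticipatory ==
  BD                           e^b = 1.21 [0.33, 4.85]  PD = 63.1%  ROPE = 12.8%
  MDD                          e^b = 1.03 [0.21, 4.78]  PD = 52.1%  ROPE = 11.3%
  SZ                           e^b = 0.86 [0.19, 4.72]  PD = 57.3%  ROPE = 9.0%
  age_z                        e^b = 1.04 [0.55, 1.79]  PD = 55.1%  ROPE = 29.2%
  gender                       e^b = 0.96 [0.37, 2.82]  PD = 54.2%  ROPE = 18.2%
  question_code                e^b = **1.33 [1.11, 1.59]**  PD = 99.8%  ROPE = 2.5%
  fd_z                         e^b = 0.87 [0.56, 1.29]  PD = 79.6%  ROPE = 29.8%
  extent_VAN_z                 e^b = 0.74 [0.32, 1.68]  PD = 78.4%  ROPE = 15.2%
  extent_VAN_z:BD              e^b = 1.66 [0.54, 5.35]  PD = 83.6%  ROPE = 10.4%
  extent_VAN_z:MDD             e^b = 1.85 [0.66, 5.08]  PD = 92.0%  ROPE = 6.7%
  extent_VAN_z:SZ              e^b = 2.87 [0.27, 26.66]  PD = 84.4%  ROPE = 3.7%
== slopes_extent_VAN_anticipatory_extent_VAN_z (conditional effects) ==
  CON    0.74 [0.32, 1.68]
  BD     1.25 [0.51, 2.46]
  MDD    1.39 [0.73, 2.51]
  SZ     2.12 [0.22, 17.99]
```

Read it like a published effect table: each row is a posterior-median odds
ratio per SD of the predictor with its 95% credible interval (bolded
`**…**` when the interval excludes 1 — here only the question-type effect,
the planted pleasure > motivation offset, is significant at this small
demonstration size), the probability of direction, and the percent of
posterior mass inside the region of practical equivalence. The conditional
block gives each diagnostic group's simple slope for the metric.

The same stages are available on the command line:

```bash
emaconn simulate --out bundle/ --seed 1
emaconn map-networks --bundle bundle/ --out mapped/
emaconn metrics --bundle bundle/ --out metrics/
emaconn ema --records bundle/ema.csv --covariates bundle/covariates.csv \
        --construct anticipatory --out tables/
emaconn fit --table tables/model_table_anticipatory.tsv --model diagnostic \
        --seed 1 --out fit/
emaconn pipeline --config config.yaml --out results/
```

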