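# dynamark

Dynamic Landmarking diagnostics for propensity-score-matched
time-to-event analyses.

## The problem

In a non-randomized study the hazard ratio for a treatment is usually
estimated in two steps: balance the arms by propensity-score (PS)
matching, then fit a Cox model with treatment as the only covariate.
Two distinct omissions can leave that single number biased:

* **an omitted confounder** — a covariate associated with both
  treatment allocation and outcome that was left out of the PS model.
  Matching cannot balance it, and the estimate carries *confounding
  bias*;
* **an omitted prognostic factor** — a covariate associated with the
  outcome only.  Matching leaves it balanced, but because the hazard
  ratio is non-collapsible, omitting it from the Cox model makes the
  estimate drift over follow-up as high-risk subjects are selectively
  depleted: *built-in selection bias*.

The hazard ratio itself gives no hint which (if either) is at work.
**Dynamic Landmarking** turns it into a trajectory: sort the matched
data by observation time, repeatedly delete the earliest *M*
observations (events and censorings alike), move time zero forward to
the follow-up time of the latest deleted subject, refit the
treatment-only Cox model — here the pair-stratified model
h_j(t|Z) = h_{0j}(t)·exp(β_Z Z) — and, in parallel, re-measure the
balance of every *omitted but observed* covariate with the sum of
squared z-differences

SSQ = Σ z²_con + Σ z²_bin + Σ z²_ord + Σ z²_nom,&emsp;
z_con = (x̄_T − x̄_C) / √(σ̂²_T/N_T + σ̂²_C/N_C),

which under balance is approximately χ²_k for k independent
components.  Reading the two trajectories in sequence separates the
bias sources:

| effect trajectory | initial SSQ | SSQ trend | diagnosis |
|---|---|---|---|
| stable | low | — | no bias indicated |
| stable | high | — | instrument omitted |
| shifting | high | — | confounding suspected |
| shifting | low | rising | built-in selection suspected |
| shifting | low | flat | unmeasured source suspected |

The package ships the complete pipeline — typed cohort I/O, a
Weibull-proportional-hazards simulation engine with a known
confounding structure, ML logistic PS estimation, greedy 1:1 caliper
matching on the logit-PS scale, marginal and matched-pair-stratified
Cox fits, the landmark loop, the classification scheme, and
scenario-level experiment drivers — as a library with a thin
`dynamark` CLI on top.

## Worked example

`examples/landmark_prognostic_factor.py` simulates the headline
scenario — 5000 subjects, standard-normal confounder X and omitted
covariate U, treatment assigned with logit(p) = −1.21 + log 3 · X,
Weibull(λ = 0.01, γ = 1.5) hazards with conditional treatment effect
β_Z = log 3 and prognostic effect β_U = log 3, ≈10% censoring — then
matches on X and landmarks the matched pairs with U omitted:

```
matched analysis set: 2350 subjects; 92 landmark steps (min_size_reached)
step 0:   log-HR = +0.759 (SE 0.064), SSQ(U) = 0.22
50% del.: log-HR = +0.562, SSQ(U) = 36.45
diagnosis: builtin_selection_suspected (shift 3.1 SE, initial SSQ p = 0.638)
```

Although the conditional effect is log 3 ≈ 1.10, the step-0 estimate
is already attenuated to 0.76 (non-collapsibility), keeps shrinking as
low-risk subjects dominate, and U's balance erodes from its χ²₁
baseline — the built-in selection signature.  Contrast
`examples/diagnose_confounder.py`, where U also drives allocation
(α_U = log 3): there the SSQ is ≈700 *before the first deletion* and
the diagnosis flips to `confounding_suspected`, with the advice to
re-estimate the PS including U.

Other examples: `simulate_and_match.py` (pipeline up to the matched
analysis set) and `balance_from_printed_summaries.py` (z-differences
computed from published baseline tables alone).

The same steps are available from a shell:

```
dynamark simulate --n 5000 --seed 42 --out cohort.csv
dynamark match --cohort cohort.csv --schema cohort.schema.json \
    --ps-covariates X --out matched.csv
dynamark landmark --cohort matched.csv --schema cohort.schema.json \
    --omitted U --out trajectory.csv
dynamark diagnose --cohort matched.csv --schema cohort.schema.json --omitted U
dynamark plot --trajectory trajectory.csv --true-log-hr 1.0986 --out traj.png
```

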