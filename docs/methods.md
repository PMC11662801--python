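# Methods

## Model and estimands

Subjects carry a treatment indicator Z ∈ {0,1}, a follow-up time Y > 0,
an event indicator δ (1 = event, 0 = censored) and typed baseline
covariates.  The working outcome model is proportional hazards,
λ(t|Z, covariates) = λ₀(t)·exp(β_Z Z + …).  Two treatment-only Cox
fits are distinguished throughout:

* the **marginal** fit, λ(t|Z) = λ₀(t)·exp(β Z), a population-averaged
  effect; and
* the **pair-stratified** fit on 1:1 matched data,
  h_j(t|Z) = h_{0j}(t)·exp(β Z) with one stratum per matched pair.

Because the hazard ratio is non-collapsible, these differ from the
covariate-conditional effect whenever a prognostic factor is omitted,
even without confounding.  The diagnostic's preconditions are
independent censoring, a time-constant conditional treatment effect
(proportional hazards), and at least one observed covariate omitted
from the PS and/or Cox model whose balance can be tracked.

## Dynamic Landmarking

The matched analysis set is sorted by follow-up time (ties: events
before censorings, then subject id — a fixed, documented rule so runs
are bit-reproducible).  Step 0 records the fit and the balance of the
omitted set on the full data.  Each subsequent step deletes the
earliest M observations regardless of event status, advances the
landmark time to the follow-up of the latest deleted subject, refits,
and re-measures balance.  Partial-likelihood estimates depend on times
only through their ordering, so the time-zero reset is bookkeeping; it
carries the "conditional on survival to t" reading of each step.

Design choices where the procedure itself is open:

* **Deletion step M** — default 1% of the analysis-set size
  (configurable absolutely or as a fraction).  Trajectories are read
  on a percent-deleted axis, and a 1% step yields ~100 points, enough
  to resolve the first-half trends the classification uses.
* **Stop rule** — stop when fewer than 100 subjects remain, either arm
  has fewer than 5 events, or fewer than 10 informative pairs remain
  (all configurable); a non-converging fit also terminates the loop.
  These operationalize "too few observations for convergence".
* **Orphans** — deleting one member of a pair leaves its partner in
  the data as a singleton stratum: it contributes a factor of one to
  the stratified partial likelihood but still counts in balance
  measurement.  This is the literal reading of "delete the earliest M
  observations"; `drop_orphans=True` removes partners as a sensitivity
  analysis.
* **Balance at each step** uses the plain two-group z formulas on all
  remaining subjects (orphans included), not pair-differenced
  statistics.

## Balance statistics

z-differences are oriented treated − control for every covariate kind.
Continuous covariates use the Welch form with unbiased (n−1)
variances; binary covariates the unpooled two-proportion form.  The
published decomposition defines ordinal and nominal components but
their exact formulas are not available in the source text, so this
package uses, explicitly as stand-ins isolated behind two functions:

* **ordinal** — the tie-corrected mid-rank (Mann–Whitney)
  standardization on the declared level order: mean 0, unit variance
  under exchangeability, df 1.  On two-level data it tracks the binary
  z within ~2%.
* **nominal** — one indicator z per non-reference level (reference =
  first declared level), df = #levels − 1.

SSQ sums squared components; its reference is χ²_k with k the summed
df.  A covariate degenerate in *both* arms (zero denominator, equal
location) is recorded as NaN with its df still counted; degenerate in
one arm only is an error, since that is real, infinite-z imbalance.
Covariate kinds are declared in a JSON sidecar rather than inferred:
misreading ordinal as nominal silently changes k.

## Cox fits

Both fits are scalar-parameter Newton solvers written for the landmark
loop (hundreds of refits per run): relative tolerance 1e-9, at most
100 iterations, |β| > 15 treated as monotone-likelihood divergence and
flagged rather than raised.  The marginal fit maximizes the Breslow
partial likelihood using per-event-time risk counts by arm; Breslow
handling is inconsequential under the continuous simulation model
(ties have probability zero) and is the documented policy for real
data.  For treatment-discordant 1:1 pairs the stratified likelihood
collapses to a·β − (a+b)·log(1+e^β), where a (b) counts informative
pairs whose treated (control) member fails first — "informative"
meaning the earlier time is an event while the partner is still at
risk — so the solution equals log(a/b) with SE √((a+b)/(ab)); the
Newton route is retained and cross-checked against this closed form
and against an independent library implementation in the tests.
Confidence intervals are Wald on the log scale (default 95%).

## Propensity scores and matching

The PS is estimated by maximum-likelihood logistic regression
(Newton/IRLS, tolerance 1e-8, ≤50 iterations) on the declared
covariates; collinear designs and separation (non-convergence or any
|coefficient| > 15) raise an estimation error rather than returning a
degenerate score.  Matching is greedy 1:1 nearest-neighbour without
replacement on the logit-PS scale with caliper 0.2 × the *pooled*
(all-subject) SD of the logit PS — pooled being the convention the
caliper recommendation is usually attributed to.  Treated subjects are
processed in seeded-random order (the procedure does not prescribe
one; random order avoids PS-sorted artefacts and stays reproducible);
distance ties break to the smaller control id; treated remain the
"cases" even if they outnumber controls.  Greedy nearest-neighbour
pairing retains a small directional residual on the matched covariate
(nearest controls for extreme treated subjects sit systematically
slightly inside them).  It is negligible on the SMD scale (~0.006
here) but visible on the √n-scaled z scale (mean z ≈ 0.15 at a matched
n of ~2400), which is worth knowing when reading near-zero SSQ values.

## Simulation engine

The generator emulates a non-randomized two-arm trial with one
measured confounder X and one omitted covariate U: (X, U) jointly
standard normal with correlation ρ (Cholesky), treatment Bernoulli
with logit(p) = α₀ + α_X X + α_U U, event times Weibull proportional
hazards h(t) = γλt^{γ−1}·exp(β_Z Z + β_X X + β_U U) by inverse
transform, censoring exponential and independent.  Defaults are the
headline conditions: n = 5000, α₀ = −1.21, α_X = β_X = β_Z = β_U =
log 3, λ = 0.01, γ = 1.5, ρ = 0.  The zero-pattern of (α_U, β_U)
defines U's role — independent / prognostic / instrument / confounder
— exposed as `ScenarioConfig.u_role`.  Reproducibility: one master
seed per scenario; replicate r draws from the child generator
SeedSequence([seed, r]).

Two points where the stated conditions do not self-reproduce, kept as
recorded observations rather than forced:

* α₀ = −1.21 with α_X = log 3 yields ≈27.3% treated (by Gauss–Hermite
  integration and simulation), not the ~24% quoted alongside it.
* achieved censoring is a steep function of the exponential rate under
  these event-time parameters; the quoted parameter values {0.2, 0.6,
  0.9} yield ≈78/91/94% censoring, not 10/40/80%.  The package
  therefore treats the exponential parameter as a rate and ships
  `calibrate_censor_rate`, a bisection on a fixed 10⁵-subject probe
  with common exponential draws (exactly monotone in the rate), so
  scenario code requests target fractions — the "10% censoring"
  scenarios use a calibrated rate ≈0.004 — and the achieved fraction
  is always an output diagnostic.

What the generator does *not* emulate: covariate-dependent or
administrative censoring, time-varying treatment effects (explicitly a
precondition violation for the method), competing risks, more than one
omitted covariate with distinct roles at once, or non-normal covariate
distributions.  Passing tests therefore demonstrate the diagnostic's
behaviour under its own assumptions, not robustness to their failure.

## Classification

The screening rule evaluates the first half of the deletion path:
shift = |log-HR at the step nearest 50% deleted − log-HR at step 0| in
step-0 SE units, flagged above 2.0; initial imbalance = step-0 SSQ
above the upper-1% χ²_k quantile; SSQ trend = least-squares slope of
SSQ against deleted fraction (computed by the covariance formula so a
constant series has slope exactly 0), "rising" when positive.  The
decision table in the README is total and deterministic in these three
quantities.  Per-covariate diagnosis reuses one landmark run's effect
trajectory (it does not depend on the balance set) and judges each
covariate on its own z series and df.  All cutoffs are explicit
configuration; the rule is a screening device, not a calibrated test —
no error rates are controlled, which mirrors its intended post-hoc
visual use.  Note a structural consequence of the shared trajectory:
when a genuine shift exists, a covariate that is itself innocent can
only be sorted into the "built-in selection" or "unmeasured source"
branches by its own (noisy) trend; what per-covariate evidence
reliably isolates is which covariate carries the confounding
signature.

## Experiment scale

Scenario-level runs aggregate replicate trajectories on a common 1%
percent-remaining grid with linear interpolation, NaN outside each
replicate's observed range.  The packaged default of 500 replicates
per scenario matches the ambient scenario definition; the shipped
tests and the acceptance script use 100 replicates per scenario (200
for the matched-sample-size average), sizes chosen so the full
evidence suite runs in minutes on a single CPU while Monte-Carlo error
stays well inside the asserted margins.  Failed replicates (matching
or estimation errors) are excluded from aggregates and counted.

## Known limitations

* Ordinal/nominal z components are principled stand-ins, not the
  original (unavailable) definitions; they are isolated so they can be
  swapped without touching SSQ aggregation.
* The stratified fit assumes 1:1 discordant pairs (plus singletons);
  k:1 or variable-ratio matching is out of scope, as are PS weighting,
  re-matching after deletion, covariate-adjusted refits within the
  loop, robust variances for matched pairs, and Efron tie handling.
* A shifting trajectory cannot distinguish built-in selection from a
  genuinely time-dependent treatment effect; that identification
  problem is inherent to the method, not to this implementation.
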