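"""Built-in selection bias made visible: landmarking an omitted prognostic factor.

In this scenario U affects the outcome (beta_u = log 3) but not
treatment allocation, so PS matching leaves it balanced — yet omitting
it from the Cox model makes the pair-stratified hazard ratio drift as
follow-up accrues.  Dynamic Landmarking shows the drift directly: the
log-HR trajectory declines over the first half of deletions while the
SSQ balance statistic for U rises from its chi-squared baseline.
"""

import dynamark as dm

config = dm.ScenarioConfig(seed=42, alpha_u=0.0)  # U: prognostic factor
config = config.replace(censor_rate=dm.calibrate_censor_rate(config, 0.10))

trajectory, matched_n = dm.run_replicate(config, dm.LandmarkSettings(), rep=0)
print(f"matched analysis set: {matched_n} subjects; "
      f"{len(trajectory)} landmark steps ({trajectory.termination_reason})")

step0 = trajectory.steps[0]
i50 = trajectory.step_nearest_fraction(0.5)
print(f"step 0:   log-HR = {step0.fit.log_hr:+.3f} (SE {step0.fit.se:.3f}), "
      f"SSQ(U) = {step0.ssq_omitted.ssq:.2f}")
print(f"50% del.: log-HR = {trajectory.log_hr[i50]:+.3f}, "
      f"SSQ(U) = {trajectory.ssq[i50]:.2f}")
# the conditional (subject-specific) effect is log 3 = 1.099; already at
# step 0 the estimate is attenuated, and it keeps shrinking while U's
# imbalance grows - the built-in selection signature.

result = dm.classify(trajectory)
print(f"diagnosis: {result.label} "
      f"(shift {result.shift_magnitude:.1f} SE, initial SSQ p = {result.initial_ssq_pvalue:.3f})")
print(dm.recommendation(result))

dm.plot_trajectories(trajectory, "scratch_prognostic.png", true_log_hr=config.beta_z)
print("wrote scratch_prognostic.png")
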