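"""Declare a two-arm experiment from step primitives and diagnose it.

Builds the canonical design -- 200 units with standard-normal noise, a
constant unit treatment effect, a sample of 100, 50 treated, and a
difference-in-means answer -- then estimates its power, bias, RMSE and
coverage from 1000 simulations with bootstrap standard errors.
"""

import designdiag as dd

steps = [
    dd.declare_population(200, {"u": {"normal": [0, 1]}}),
    dd.declare_potential_outcomes("Y", dd.ConditionSet("Z", [0, 1]),
                                  "Z + u"),
    dd.declare_inquiry("ATE", "summary", expr="mean(Y_Z_1 - Y_Z_0)"),
    dd.declare_sampling("simple", n=100),
    dd.declare_assignment("complete", m=50),
    dd.declare_reveal("Y", "Z"),
    dd.declare_estimator(dd.difference_in_means, "DIM", estimand="ATE",
                         outcome="Y", assignment="Z"),
]
design = dd.compose_design(steps, "two_arm_experiment")

diagnosis = dd.diagnose_design(design, ["power", "bias", "rmse", "coverage"],
                               m=1000, n_bootstrap=100, seed=1)
print(diagnosis[["diagnosand", "estimate", "bootstrap_se"]].to_string(
    index=False))
print()
print("The estimand is exactly 1; bias should sit within a couple of")
print("bootstrap SEs of 0, coverage near 0.95, and power near 1 (the")
print("effect is a full residual SD).")
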