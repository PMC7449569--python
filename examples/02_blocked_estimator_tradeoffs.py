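"""Compare rival answer strategies for a blocked experiment.

Assignment probabilities differ by block and effect sizes correlate with
block size, so the unweighted answers (difference in means, block fixed
effects) are biased for the average treatment effect.  Inverse-probability
weighting removes the bias and raises power -- but its conventional
weighted-regression variance estimates are too small, so its confidence
intervals undercover and its RMSE is no better than the fixed-effects
answer.  Power alone would badly misrank these strategies.
"""

import designdiag as dd

design = dd.make_design("blocked_hetero")
diagnosis = dd.diagnose_design(design,
                               ["power", "bias", "coverage", "rmse"],
                               m=1000, n_bootstrap=100, seed=4)
table = diagnosis.pivot(index="estimator_label", columns="diagnosand",
                        values="estimate")
print(table.round(3).to_string())
print()
print("Reading: BFE_IPW has the best power and essentially no bias, but")
print("coverage well below 0.95 and no RMSE advantage over BFE --")
print("diagnosands beyond power are needed to see the trade-off.")
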