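"""Diagnose clue-seeking strategies in Bayesian process tracing.

A case with both X and Y present is selected; the hypothesis that X
caused Y holds with prior probability 0.5.  Two clues are available: a
straw-in-the-wind (seen with probability 0.75 if true, 0.25 if not) and
a smoking gun (0.30 vs 0.05).  The diagnosand is the expected absolute
posterior error, computed exactly by enumeration and confirmed by Monte
Carlo over the declared design.
"""

import designdiag as dd

table = dd.LikelihoodTable((0.75, 0.30), (0.25, 0.05))

print("clue 1 classifies as:", dd.classify_test(0.75, 0.25))
print("clue 2 classifies as:", dd.classify_test(0.30, 0.05))
print()
for strategy in ("cpo1_only", "cpo2_only", "both"):
    exact = dd.pt_strategy_diagnosis(0.5, table, strategy)
    print(f"expected |posterior error|, {strategy:10s}: {exact:.4f}")
print()
design = dd.make_design("process_tracing", strategy="cpo1_only")
diag = dd.diagnose_design(design, ["mean_absolute_error"], m=2000,
                          n_bootstrap=100, seed=2)
row = diag.iloc[0]
print(f"Monte Carlo check (straw only): {row['estimate']:.4f} "
      f"(bootstrap SE {row['bootstrap_se']:.4f})")
print()
print("The weaker straw-in-the-wind beats the smoking gun on average:")
print("the gun is more informative when seen, but it is rarely seen.")
print("Seeking both clues helps most when they are negatively correlated:")
for rho in (-0.1, 0.0, 0.1):
    err = dd.pt_strategy_diagnosis(0.5, table, "both", rho=rho)
    print(f"  rho = {rho:+.1f}: expected error {err:.4f}")
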