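"""Confounded selection, covariate balance, and what refinement buys.

Uses the confounded preset: healthier people (with better cognition) are
more likely to enter the labour market, and worse health steepens cognitive
decline, so the raw matched contrast overstates the benefit of entry (the
true effect here is zero).  Prints the unadjusted and CBPS-adjusted
estimates and the worst covariate standardised mean difference before and
after refinement.
"""

from matchdid import RunSpec, analyse_direction, confounded_scenario, generate

scenario = confounded_scenario(n_units=2000, seed=3)
panel, truth = generate(scenario)
dr = analyse_direction(panel, RunSpec(scenario=scenario, seed=3), "entry",
                       with_bootstrap=False)

for res in dr.results:
    if res.F == 0:
        print(f"{res.adjustment:10s} DID at F=0 = {res.estimate:+.3f} "
              "(truth: +0.000)")
ok = dr.balance[~dr.balance["undefined"]]
print(f"max |SMD| over covariate-history slots: "
      f"{ok['smd_before'].abs().max():.3f} before refinement -> "
      f"{ok['smd_after'].abs().max():.3f} after CBPS weighting")
print("The adjusted estimate sits much closer to zero because the CBPS "
      "weights force the matched controls' covariate histories (health, "
      "past cognition, ...) to line up with the treated group's.")
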