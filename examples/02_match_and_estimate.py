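"""Exact history matching, CBPS refinement and the DID point estimate.

Runs the full chain for labour-market entry on one synthetic cohort with a
known true effect of +0.65 score points at the transition wave, and prints
the unadjusted and CBPS-adjusted estimates at leads F=0 and F=1.
"""

from matchdid import RunSpec, ScenarioConfig, analyse_direction, generate

scenario = ScenarioConfig(n_units=2000, tau_entry=0.65, tau_exit=0.0, seed=1)
panel, truth = generate(scenario)
spec = RunSpec(scenario=scenario, seed=1)

dr = analyse_direction(panel, spec, "entry", with_bootstrap=False)
print(f"treated entry events: {dr.tally['n_treated_events']}, "
      f"unmatched (no history-sharing control): {dr.tally['n_unmatched']}")
for res in dr.results:
    print(f"F={res.F} {res.adjustment:10s} DID = {res.estimate:+.3f}")
print(f"true effect at F=0 is {truth['tau_entry']:+.2f} score points and 0 "
      "at F=1; a single cohort estimates it with sampling noise of roughly "
      "0.25 points (about 200 treated events), and with no confounded "
      "selection the unadjusted and adjusted estimators target the same "
      "quantity.")
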