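# matchdid

Matched difference-in-differences for longitudinal cohort data: estimate the
effect of a binary status *transition* (the motivating application is
late-life labour-market entry and exit) on a bounded integer outcome (a
global-cognition score such as MMSE 0–30 or TICS 0–27), using exact matching
on treatment histories, covariate-balancing refinement of the matched sets,
and weighted block-bootstrap inference.

It is written for epidemiologists and applied economists analysing biennial
ageing panels (KLoSA/HRS-style person–wave tables), and for methodologists
who want a fully simulatable test bed: a synthetic cohort generator with
known ground truth makes every stage checkable without restricted survey
data.

## The estimator

For each treated observation (i, t) — a person who switched state between
waves t−1 and t — the matched set M<sub>it</sub> contains every control
observation at the same wave t with the identical employment history over
the previous L waves (default L = 3) that did not switch. Refinement weights
w<sub>it</sub><sup>i′</sup> ≥ 0 (summing to 1 within each set) align the
controls' pre-treatment covariate histories with the treated person's. The
effect at lead F ∈ {0, 1} is the average treatment effect on the treated,

> DID(F, L) = mean over treated, matched (i, t) of
> [ (Y<sub>i,t+F</sub> − Y<sub>i,t−1</sub>) −
>   Σ<sub>i′∈M<sub>it</sub></sub> w<sub>it</sub><sup>i′</sup>
>   (Y<sub>i′,t+F</sub> − Y<sub>i′,t−1</sub>) ],

in score points of the outcome instrument. The default refinement is a
covariate-balancing propensity score (CBPS) fitted by just-identified
balance estimating equations targeting the treated (odds-weighted control
covariate means equal treated means exactly at the solution); Mahalanobis
nearest-J, propensity-score nearest-J and plain propensity-odds weighting
are available as comparators. Standard errors come from a weighted block
bootstrap: whole persons (their full time series) are resampled with
matched sets and weights frozen. Balance is reported as standardised mean
differences per covariate and lag, before and after refinement, including
pre-treatment outcome levels and changes (the observable face of the
parallel-trends assumption).

## Worked example

```python
from matchdid import (BootstrapConfig, RunSpec, ScenarioConfig,
                      analyse_direction, generate)

scenario = ScenarioConfig(n_units=2000, tau_entry=0.65, tau_exit=0.0, seed=5)
panel, _ = generate(scenario)                  # synthetic biennial cohort
spec = RunSpec(scenario=scenario, seed=5,
               bootstrap=BootstrapConfig(reps=1000, seed=5))
dr = analyse_direction(panel, spec, "entry", adjustments=("adjusted",))
res = next(r for r in dr.results if r.F == 0)
print(res.estimate, res.se, res.ci_low, res.ci_high, res.n_treated)
```

This prints (see `examples/04_bootstrap_inference.py` for the full script):

```
entry, F=0, adjusted: DID = +0.608, SE = 0.152, 95% CI [+0.317, +0.915] (215 treated events)
```

meaning: across 215 matched entry transitions in this simulated cohort,
entering the labour market raised the cognition score by an estimated 0.61
points at the transition wave (true injected effect: 0.65), with a
bootstrap SE of 0.15 and a 95% percentile interval excluding zero. The
`examples/` directory walks through each capability — cohort generation,
matching and estimation, confounding and balance diagnostics, bootstrap
inference, and a full config-driven study with subgroups — each printing
its numbers with a line on what they mean. A thin CLI mirrors the library
(`matchdid run-all --config cfg.yaml --seed 1 --out out/`).

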