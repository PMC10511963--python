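"""Config-driven end-to-end analysis runs and Monte-Carlo studies.

``run`` executes the full chain — treatment coding, eligibility filtering,
covariate construction, exact history matching, refinement, DID estimation
with block-bootstrap inference, and balance diagnostics — for each requested
direction and, optionally, for subgroups (median baseline asset, education
up to high school vs above, sex).  Subgroup runs redo the matching within
the subgroup so matched controls share subgroup membership.  Everything is
reproducible bit-for-bit from (input, config, seed), and each run writes a
results table shaped like a published DID summary, a balance table per
direction, and a flowchart-style exclusion tally whose counts conserve.

``simulate_study`` repeats generate -> analyse over many seeds and
aggregates bias, RMSE, the empirical SE of the estimator, the mean bootstrap
SE and 95% CI coverage of the truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import BootstrapConfig, block_bootstrap
from .cohort import (CovariateSpec, apply_eligibility, build_covariates,
                     code_transitions)
from .diagnostics import balance_smd, pretrend_check, write_balance
from .estimator import EstimationError, estimate_did, results_table
from .matching import build_matched_sets, n_unmatched
from .panel import Panel, read_panel
from .refine import fit_refinement, refine, RefinementError
from .simulate import ScenarioConfig, generate


def default_covariate_spec(lags: int = 3) -> CovariateSpec:
    """Covariate set mirroring an ageing-cohort confounder list: demographics
    and socio-economic position at the transition wave, plus three-wave
    histories of health, (tertiled) income and asset, and the outcome."""
    return CovariateSpec(
        time_invariant=["age", "age_sq", "sex", "education", "spouse",
                        "occupation", "pre1945"],
        time_varying=["health", "income", "asset"],
        lags=lags,
        include_lagged_outcome=True,
        tertile_vars=["income", "asset"],
        missing_indicator_vars=["health", "income", "asset"],
        categorical={"education": [0.0, 1.0, 2.0, 3.0],
                     "occupation": [0.0, 1.0, 2.0]},
    )


@dataclass
class RunSpec:
    """Everything one end-to-end analysis needs."""

    panel_path: str | None = None
    schema: dict | None = None
    scenario: ScenarioConfig | None = None
    directions: tuple = ("entry", "exit")
    lags: int = 3
    leads: int = 1
    window: tuple = (2012, 2018)
    min_age: float | None = 65.0
    refinement: str = "cbps_weight"
    size_match: int = 5
    covariates: CovariateSpec | None = None
    bootstrap: BootstrapConfig = dc_field(default_factory=BootstrapConfig)
    subgroups: tuple = ()  # subset of ("asset", "education", "sex")
    seed: int = 0
    tag: str = ""

    def __post_init__(self):
        if not self.directions:
            raise ValueError("at least one direction is required")
        if self.covariates is None:
            self.covariates = default_covariate_spec(self.lags)

    @classmethod
    def from_yaml(cls, path) -> "RunSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw and raw["scenario"] is not None:
            raw["scenario"] = ScenarioConfig(**raw["scenario"])
        if "bootstrap" in raw:
            raw["bootstrap"] = BootstrapConfig(**raw["bootstrap"])
        if "covariates" in raw and raw["covariates"] is not None:
            raw["covariates"] = CovariateSpec(**raw["covariates"])
        for key in ("directions", "window", "subgroups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class DirectionRun:
    """Artifacts of one direction's analysis (one matched design)."""

    direction: str
    results: list
    balance: pd.DataFrame
    pretrend: pd.DataFrame
    tally: dict
    matched_sets: list
    refined_sets: list


@dataclass
class RunResult:
    results: pd.DataFrame
    balance: dict
    tallies: dict
    log: list
    subgroup_results: dict = dc_field(default_factory=dict)


def _load_panel(spec: RunSpec) -> Panel:
    if spec.scenario is not None:
        panel, _ = generate(spec.scenario)
        return panel
    if spec.panel_path is None:
        raise ValueError("RunSpec needs either a panel_path or a scenario")
    return read_panel(spec.panel_path, schema=spec.schema)


def analyse_direction(panel: Panel, spec: RunSpec, direction: str,
                      with_bootstrap: bool = True,
                      adjustments=("unadjusted", "adjusted"),
                      with_diagnostics: bool = True) -> DirectionRun:
    """Run one direction end-to-end on an already-loaded panel."""
    events, code_tally = code_transitions(panel, direction, spec.window)
    events, elig_tally = apply_eligibility(panel, events, spec.lags,
                                           spec.leads, spec.min_age)
    tally = {"coding": code_tally, "eligibility": elig_tally,
             "n_treated_events": int(events["treated"].sum()),
             "n_control_events": int((~events["treated"]).sum())}
    if events["treated"].sum() == 0:
        raise EstimationError(f"no treated {direction} events after "
                              "eligibility filtering")
    cov = build_covariates(panel, events, spec.covariates)
    raw_sets = build_matched_sets(events, panel, spec.lags)
    tally["n_unmatched"] = n_unmatched(raw_sets)
    model = fit_refinement(raw_sets, cov, spec.refinement, spec.size_match)
    refined = refine(raw_sets, cov, model)

    results = []
    for adjustment in adjustments:
        if adjustment == "adjusted":
            sets = refined
        else:
            sets = [s.with_weights(
                np.full(s.n_members, 1.0 / s.n_members)
                if s.is_matched else np.empty(0)) for s in raw_sets]
        for F in range(spec.leads + 1):
            if with_bootstrap:
                res = block_bootstrap(sets, panel, F, spec.bootstrap,
                                      direction=direction,
                                      adjustment=adjustment)
            else:
                res = estimate_did(sets, panel, F, direction, adjustment)
            results.append(res)
    if with_diagnostics:
        equal_sets = [s.with_weights(np.full(s.n_members, 1.0 / s.n_members)
                                     if s.is_matched else np.empty(0))
                      for s in raw_sets]
        balance = balance_smd(equal_sets, refined, cov)
        pretrend = pretrend_check(refined, panel, spec.lags)
    else:
        balance = pretrend = pd.DataFrame()
    return DirectionRun(direction=direction, results=results, balance=balance,
                        pretrend=pretrend, tally=tally,
                        matched_sets=raw_sets, refined_sets=refined)


def _subgroup_masks(panel: Panel, name: str) -> dict:
    """Unit-level subgroup membership from baseline (first observed) values."""
    first = panel.data.sort_values("wave").groupby("unit").first()
    if name == "asset":
        base = first["asset"]
        med = base.median()
        return {"asset_below_median": set(base.index[base <= med]),
                "asset_above_median": set(base.index[base > med])}
    if name == "education":
        base = first["education"]
        return {"education_leq_highschool": set(base.index[base <= 2]),
                "education_above_highschool": set(base.index[base > 2])}
    if name == "sex":
        base = first["sex"]
        return {"sex_0": set(base.index[base == 0]),
                "sex_1": set(base.index[base == 1])}
    raise ValueError(f"unknown subgroup {name!r}")


def run(spec: RunSpec, outdir=None) -> RunResult:
    """Full analysis per direction (and subgroup); optionally write outputs."""
    panel = _load_panel(spec)
    log = [f"seed={spec.seed}",
           f"config_hash={_config_hash(spec)}",
           f"n_units={panel.n_units}", f"n_waves={panel.n_waves}"]
    all_results, balance, tallies = [], {}, {}
    for direction in spec.directions:
        dr = analyse_direction(panel, spec, direction)
        all_results.extend(dr.results)
        balance[direction] = dr.balance
        tallies[direction] = dr.tally
        log.append(f"{direction}: treated={dr.tally['n_treated_events']} "
                   f"controls={dr.tally['n_control_events']} "
                   f"unmatched={dr.tally['n_unmatched']}")

    subgroup_results = {}
    for name in spec.subgroups:
        rows = []
        for label, members in _subgroup_masks(panel, name).items():
            sub = panel.subset_units(members)
            for direction in spec.directions:
                try:
                    dr = analyse_direction(sub, spec, direction)
                    df = results_table(dr.results)
                    df.insert(0, "subgroup", label)
                    rows.append(df)
                except (EstimationError, RefinementError) as exc:
                    rows.append(pd.DataFrame([{
                        "subgroup": label, "direction": direction,
                        "F": np.nan, "adjustment": "NA",
                        "estimate": np.nan, "se": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan,
                        "n_treated": 0, "n_unmatched": 0,
                        "reason": str(exc)}]))
                    log.append(f"subgroup {label} {direction}: NA ({exc})")
        subgroup_results[name] = pd.concat(rows, ignore_index=True)

    result = RunResult(results=results_table(all_results), balance=balance,
                       tallies=tallies, log=log,
                       subgroup_results=subgroup_results)
    if outdir is not None:
        _write_outputs(result, spec, Path(outdir))
    return result


def _config_hash(spec: RunSpec) -> str:
    payload = {k: v for k, v in asdict(spec).items()}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_outputs(result: RunResult, spec: RunSpec, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"_{spec.tag}" if spec.tag else ""
    header = (f"# matchdid run  seed={spec.seed} lags={spec.lags} "
              f"leads={spec.leads} refinement={spec.refinement} "
              f"hash={_config_hash(spec)}\n")
    path = outdir / f"results{tag}.tsv"
    with open(path, "w") as fh:
        fh.write(header)
        result.results.to_csv(fh, sep="\t", index=False)
    for direction, table in result.balance.items():
        write_balance(table, outdir / f"balance_{direction}{tag}.tsv")
    with open(outdir / f"exclusions{tag}.tsv", "w") as fh:
        fh.write("direction\tstage\tcriterion\tcount\n")
        for direction, tally in result.tallies.items():
            for stage, counts in tally.items():
                if isinstance(counts, dict):
                    for crit, cnt in counts.items():
                        fh.write(f"{direction}\t{stage}\t{crit}\t{cnt}\n")
                else:
                    fh.write(f"{direction}\t-\t{stage}\t{counts}\n")
    for name, table in result.subgroup_results.items():
        table.to_csv(outdir / f"results_subgroup_{name}{tag}.tsv",
                     sep="\t", index=False)
    with open(outdir / f"run{tag}.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")
    with open(outdir / f"metadata{tag}.txt", "w") as fh:
        for k, v in asdict(spec).items():
            fh.write(f"{k}={v}\n")


def simulate_study(scenario: ScenarioConfig, n_sims: int, seed: int = 0,
                   directions=("entry",), leads=(0,),
                   adjustments=("adjusted",), lags: int = 3,
                   bootstrap_reps: int = 0, min_age: float | None = 65.0,
                   refinement: str = "cbps_weight") -> pd.DataFrame:
    """Monte-Carlo summary of estimator performance on a known scenario.

    Per (direction, adjustment, F) cell: mean estimate, bias against the
    scenario truth, empirical SE across simulations, RMSE and — when
    ``bootstrap_reps`` > 0 — the mean bootstrap SE and the coverage of the
    95% percentile interval.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.generate_state(2 * n_sims) % (2 ** 31)
    rows = []
    for s in range(n_sims):
        cfg = ScenarioConfig(**{**vars(scenario),
                                "seed": int(sim_seeds[2 * s])})
        panel, truth = generate(cfg)
        spec = RunSpec(directions=tuple(directions), lags=lags, leads=max(leads),
                       min_age=min_age, refinement=refinement,
                       bootstrap=BootstrapConfig(
                           reps=max(bootstrap_reps, 2),
                           seed=int(sim_seeds[2 * s + 1])),
                       seed=int(sim_seeds[2 * s]))
        for direction in directions:
            dr = analyse_direction(panel, spec, direction,
                                   with_bootstrap=bootstrap_reps > 0,
                                   adjustments=adjustments,
                                   with_diagnostics=False)
            for res in dr.results:
                if res.F not in leads:
                    continue
                if res.F == 0:
                    true_val = truth[f"tau_{direction}"]
                else:
                    true_val = truth[f"carryover_{direction}"]
                rows.append({"sim": s, "direction": direction,
                             "adjustment": res.adjustment, "F": res.F,
                             "estimate": res.estimate, "se": res.se,
                             "ci_low": res.ci_low, "ci_high": res.ci_high,
                             "truth": true_val,
                             "covered": (res.ci_low <= true_val <= res.ci_high)
                             if np.isfinite(res.se) else np.nan})
    per_sim = pd.DataFrame(rows)
    grp = per_sim.groupby(["direction", "adjustment", "F"])
    summary = grp.apply(lambda g: pd.Series({
        "mean_estimate": g["estimate"].mean(),
        "truth": g["truth"].iloc[0],
        "bias": (g["estimate"] - g["truth"]).mean(),
        "empirical_se": g["estimate"].std(ddof=1),
        "rmse": float(np.sqrt(((g["estimate"] - g["truth"]) ** 2).mean())),
        "mean_boot_se": g["se"].mean(),
        "coverage": g["covered"].mean(),
        "n_sims": len(g),
    }), include_groups=False).reset_index()
    summary.attrs["per_sim"] = per_sim
    return summary
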