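"""Synthetic longitudinal ageing cohorts with known ground truth.

The generator emulates the statistical structure of a biennial ageing panel
(2006-2020 by default): persistent two-state employment dynamics with
age-declining retention, a bounded integer cognition outcome with age-related
decline, socio-demographic covariates with documented dependencies,
absorbing attrition and item missingness.  It is deliberately a *structural*
emulation — marginal distributions match a real cohort only in order of
magnitude — but every mechanism the matched-DID design must handle is
switchable: confounded selection into transitions (on self-reported health
and the lagged cognition score), health-dependent decline slopes that make
the unadjusted contrast biased, a treated-specific pre-trend that violates
parallel trends, and carry-over effects one wave after a transition.

Ground truth (the injected effects and each unit's confounders) is returned
alongside the panel so recovery, null-calibration and coverage studies can
score the estimator against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .panel import DEFAULT_WAVE_YEARS, Panel


@dataclass
class ScenarioConfig:
    """Full parameterisation of the synthetic data-generating process.

    Probabilities are per biennial wave.  Effects are in score points of the
    cognition instrument, applied on the latent scale before rounding and
    clipping.  ``selection_strength`` scales how strongly the transition
    propensity loads on standardised health and lagged cognition when
    ``confounding_on``; ``health_slope_per_year`` makes worse health steepen
    the cognitive decline slope, which is what turns that selection into
    bias of the unadjusted estimator.
    """

    n_units: int = 2000
    wave_years: tuple = DEFAULT_WAVE_YEARS
    outcome_instrument: str = "mmse30"  # or "tics27"
    age_baseline: tuple = (55.0, 75.0)  # uniform bounds at the first wave
    # employment dynamics (biennial transition probabilities at age 65)
    p_stay_employed: float = 0.88
    p_stay_out: float = 0.90
    age_logit_slope: float = 0.05      # per year of age past 65
    p_employed_at_baseline: float = 0.55
    # treatment effects (score points)
    tau_entry: float = 0.65
    tau_exit: float = -0.44
    carryover_entry: float = 0.0
    carryover_exit: float = 0.0
    # confounding and violations
    confounding_on: bool = False
    selection_strength: float = 0.0
    selection_health_weight: float = 0.7
    selection_cog_weight: float = 0.3
    health_slope_per_year: float = 0.0
    pretrend_violation: float = 0.0    # extra slope (pts/wave) for ever-treated
    # outcome model
    cog_intercept: float = 24.0
    cog_education: float = 0.8
    decline_per_year: float = 0.08
    sd_unit: float = 2.0
    sd_noise: float = 1.5
    # missingness
    attrition_rate: float = 0.05
    covariate_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("p_stay_employed", "p_stay_out", "p_employed_at_baseline",
                     "attrition_rate", "covariate_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability")
        if self.outcome_instrument not in ("mmse30", "tics27"):
            raise ValueError("outcome_instrument must be 'mmse30' or 'tics27'")
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        self.wave_years = tuple(int(y) for y in self.wave_years)

    @property
    def instrument_range(self):
        return (0, 30) if self.outcome_instrument == "mmse30" else (0, 27)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def confounded_scenario(**overrides) -> ScenarioConfig:
    """Preset with selection on health and lagged cognition plus
    health-graded decline, strong enough to visibly bias the unadjusted
    contrast; the refinement step is expected to remove most of it."""
    base = dict(confounding_on=True, selection_strength=1.5,
                selection_health_weight=0.9, selection_cog_weight=0.1,
                health_slope_per_year=0.40, tau_entry=0.0, tau_exit=0.0)
    base.update(overrides)
    return ScenarioConfig(**base)


def _logit(p):
    return np.log(p / (1.0 - p))


def generate(config: ScenarioConfig):
    """Simulate one cohort.  Returns ``(panel, truth)``.

    ``truth`` holds the injected effects, per-unit confounders (baseline
    health, decline slope, unit intercept) and the realised entry/exit waves
    of every unit.  All randomness flows from ``config.seed``; the same
    config yields a byte-identical panel.
    """
    rng = np.random.default_rng(config.seed)
    n, waves = config.n_units, len(config.wave_years)
    lo, hi = config.instrument_range

    age0 = rng.uniform(*config.age_baseline, size=n)
    birth_year = config.wave_years[0] - age0
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    education = rng.choice(4, size=n, p=[0.30, 0.25, 0.30, 0.15]).astype(float)
    spouse = rng.binomial(1, np.clip(0.85 - 0.01 * (age0 - 65), 0.05, 0.95)
                          ).astype(float)
    # self-reported health: ordinal 1..5, better with education, worse with age
    health_latent = (0.25 * (education - 1.5) - 0.02 * (age0 - 65)
                     + rng.normal(size=n))
    health = np.digitize(health_latent, [-1.2, -0.4, 0.4, 1.2]) + 1.0
    occupation = np.clip(
        rng.choice(3, size=n, p=[0.25, 0.55, 0.20]) + (education >= 3), 0, 2
    ).astype(float)
    income_base = np.exp(rng.normal(2.5 + 0.25 * education, 0.6))
    asset_base = np.exp(rng.normal(4.0 + 0.30 * education, 0.9))
    unit_intercept = rng.normal(0.0, config.sd_unit, size=n)

    health_z = (health - 3.0) / 1.2
    slope = (config.decline_per_year
             + config.health_slope_per_year * (3.0 - health) / 2.0)

    employed = np.empty((n, waves))
    outcome = np.empty((n, waves))
    latent_noise = rng.normal(0.0, config.sd_noise, size=(n, waves))
    entry_wave = np.full((n, waves), False)
    exit_wave = np.full((n, waves), False)
    effect = np.zeros((n, waves))

    employed[:, 0] = rng.binomial(1, np.clip(
        config.p_employed_at_baseline - 0.02 * (age0 - 65), 0.02, 0.98))

    def cog_level(age):
        return (config.cog_intercept + config.cog_education * education
                + unit_intercept - slope * (age - 65.0))

    spacing = float(config.wave_years[1] - config.wave_years[0]) if waves > 1 else 2.0
    ages = age0[:, None] + spacing * np.arange(waves)[None, :]
    outcome[:, 0] = cog_level(ages[:, 0]) + latent_noise[:, 0]

    for w in range(1, waves):
        age = ages[:, w]
        prev_emp = employed[:, w - 1]
        prev_cog_z = (outcome[:, w - 1] - outcome[:, w - 1].mean()) / max(
            outcome[:, w - 1].std(), 1e-9)
        sel = 0.0
        if config.confounding_on:
            sel = config.selection_strength * (
                config.selection_health_weight * health_z
                + config.selection_cog_weight * prev_cog_z)
        stay_emp = _sigmoid(_logit(config.p_stay_employed)
                            - config.age_logit_slope * (age - 65) + sel)
        enter = _sigmoid(_logit(1.0 - config.p_stay_out)
                         - config.age_logit_slope * (age - 65) + sel)
        u = rng.uniform(size=n)
        employed[:, w] = np.where(prev_emp == 1, (u < stay_emp), (u < enter)
                                  ).astype(float)
        entered = (prev_emp == 0) & (employed[:, w] == 1)
        exited = (prev_emp == 1) & (employed[:, w] == 0)
        entry_wave[:, w], exit_wave[:, w] = entered, exited
        effect[entered, w] += config.tau_entry
        effect[exited, w] += config.tau_exit
        if w + 1 < waves:
            effect[entered, w + 1] += config.carryover_entry
            effect[exited, w + 1] += config.carryover_exit
        outcome[:, w] = cog_level(age) + effect[:, w] + latent_noise[:, w]

    if config.pretrend_violation != 0.0:
        # ever-treated units drift upward before their first transition
        first = np.where(entry_wave.any(axis=1),
                         entry_wave.argmax(axis=1), -1)
        for i in np.flatnonzero(first >= 0):
            w0 = first[i]
            drift = config.pretrend_violation * (np.arange(waves) - w0)
            outcome[i, :w0] += drift[:w0]

    outcome = np.clip(np.round(outcome), lo, hi)

    # absorbing attrition: once a unit misses a wave it never returns
    alive = np.ones((n, waves), dtype=bool)
    for w in range(1, waves):
        alive[:, w] = alive[:, w - 1] & (rng.uniform(size=n)
                                         >= config.attrition_rate)

    income = income_base[:, None] * np.exp(rng.normal(0, 0.15, size=(n, waves)))
    income *= np.where(employed == 1, 1.4, 1.0)
    asset = asset_base[:, None] * np.exp(rng.normal(0, 0.10, size=(n, waves)))
    health_wave = np.clip(
        health[:, None] + rng.choice([-1, 0, 0, 0, 1], size=(n, waves)), 1, 5
    ).astype(float)

    miss = rng.uniform(size=(n, waves, 3)) < config.covariate_missing_rate
    income[miss[:, :, 0]] = np.nan
    asset[miss[:, :, 1]] = np.nan
    health_wave[miss[:, :, 2]] = np.nan

    recs = []
    for w, year in enumerate(config.wave_years):
        sel_alive = np.flatnonzero(alive[:, w])
        recs.append(pd.DataFrame({
            "unit": [f"u{i:05d}" for i in sel_alive],
            "year": year,
            "employed": employed[sel_alive, w],
            "outcome": outcome[sel_alive, w],
            "age": ages[sel_alive, w],
            "age_sq": ages[sel_alive, w] ** 2,
            "sex": sex[sel_alive],
            "education": education[sel_alive],
            "spouse": spouse[sel_alive],
            "health": health_wave[sel_alive, w],
            "income": income[sel_alive, w],
            "asset": asset[sel_alive, w],
            "occupation": occupation[sel_alive],
            "pre1945": (birth_year[sel_alive] <= 1945).astype(float),
        }))
    panel = Panel(pd.concat(recs, ignore_index=True), config.wave_years,
                  config.instrument_range)
    truth = {
        "tau_entry": config.tau_entry, "tau_exit": config.tau_exit,
        "carryover_entry": config.carryover_entry,
        "carryover_exit": config.carryover_exit,
        "unit_ids": np.array([f"u{i:05d}" for i in range(n)]),
        "health": health, "slope": slope, "unit_intercept": unit_intercept,
        "entry_waves": entry_wave, "exit_waves": exit_wave,
    }
    return panel, truth


def _sigmoid(u):
    return 0.5 * (1.0 + np.tanh(0.5 * u))


# ---------------------------------------------------------------------------
# Hand-checkable fixtures

FIXTURE_NAMES = ("histories8", "unmatched", "tie_refine", "reuse")


def make_fixture(name: str) -> Panel:
    """Tiny deterministic panels (<=12 units, <=6 waves) for hand checks.

    ``histories8``  one control unit per length-3 employment history plus a
                    treated entry, so exact-history matching is enumerable.
    ``unmatched``   exactly one treated entry whose history no control shares.
    ``tie_refine``  a treated entry with identical-covariate controls that
                    tie under nearest-J refinement.
    ``reuse``       one control serving in two matched sets.
    """
    years = tuple(range(2006, 2017, 2))  # 6 waves, event wave t=4 (2014)

    def unit_rows(uid, emp, out, **cov):
        base = {"age": 66.0, "sex": 0.0, "health": 3.0, "income": 10.0}
        base.update(cov)
        return pd.DataFrame({
            "unit": uid, "year": years, "employed": emp,
            "outcome": out, **{k: v for k, v in base.items()}})

    frames = []
    if name == "histories8":
        # 8 controls covering all histories over waves 1..3; employed=0 at t=4
        for h in range(8):
            bits = [(h >> b) & 1 for b in (2, 1, 0)]
            frames.append(unit_rows(f"c{h}", [0, *bits, 0, 0],
                                    [25, 25, 25, 25, 25, 25]))
        frames.append(unit_rows("T", [0, 0, 0, 0, 1, 1],
                                [25, 25, 25, 25, 27, 27]))
    elif name == "unmatched":
        frames.append(unit_rows("T", [0, 0, 1, 0, 1, 1],
                                [25, 25, 25, 25, 27, 27]))
        frames.append(unit_rows("c0", [0, 0, 0, 0, 0, 0],
                                [24, 24, 24, 24, 24, 24]))
        frames.append(unit_rows("c1", [0, 1, 1, 0, 0, 0],
                                [24, 24, 24, 24, 24, 24]))
    elif name == "tie_refine":
        frames.append(unit_rows("T", [0, 0, 0, 0, 1, 1],
                                [25, 25, 25, 25, 27, 27], income=12.0))
        for j in range(3):
            frames.append(unit_rows(f"c{j}", [0, 0, 0, 0, 0, 0],
                                    [24, 24, 24, 24, 24, 24], income=10.0))
        frames.append(unit_rows("far", [0, 0, 0, 0, 0, 0],
                                [20, 20, 20, 20, 20, 20],
                                income=40.0, health=1.0))
    elif name == "reuse":
        frames.append(unit_rows("T1", [0, 0, 0, 0, 1, 1],
                                [25, 25, 25, 25, 27, 27]))
        frames.append(unit_rows("T2", [0, 0, 0, 0, 1, 1],
                                [26, 26, 26, 26, 28, 28]))
        frames.append(unit_rows("c0", [0, 0, 0, 0, 0, 0],
                                [24, 24, 24, 24, 24, 24]))
    else:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"choose from {FIXTURE_NAMES}")
    return Panel(pd.concat(frames, ignore_index=True), years, (0, 30))
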