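"""Cohort preparation: treatment coding, eligibility filtering, covariates.

The exposure of interest is a late-life employment transition between two
consecutive biennial waves.  *Entry* means non-employed at wave t-1 and
employed at wave t; the entry control state is non-employed at both waves.
*Exit* is the mirror image.  Each eligible (unit, t) pair with the required
origin state becomes a :data:`TreatmentEvent` row — treated when it
transitioned, control when it stayed — and a unit may contribute events at
several waves.

Eligibility mirrors flowchart-style sample construction: an event survives
only if the unit has employment and outcome observed at every wave from
t-L through t+Fmax (consecutive participation across L lags and Fmax leads)
and, optionally, is at least ``min_age`` at the transition wave.  Each filter
reports how many events it removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .panel import Panel

DIRECTIONS = ("entry", "exit")

#: events: DataFrame with columns unit, t, year, treated (bool) — one row per
#: classified (unit, wave) pair; row position is the event id used downstream.


class CohortError(ValueError):
    """Raised for invalid cohort-preparation inputs."""


def code_transitions(panel: Panel, direction: str, window=(2012, 2018)):
    """Classify every (unit, t) as treated / control for one direction.

    Returns ``(events, tally)`` where ``events`` has columns
    ``unit, t, year, treated`` and ``tally`` counts the (unit, wave) pairs
    skipped for unobserved employment or excluded for the wrong origin state.
    Only waves whose calendar year falls inside ``window`` (closed) are
    considered, and t must have a preceding wave.
    """
    if direction not in DIRECTIONS:
        raise CohortError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if panel.n_waves < 2:
        raise CohortError("panel needs at least two waves to code transitions")
    origin = 0.0 if direction == "entry" else 1.0
    dest_treated = 1.0 - origin
    E = panel.matrix("employed")
    lo, hi = window
    rows = []
    tally = {"candidates": 0, "unobserved_employment": 0, "wrong_origin": 0}
    for t, year in enumerate(panel.wave_years):
        if t == 0 or not (lo <= year <= hi):
            continue
        prev, cur = E[:, t - 1], E[:, t]
        tally["candidates"] += len(prev)
        observed = ~np.isnan(prev) & ~np.isnan(cur)
        tally["unobserved_employment"] += int((~observed).sum())
        at_origin = observed & (prev == origin)
        tally["wrong_origin"] += int((observed & ~at_origin).sum())
        for i in np.flatnonzero(at_origin):
            rows.append((panel.units[i], t, year, cur[i] == dest_treated))
    events = pd.DataFrame(rows, columns=["unit", "t", "year", "treated"])
    return events, tally


def apply_eligibility(panel: Panel, events: pd.DataFrame, lags: int = 3,
                      leads: int = 1, min_age=65, age_field: str = "age"):
    """Keep events observed at every wave t-lags .. t+leads; tally exclusions.

    Observed means employment *and* outcome non-missing at each of those
    waves.  ``min_age`` (None disables) additionally requires the unit's
    ``age_field`` at the transition wave to be at least that value.  Filters
    apply sequentially, so the tally reads like a sample flowchart and its
    counts conserve: input = kept + sum(excluded).
    """
    if lags < 0 or leads < 0:
        raise CohortError("need lags >= 0 and leads >= 0")
    tally = {"input": len(events), "outside_wave_range": 0,
             "incomplete_employment": 0, "incomplete_outcome": 0,
             "below_min_age": 0}
    if len(events) == 0:
        tally["kept"] = 0
        return events.copy(), tally
    E, O = panel.matrix("employed"), panel.matrix("outcome")
    urow = panel.unit_rows(events["unit"].to_numpy())
    t = events["t"].to_numpy()
    keep = (t - lags >= 0) & (t + leads <= panel.n_waves - 1)
    tally["outside_wave_range"] = int((~keep).sum())

    # span-completeness checks on the survivors of the range check
    def span_ok(M):
        ok = np.ones(len(events), dtype=bool)
        for j in np.flatnonzero(keep):
            w = slice(t[j] - lags, t[j] + leads + 1)
            ok[j] = not np.isnan(M[urow[j], w]).any()
        return ok

    emp_ok = span_ok(E)
    tally["incomplete_employment"] = int((keep & ~emp_ok).sum())
    keep &= emp_ok
    out_ok = span_ok(O)
    tally["incomplete_outcome"] = int((keep & ~out_ok).sum())
    keep &= out_ok

    if min_age is not None and age_field in panel.covariate_columns:
        age = panel.matrix(age_field)[urow, t]
        age_ok = ~np.isnan(age) & (age >= min_age)
        tally["below_min_age"] = int((keep & ~age_ok).sum())
        keep &= age_ok

    kept = events[keep].reset_index(drop=True)
    tally["kept"] = len(kept)
    return kept, tally


@dataclass
class CovariateSpec:
    """Which covariates enter the balancing model, and how.

    ``time_invariant`` variables are taken at the transition wave t;
    ``time_varying`` variables (plus the lagged outcome itself when
    ``include_lagged_outcome``) are taken at each of waves t-1 .. t-lags,
    so their trajectories are matched.  ``tertile_vars`` are replaced by
    their within-wave tertile rank (1/2/3) computed over the event-eligible
    sample — relative economic position, not absolute amounts.  Variables in
    ``missing_indicator_vars`` contribute a 0-filled value plus a 0/1
    observedness indicator per slot (classic dummy adjustment); any other
    variable must be fully observed.  ``categorical`` maps a variable to its
    ordered level list, first level = reference, one-hot encoded.
    """

    time_invariant: list = dc_field(default_factory=list)
    time_varying: list = dc_field(default_factory=list)
    lags: int = 3
    include_lagged_outcome: bool = True
    tertile_vars: list = dc_field(default_factory=list)
    missing_indicator_vars: list = dc_field(default_factory=list)
    categorical: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.time_invariant) & set(self.time_varying)
        if overlap:
            raise CohortError(f"variables {sorted(overlap)} listed as both "
                              "time-invariant and time-varying")
        known = set(self.time_invariant) | set(self.time_varying)
        stray = set(self.tertile_vars) - known
        if stray:
            raise CohortError(f"tertile_vars {sorted(stray)} not in the spec")


@dataclass
class EventCovariates:
    """Flattened covariate-history matrix for a set of events.

    ``X`` has one row per event (index = event id) and one numeric column per
    encoded feature slot; ``meta`` records for every column its source
    variable, lag (0 = measured at t) and kind (value / indicator / onehot).
    """

    X: pd.DataFrame
    meta: pd.DataFrame
    events: pd.DataFrame


def _tertile_rank(values: np.ndarray) -> np.ndarray:
    """Map values to tertile ranks 1/2/3 (NaN passes through)."""
    out = np.full(values.shape, np.nan)
    obs = ~np.isnan(values)
    if obs.sum() == 0:
        return out
    q1, q2 = np.quantile(values[obs], [1 / 3, 2 / 3])
    v = values[obs]
    out[obs] = 1.0 + (v > q1) + (v > q2)
    return out


def build_covariates(panel: Panel, events: pd.DataFrame,
                     spec: CovariateSpec) -> EventCovariates:
    """Build the flat per-event covariate-history matrix.

    Tertile cut-points are computed per wave within the event-eligible
    sample (units contributing at least one event), so the transform encodes
    relative position at that wave and is invariant to monotone rescaling of
    the raw amounts.
    """
    for v in spec.time_invariant + spec.time_varying:
        if v not in panel.covariate_columns:
            raise CohortError(f"covariate {v!r} not present in panel")
    if len(events) == 0:
        raise CohortError("no events to build covariates for")

    urow = panel.unit_rows(events["unit"].to_numpy())
    t = events["t"].to_numpy()
    elig_units = panel.unit_rows(events["unit"].unique())

    mats = {}
    for v in set(spec.time_invariant) | set(spec.time_varying):
        M = panel.matrix(v).copy()
        if v in spec.tertile_vars:
            T = np.full_like(M, np.nan)
            for w in range(panel.n_waves):
                T[elig_units, w] = _tertile_rank(M[elig_units, w])
            M = T
        mats[v] = M
    mats["outcome"] = panel.matrix("outcome")

    cols, meta = {}, []

    def emit(name, var, lag, raw, kind="value"):
        if np.isnan(raw).all():
            raise CohortError(f"covariate {var!r} is missing for every event "
                              f"(slot {name})")
        if var in spec.missing_indicator_vars:
            ind = (~np.isnan(raw)).astype(float)
            cols[name] = np.nan_to_num(raw, nan=0.0)
            cols[name + "_obs"] = ind
            meta.append((name, var, lag, kind))
            meta.append((name + "_obs", var, lag, "indicator"))
        else:
            if np.isnan(raw).any():
                raise CohortError(
                    f"covariate {var!r} has missing values at slot {name}; "
                    "list it in missing_indicator_vars or complete it")
            cols[name] = raw
            meta.append((name, var, lag, kind))

    for v in spec.time_invariant:
        raw = mats[v][urow, t]
        if v in spec.categorical:
            levels = list(spec.categorical[v])
            for lev in levels[1:]:
                emit(f"{v}={lev}", v, 0, (raw == lev).astype(float)
                     + np.where(np.isnan(raw), np.nan, 0.0), kind="onehot")
        else:
            emit(v, v, 0, raw)

    tv = list(spec.time_varying) + (["outcome"] if spec.include_lagged_outcome else [])
    for v in tv:
        for k in range(1, spec.lags + 1):
            raw = mats[v][urow, t - k]
            if v in spec.categorical:
                levels = list(spec.categorical[v])
                for lev in levels[1:]:
                    emit(f"{v}={lev}_lag{k}", v, k,
                         (raw == lev).astype(float)
                         + np.where(np.isnan(raw), np.nan, 0.0), kind="onehot")
            else:
                emit(f"{v}_lag{k}", v, k, raw)

    X = pd.DataFrame(cols, index=events.index)
    meta = pd.DataFrame(meta, columns=["column", "var", "lag", "kind"])
    return EventCovariates(X=X, meta=meta, events=events)


def harmonise_currency(values, ppp_factor: float, deflator: float) -> np.ndarray:
    """Convert local-currency amounts to thousands of reference currency.

    ``value * deflator / ppp_factor / 1000`` — a strictly monotone scaling,
    so downstream tertile ranks are unaffected by the factors chosen.  The
    PPP factor and deflator are user-supplied (no lookup tables here).
    """
    if ppp_factor <= 0 or deflator <= 0:
        raise CohortError("ppp_factor and deflator must be positive")
    return np.asarray(values, dtype=float) * deflator / ppp_factor / 1000.0
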