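"""The matched difference-in-differences estimator.

For a treated event at (i, t) and lead F, the event's contribution is its
own outcome change from the base wave t-1 to t+F minus the weight-averaged
change of its matched controls over the same waves:

    (Cog_{i,t+F} - Cog_{i,t-1}) - sum_{i' in M_it} w_{it}^{i'} (Cog_{i',t+F} - Cog_{i',t-1})

The point estimate averages these contributions over all treated events with
a non-empty matched set; unmatched treated events are excluded and counted.
The estimand is the average effect of the transition on the treated, in
score points of the cognition instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Panel


class EstimationError(RuntimeError):
    """No estimable events, or an outcome needed by the contrast is missing."""


@dataclass
class EstimatorConfig:
    """Lag/lead geometry and refinement choice for one analysis run."""

    direction: str = "entry"
    lags: int = 3
    leads: int = 1
    refinement: str = "cbps_weight"

    def __post_init__(self):
        if self.lags < 1:
            raise ValueError("lags must be >= 1")
        if self.leads < 0:
            raise ValueError("leads must be >= 0")


@dataclass
class DIDResult:
    """One (direction, lead, adjustment) cell of the results table."""

    direction: str
    F: int
    adjustment: str
    estimate: float
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_treated: int = 0
    n_unmatched: int = 0


def event_contributions(matched_sets, panel: Panel, F: int = 0):
    """Per treated-matched-event DID contributions (in event order)."""
    O = panel.matrix("outcome")
    uidx = {u: i for i, u in enumerate(panel.units)}
    contribs = []
    for s in matched_sets:
        if not s.is_matched:
            continue
        i = uidx[s.unit]
        d_treated = O[i, s.t + F] - O[i, s.t - 1]
        rows = [uidx[u] for u in s.member_units]
        d_ctrl = O[rows, s.t + F] - O[rows, s.t - 1]
        if np.isnan(d_treated) or np.isnan(d_ctrl).any():
            raise EstimationError(
                f"missing outcome in the contrast window for event "
                f"{s.event_id} (unit {s.unit}, t={s.t}, F={F}); "
                "eligibility filtering must cover t-1 .. t+F")
        contribs.append(d_treated - float(s.weights @ d_ctrl))
    return np.array(contribs)


def estimate_did(matched_sets, panel: Panel, F: int = 0,
                 direction: str = "entry",
                 adjustment: str = "adjusted") -> DIDResult:
    """Point estimate over refined matched sets at lead F."""
    contribs = event_contributions(matched_sets, panel, F)
    if len(contribs) == 0:
        raise EstimationError("no estimable events: every treated event is "
                              "unmatched or the set list is empty")
    return DIDResult(direction=direction, F=F, adjustment=adjustment,
                     estimate=float(contribs.mean()),
                     n_treated=len(contribs),
                     n_unmatched=sum(not s.is_matched for s in matched_sets))


def estimate_unadjusted(matched_sets, panel: Panel, F: int = 0,
                        direction: str = "entry") -> DIDResult:
    """Same contrast on equal-weight (unrefined) matched sets.

    Accepts refined sets too: weights are reset to equal within each set, so
    callers can pass either the raw or the refined list, provided the member
    lists are the unpruned ones.
    """
    equal = [s.with_weights(np.full(s.n_members, 1.0 / s.n_members)
                            if s.is_matched else np.empty(0))
             for s in matched_sets]
    return estimate_did(equal, panel, F, direction, adjustment="unadjusted")


def results_table(results) -> pd.DataFrame:
    """Flat results table mirroring a published DID summary layout."""
    rows = [{"direction": r.direction, "F": r.F, "adjustment": r.adjustment,
             "estimate": r.estimate, "se": r.se, "ci_low": r.ci_low,
             "ci_high": r.ci_high, "n_treated": r.n_treated,
             "n_unmatched": r.n_unmatched} for r in results]
    return pd.DataFrame(rows)


def write_results(results, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    results_table(results).to_csv(path, sep="\t", index=False)
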