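"""Exact treatment-history matching.

For every treated event at (i, t) the matched set collects all eligible
control events at the *same* wave t whose employment vector over waves
t-L .. t equals the treated unit's everywhere except at t itself (controls
by definition keep the origin state at t).  Because treated and control
events for one direction share the origin state at t-1, matching reduces to
equality of the L-wave history over t-L .. t-1, which is done by hashing
history tuples — O(events) rather than O(events^2).

A treated event with no history-sharing control is flagged unmatched and
excluded from estimation (its count is reported).  A control unit may serve
in any number of matched sets; reuse is handled by the estimator's weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Panel


@dataclass
class MatchedSet:
    """Controls matched to one treated event, with refinement weights."""

    event_id: int
    unit: object
    t: int
    member_event_ids: np.ndarray
    member_units: np.ndarray
    weights: np.ndarray
    refinement: str = "none"

    @property
    def n_members(self) -> int:
        return len(self.member_units)

    @property
    def is_matched(self) -> bool:
        return self.n_members > 0

    def with_weights(self, weights, member_idx=None, refinement="none"):
        """Copy with new weights, optionally restricted to ``member_idx``."""
        ids, units = self.member_event_ids, self.member_units
        if member_idx is not None:
            ids, units = ids[member_idx], units[member_idx]
        w = np.asarray(weights, dtype=float)
        if len(w) != len(ids):
            raise ValueError("weight length does not match members")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if len(w) and not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        return replace(self, member_event_ids=ids, member_units=units,
                       weights=w, refinement=refinement)


def build_matched_sets(events: pd.DataFrame, panel: Panel,
                       lags: int = 3) -> list:
    """Matched sets (equal weights, refinement="none") for all treated events.

    ``events`` must already have passed eligibility so every history window
    is fully observed.  Returns one :class:`MatchedSet` per treated event,
    in event order; unmatched events appear with an empty member list.
    """
    E = panel.matrix("employed")
    urow = panel.unit_rows(events["unit"].to_numpy()) if len(events) else np.array([], int)
    sets = []
    for t in sorted(events["t"].unique()):
        at_t = np.flatnonzero((events["t"] == t).to_numpy())
        hists = {}
        for j in at_t:
            h = tuple(E[urow[j], t - lags:t])
            hists.setdefault(h, {"treated": [], "control": []})[
                "treated" if events["treated"].iat[j] else "control"].append(j)
        for h, grp in hists.items():
            ctrl = grp["control"]
            ids = np.array([events.index[j] for j in ctrl], dtype=int)
            units = np.array([events["unit"].iat[j] for j in ctrl], dtype=object)
            n = len(ctrl)
            for j in grp["treated"]:
                sets.append(MatchedSet(
                    event_id=int(events.index[j]),
                    unit=events["unit"].iat[j], t=int(t),
                    member_event_ids=ids.copy(), member_units=units.copy(),
                    weights=np.full(n, 1.0 / n) if n else np.empty(0),
                ))
    sets.sort(key=lambda s: s.event_id)
    return sets


def n_unmatched(matched_sets) -> int:
    return sum(not s.is_matched for s in matched_sets)


def write_matched_sets(matched_sets, path) -> None:
    """Audit dump: one row per (treated event, member) with its weight."""
    rows = []
    for s in matched_sets:
        if not s.is_matched:
            rows.append((s.event_id, s.unit, s.t, "", "", np.nan, s.refinement))
        for eid, u, w in zip(s.member_event_ids, s.member_units, s.weights):
            rows.append((s.event_id, s.unit, s.t, eid, u, w, s.refinement))
    df = pd.DataFrame(rows, columns=["event_id", "treated_unit", "t",
                                     "member_event_id", "member_unit",
                                     "weight", "refinement"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
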