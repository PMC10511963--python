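"""Balance and parallel-trend diagnostics for the matched design.

The balance metric is the standardised mean difference (SMD): for each
covariate-history slot, the treated-event mean minus the average of each
matched set's weighted control mean, divided by the standard deviation among
treated events.  Dividing by the treated SD (rather than a pooled SD) is the
convention in matching diagnostics, and it keeps before/after comparisons on
one denominator.  SMDs near zero for the pre-treatment outcome — levels and
wave-to-wave changes — are the observable face of the parallel-trend
assumption; these tables are a tabular stand-in for the usual visual checks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EventCovariates
from .panel import Panel


def _smd(treated_vals: np.ndarray, control_means: np.ndarray):
    sd = treated_vals.std(ddof=1) if len(treated_vals) > 1 else 0.0
    gap = treated_vals.mean() - control_means.mean()
    if sd <= 1e-12:
        return (0.0, False) if abs(gap) <= 1e-12 else (np.nan, True)
    return (float(gap / sd), False)


def _set_control_means(matched_sets, arr: np.ndarray, pos: dict) -> np.ndarray:
    """Row r = weighted control mean of every column for the r-th matched set."""
    rows = []
    for s in matched_sets:
        if not s.is_matched:
            continue
        mp = np.fromiter((pos[int(e)] for e in s.member_event_ids), dtype=int,
                         count=s.n_members)
        rows.append(s.weights @ arr[mp])
    return np.asarray(rows)


def balance_smd(sets_before, sets_after, cov: EventCovariates) -> pd.DataFrame:
    """SMD of every covariate-history slot before and after refinement.

    ``sets_before`` carry equal weights over the full matched sets,
    ``sets_after`` the refined weights (possibly pruned members).  Returns a
    table keyed by (column, var, lag) with ``smd_before``, ``smd_after`` and
    an ``undefined`` flag for slots with zero treated SD but unequal means.
    """
    arr = cov.X.to_numpy(dtype=float)
    pos = {int(eid): i for i, eid in enumerate(cov.X.index)}
    tpos = np.array([pos[s.event_id] for s in sets_before if s.is_matched])
    cm_before = _set_control_means(sets_before, arr, pos)
    cm_after = _set_control_means(sets_after, arr, pos)
    rows = []
    for j, (_, m) in enumerate(cov.meta.iterrows()):
        tv = arr[tpos, j]
        before, und_b = _smd(tv, cm_before[:, j])
        after, und_a = _smd(tv, cm_after[:, j])
        rows.append({"column": m["column"], "var": m["var"], "lag": m["lag"],
                     "smd_before": before, "smd_after": after,
                     "undefined": und_b or und_a})
    return pd.DataFrame(rows)


def pretrend_check(matched_sets, panel: Panel, lags: int = 3) -> pd.DataFrame:
    """Post-refinement SMDs of pre-treatment outcome levels and changes.

    Levels at waves t-1 .. t-L and lag-to-lag changes within t-L .. t-1
    (L-1 change rows).  Under parallel trends the change SMDs should sit
    near zero; a treated-specific pre-trend shows up as a systematic
    change-SMD away from zero.
    """
    O = panel.matrix("outcome")
    uidx = {u: i for i, u in enumerate(panel.units)}
    live = [s for s in matched_sets if s.is_matched]
    trow = np.array([uidx[s.unit] for s in live])
    tt = np.array([s.t for s in live])
    mrows = [np.array([uidx[u] for u in s.member_units]) for s in live]
    rows = []

    def smd_of(value_at, label, lag):
        tvals = value_at(trow, tt)
        cmeans = np.array([float(s.weights @ value_at(mr, np.full(len(mr), s.t)))
                           for s, mr in zip(live, mrows)])
        smd, und = _smd(tvals, cmeans)
        rows.append({"quantity": label, "lag": lag, "smd": smd,
                     "undefined": und})

    for k in range(1, lags + 1):
        smd_of(lambda r, t, k=k: O[r, t - k], f"outcome level t-{k}", k)
    for k in range(1, lags):
        smd_of(lambda r, t, k=k: O[r, t - k] - O[r, t - k - 1],
               f"outcome change (t-{k + 1} to t-{k})", k)
    return pd.DataFrame(rows)


def write_balance(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
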