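"""Weighted block bootstrap for the matched DID estimator.

The block is a unit's entire time series: resampling whole units preserves
within-person dependence across waves.  The estimator decomposes into
per-unit pieces

    estimate = sum_j c_j / sum_j d_j

where, for unit j, ``d_j`` counts its treated-and-matched events and
``c_j`` collects its own outcome changes as a treated unit minus its
weight-times-change terms over every matched-set membership.  Refinement
weights are frozen — they are part of the estimator, which is what makes
this the *weighted* block bootstrap.  Each replicate draws n units with
replacement and recomputes the ratio; replicates whose resample contains no
treated-matched unit are redrawn (counted, warned about when frequent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimator import DIDResult, EstimationError
from .panel import Panel


@dataclass
class BootstrapConfig:
    reps: int = 1000
    seed: int = 0
    ci_mode: str = "percentile"  # or "normal"

    def __post_init__(self):
        if self.reps < 2:
            raise ValueError("bootstrap needs reps >= 2")
        if self.ci_mode not in ("percentile", "normal"):
            raise ValueError("ci_mode must be 'percentile' or 'normal'")


def unit_decomposition(matched_sets, panel: Panel, F: int = 0):
    """Per-unit (c_j, d_j) in canonical unit order; sum c / sum d = estimate."""
    O = panel.matrix("outcome")
    uidx = {u: i for i, u in enumerate(panel.units)}
    c = np.zeros(panel.n_units)
    d = np.zeros(panel.n_units)
    for s in matched_sets:
        if not s.is_matched:
            continue
        i = uidx[s.unit]
        rows = np.array([uidx[u] for u in s.member_units])
        d_treated = O[i, s.t + F] - O[i, s.t - 1]
        d_ctrl = O[rows, s.t + F] - O[rows, s.t - 1]
        if np.isnan(d_treated) or np.isnan(d_ctrl).any():
            raise EstimationError(f"missing outcome in contrast window for "
                                  f"event {s.event_id}")
        c[i] += d_treated
        d[i] += 1.0
        np.add.at(c, rows, -s.weights * d_ctrl)
    return c, d


def block_bootstrap(matched_sets, panel: Panel, F: int = 0,
                    config: BootstrapConfig | None = None,
                    direction: str = "entry",
                    adjustment: str = "adjusted") -> DIDResult:
    """DIDResult with the point estimate, bootstrap SE and 95% interval."""
    config = config or BootstrapConfig()
    c, d = unit_decomposition(matched_sets, panel, F)
    d_total = d.sum()
    if d_total == 0:
        raise EstimationError("no estimable events: nothing to bootstrap")
    estimate = float(c.sum() / d_total)

    n = panel.n_units
    rng = np.random.default_rng(config.seed)
    prob = np.full(n, 1.0 / n)
    counts = rng.multinomial(n, prob, size=config.reps)
    den = counts @ d
    n_redrawn = 0
    while (den == 0).any():
        bad = np.flatnonzero(den == 0)
        n_redrawn += len(bad)
        counts[bad] = rng.multinomial(n, prob, size=len(bad))
        den = counts @ d
    if n_redrawn > 0.01 * config.reps:
        warnings.warn(f"{n_redrawn} bootstrap replicates redrawn for having "
                      "no treated-matched unit (>1% of reps)")
    stats = (counts @ c) / den
    se = float(stats.std(ddof=1))
    if config.ci_mode == "percentile":
        ci_low, ci_high = (float(v) for v in np.percentile(stats, [2.5, 97.5]))
    else:
        ci_low, ci_high = estimate - 1.96 * se, estimate + 1.96 * se
    return DIDResult(direction=direction, F=F, adjustment=adjustment,
                     estimate=estimate, se=se, ci_low=ci_low, ci_high=ci_high,
                     n_treated=int(round(d_total)),
                     n_unmatched=sum(not s.is_matched for s in matched_sets))
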