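"""Matched-set refinement by covariate-history balancing.

Exact history matching leaves covariate imbalance inside each matched set;
refinement re-weights (or prunes) the controls so that their pre-treatment
covariate trajectories resemble the treated unit's.  Four methods:

``mahalanobis``
    Keep the J controls with the smallest average per-wave Mahalanobis
    distance to the treated unit, equal weights.
``ps_match``
    Fit a pooled logistic propensity score of treated-vs-matched-control on
    the flattened covariate history; keep the J controls with the nearest
    scores, equal weights.
``ps_weight``
    Weight each control by its fitted odds e/(1-e), renormalised within the
    matched set.
``cbps_weight``
    Same weighting rule, but the score is fitted by covariate-balancing
    estimating equations (just-identified CBPS) instead of maximum
    likelihood — the weights are chosen to force balance of the covariate
    moments, not to fit the data best.  This is the analysis default.

Scores are fitted once, pooled over all treated events and the unique
controls appearing in any matched set for that direction; per-set fits would
be underdetermined.  All methods leave non-negative weights summing to one
within each non-empty set, and re-applying a fitted model is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .cohort import EventCovariates

METHODS = ("mahalanobis", "ps_match", "ps_weight", "cbps_weight")


class RefinementError(RuntimeError):
    """A refinement model failed to fit (separation, non-convergence)."""


def _sigmoid(u):
    return 0.5 * (1.0 + np.tanh(0.5 * u))


@dataclass
class LogisticScore:
    """A fitted linear-logistic score on standardised features."""

    beta: np.ndarray            # intercept first, standardised scale
    means: np.ndarray
    sds: np.ndarray
    columns: list
    fit_method: str = "mle"
    max_moment: float = np.nan  # CBPS balance residual at the solution

    def linpred(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.columns].to_numpy(dtype=float) - self.means) / self.sds
        return self.beta[0] + Z @ self.beta[1:]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return _sigmoid(self.linpred(X))


def _standardise(X: pd.DataFrame):
    arr = X.to_numpy(dtype=float)
    means, sds = arr.mean(axis=0), arr.std(axis=0)
    keep = sds > 1e-12
    if not keep.all():
        dropped = [c for c, k in zip(X.columns, keep) if not k]
        warnings.warn(f"dropping constant covariate columns {dropped} "
                      "before score fitting")
    cols = [c for c, k in zip(X.columns, keep) if k]
    return (arr[:, keep] - means[keep]) / sds[keep], means[keep], sds[keep], cols


def fit_logistic_mle(treated: np.ndarray, X: pd.DataFrame) -> LogisticScore:
    """Plain logistic-regression score (standardised features, intercept)."""
    Z, means, sds, cols = _standardise(X)
    T = np.asarray(treated, dtype=float)
    design = sm.add_constant(Z, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(T, design).fit(disp=0, method="lbfgs", maxiter=500)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise RefinementError(f"logistic score failed to fit: {exc}") from exc
    beta = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 50:
        raise RefinementError(
            "logistic score diverged (groups look perfectly separable on the "
            "covariate history); refinement scores are not identified")
    return LogisticScore(beta, means, sds, cols, fit_method="mle")


def fit_cbps(treated: np.ndarray, X: pd.DataFrame, *, tol: float = 1e-8,
             max_iter: int = 200) -> LogisticScore:
    """Just-identified covariate-balancing propensity score for the ATT.

    Solves the balance estimating equations

        mean_e [ (T_e - (1 - T_e) * pi(x_e) / (1 - pi(x_e))) * x~_e ] = 0

    with pi the logistic function of the linear score and x~ the
    standardised features plus an intercept.  This is the treated-target
    form of the balancing conditions: at the root, the odds-weighted
    control covariate means equal the unweighted treated means *exactly* —
    the same e/(1-e) weighting the refinement applies, so the fitted
    balance carries over to the estimator.  (The average-treatment-effect
    form divides the residual by pi(1-pi) instead; it balances
    inverse-propensity-weighted means of both groups, which is not the
    weighting this design uses.)

    The moment function is the gradient of a strictly concave objective, so
    a damped Newton ascent started at the logistic MLE converges globally
    whenever a root exists.  Convergence: max |mean moment| < ``tol``.
    """
    T_raw = np.asarray(treated, dtype=float)
    # a feature constant within either group has no finite balance root:
    # matching a degenerate point forces boundary propensities, so the
    # just-identified equations are only posed for two-sided variation
    degenerate = [c for c in X.columns
                  if X.loc[T_raw == 1, c].std() <= 1e-12
                  or X.loc[T_raw == 0, c].std() <= 1e-12]
    if degenerate:
        warnings.warn("dropping features without variation in both groups "
                      f"from the CBPS balance conditions: {degenerate}")
        X = X.drop(columns=degenerate)
    mle = fit_logistic_mle(treated, X)
    Z = (X[mle.columns].to_numpy(dtype=float) - mle.means) / mle.sds
    design = np.column_stack([np.ones(len(Z)), Z])
    T = np.asarray(treated, dtype=float)
    n = len(T)

    def odds(beta):
        return np.exp(np.clip(design @ beta, -700.0, 80.0))

    def moments(beta):
        f = T - (1 - T) * odds(beta)
        return design.T @ f / n, None

    def jac(beta):
        dfdu = -(1 - T) * odds(beta)
        return design.T @ (design * dfdu[:, None]) / n

    sol = optimize.root(lambda b: moments(b)[0], mle.beta, jac=jac,
                        method="hybr", options={"maxfev": 400 * len(mle.beta)})
    beta = sol.x
    g, _ = moments(beta)
    # damped-Newton polish: hybr stops at its own xtol, the balance
    # moments must still be driven to tol
    for _ in range(max_iter):
        if np.abs(g).max() < tol:
            break
        step, *_ = np.linalg.lstsq(jac(beta), g, rcond=None)
        alpha, norm0 = 1.0, np.linalg.norm(g)
        for _ in range(50):
            cand = beta - alpha * step
            g_new, _ = moments(cand)
            if np.linalg.norm(g_new) < norm0:
                beta, g = cand, g_new
                break
            alpha *= 0.5
        else:
            break
    if np.abs(g).max() >= tol:
        raise RefinementError(
            f"CBPS balance equations did not converge (max moment "
            f"{np.abs(g).max():.2e} > {tol}); consider the ps_weight fallback")
    return LogisticScore(beta, mle.means, mle.sds, mle.columns,
                         fit_method="cbps", max_moment=float(np.abs(g).max()))


@dataclass
class RefinementModel:
    """A fitted refinement ready to be applied to matched sets."""

    method: str
    size_match: int = 5
    score: LogisticScore | None = None
    feature_names: list = dc_field(default_factory=list)

    def __post_init__(self):
        if self.method not in METHODS:
            raise RefinementError(f"unknown refinement method {self.method!r}")
        if self.size_match < 1:
            raise RefinementError("size_match J must be >= 1")


def _pooled_sample(matched_sets, cov: EventCovariates):
    """Unique treated + control event ids entering the score fit."""
    treated_ids = [s.event_id for s in matched_sets if s.is_matched]
    control_ids = sorted({int(eid) for s in matched_sets
                          for eid in s.member_event_ids})
    ids = treated_ids + [c for c in control_ids if c not in set(treated_ids)]
    flags = np.array([1] * len(treated_ids)
                     + [0] * (len(ids) - len(treated_ids)), dtype=float)
    return ids, flags


def fit_refinement(matched_sets, cov: EventCovariates, method: str,
                   size_match: int = 5, **cbps_kwargs) -> RefinementModel:
    """Fit the score (if the method needs one) pooled over all matched sets."""
    model = RefinementModel(method=method, size_match=size_match,
                            feature_names=list(cov.X.columns))
    if method in ("ps_match", "ps_weight", "cbps_weight"):
        ids, flags = _pooled_sample(matched_sets, cov)
        Xfit = cov.X.loc[ids]
        if method == "cbps_weight":
            model.score = fit_cbps(flags, Xfit, **cbps_kwargs)
        else:
            model.score = fit_logistic_mle(flags, Xfit)
    return model


def _tiebreak_order(keys, units):
    """Ascending by key, ties broken by unit id (string order): reproducible."""
    return sorted(range(len(keys)), key=lambda i: (keys[i], str(units[i])))


def _wave_covariances(matched_sets, cov: EventCovariates, blocks):
    """Inverse covariance of the time-varying block, per calendar wave.

    Pooled over every event's lag-k vector measured at that wave; a singular
    matrix falls back to the diagonal (variances only) with a warning.
    """
    t = cov.events["t"]
    rows_by_wave = {}
    for k, colpos in blocks.items():
        arr = cov.X.iloc[:, colpos].to_numpy(dtype=float)
        for w in np.unique(t.to_numpy() - k):
            sel = (t.to_numpy() - k) == w
            rows_by_wave.setdefault(int(w), []).append(arr[sel])
    inv = {}
    for w, chunks in rows_by_wave.items():
        M = np.vstack(chunks)
        S = np.cov(M, rowvar=False)
        S = np.atleast_2d(S)
        if not np.all(np.isfinite(S)) or np.linalg.matrix_rank(S) < S.shape[0]:
            warnings.warn(f"singular covariance at wave {w}; "
                          "falling back to diagonal")
            d = np.clip(np.diag(S), 1e-12, None)
            inv[w] = np.diag(1.0 / d)
        else:
            inv[w] = np.linalg.inv(S)
    return inv


def refine(matched_sets, cov: EventCovariates,
           model: RefinementModel) -> list:
    """Apply a fitted refinement, returning matched sets with new weights.

    Deterministic given the fitted model: nearest-J ties are broken by unit
    id order, and weighting methods renormalise within each set.  Unmatched
    sets pass through unchanged.
    """
    J = model.size_match
    out = []
    if model.method == "mahalanobis":
        lags = sorted(cov.meta.loc[cov.meta["lag"] > 0, "lag"].unique())
        colindex = {c: i for i, c in enumerate(cov.X.columns)}
        blocks = {}
        for k in lags:
            cols = cov.meta.loc[cov.meta["lag"] == k, "column"]
            blocks[k] = [colindex[c] for c in cols]
        winv = _wave_covariances(matched_sets, cov, blocks)
        Xarr = cov.X.to_numpy(dtype=float)
        pos = {eid: i for i, eid in enumerate(cov.X.index)}
    elif model.score is not None:
        lp = pd.Series(model.score.linpred(cov.X), index=cov.X.index)

    for s in matched_sets:
        if not s.is_matched:
            out.append(s.with_weights(np.empty(0), refinement=model.method))
            continue
        if model.method == "mahalanobis":
            ti = pos[s.event_id]
            dists = []
            for eid in s.member_event_ids:
                ci = pos[int(eid)]
                d = 0.0
                for k in blocks:
                    diff = Xarr[ti, blocks[k]] - Xarr[ci, blocks[k]]
                    d += float(np.sqrt(max(diff @ winv[s.t - k] @ diff, 0.0)))
                dists.append(d / len(blocks))
            order = _tiebreak_order(dists, s.member_units)[:J]
            w = np.full(len(order), 1.0 / len(order))
            out.append(s.with_weights(w, member_idx=np.array(order, int),
                                      refinement=model.method))
        elif model.method == "ps_match":
            gap = np.abs(lp[s.member_event_ids].to_numpy() - lp[s.event_id])
            order = _tiebreak_order(list(gap), s.member_units)[:J]
            w = np.full(len(order), 1.0 / len(order))
            out.append(s.with_weights(w, member_idx=np.array(order, int),
                                      refinement=model.method))
        else:  # ps_weight / cbps_weight
            odds = np.exp(lp[s.member_event_ids].to_numpy())
            total = odds.sum()
            if not np.isfinite(total) or total <= 0:
                w = np.full(s.n_members, 1.0 / s.n_members)
            else:
                w = odds / total
            out.append(s.with_weights(w, refinement=model.method))
    return out
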