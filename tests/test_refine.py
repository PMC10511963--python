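import numpy as np
import pandas as pd
import pytest

from matchdid.cohort import (CovariateSpec, apply_eligibility,
                             build_covariates, code_transitions)
from matchdid.matching import build_matched_sets
from matchdid.refine import (METHODS, LogisticScore, RefinementError,
                             RefinementModel, fit_cbps, fit_logistic_mle,
                             fit_refinement, refine)
from matchdid.simulate import ScenarioConfig, generate, make_fixture

# lean spec: the tie fixture has 5 events, so keep the feature count low
SPEC = CovariateSpec(time_varying=["health", "income"], lags=1,
                     include_lagged_outcome=False)


def tie_setup(method, size_match=2):
    """Fixture with identical-covariate controls (score-free methods only)."""
    panel = make_fixture("tie_refine")
    events, _ = code_transitions(panel, "entry", window=(2012, 2016))
    events, _ = apply_eligibility(panel, events, 3, 1, min_age=None)
    cov = build_covariates(panel, events, SPEC)
    sets = build_matched_sets(events, panel, 3)
    model = fit_refinement(sets, cov, method, size_match=size_match)
    return refine(sets, cov, model), cov, model


def synth_setup(method, size_match=5):
    """Moderate synthetic cohort: enough treated events to fit scores."""
    panel, _ = generate(ScenarioConfig(n_units=250, seed=99))
    events, _ = code_transitions(panel, "entry", window=(2012, 2018))
    events, _ = apply_eligibility(panel, events, 3, 1, min_age=None)
    spec = CovariateSpec(time_invariant=["age", "sex"],
                         time_varying=["health"], lags=3,
                         missing_indicator_vars=["health"])
    cov = build_covariates(panel, events, spec)
    sets = build_matched_sets(events, panel, 3)
    model = fit_refinement(sets, cov, method, size_match=size_match)
    return refine(sets, cov, model), cov, model


@pytest.mark.parametrize("method", METHODS)
def test_weights_sum_to_one_and_nonnegative(method):
    refined, _, _ = synth_setup(method)
    assert any(s.is_matched for s in refined)
    for s in refined:
        if s.is_matched:
            assert np.isclose(s.weights.sum(), 1.0)
            assert (s.weights >= 0).all()


@pytest.mark.parametrize("method", METHODS)
def test_refine_is_idempotent(method):
    refined, cov, model = synth_setup(method)
    again = refine(refined, cov, model)
    for a, b in zip(refined, again):
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.member_units, b.member_units)


def test_mahalanobis_tie_broken_by_unit_id():
    refined, _, _ = tie_setup("mahalanobis", size_match=2)
    s = next(s for s in refined if s.unit == "T")
    # c0, c1, c2 are identical; far is distant -- ties resolve to id order
    assert list(s.member_units) == ["c0", "c1"]
    np.testing.assert_allclose(s.weights, [0.5, 0.5])


def test_ps_match_tie_broken_by_unit_id():
    # hand-built score giving c0/c1/c2 identical scores, far a distant one
    panel = make_fixture("tie_refine")
    events, _ = code_transitions(panel, "entry", window=(2012, 2016))
    events, _ = apply_eligibility(panel, events, 3, 1, min_age=None)
    cov = build_covariates(panel, events, SPEC)
    sets = build_matched_sets(events, panel, 3)
    score = LogisticScore(beta=np.array([0.0, 0.0, 1.0]),
                          means=np.zeros(2), sds=np.ones(2),
                          columns=["health_lag1", "income_lag1"])
    model = RefinementModel(method="ps_match", size_match=2, score=score)
    s = next(s for s in refine(sets, cov, model) if s.unit == "T")
    assert list(s.member_units) == ["c0", "c1"]


def test_single_control_gets_weight_one():
    panel = make_fixture("reuse")
    events, _ = code_transitions(panel, "entry", window=(2012, 2016))
    events, _ = apply_eligibility(panel, events, 3, 1, min_age=None)
    spec = CovariateSpec(time_invariant=["age"], time_varying=["income"],
                         lags=3)
    cov = build_covariates(panel, events, spec)
    sets = build_matched_sets(events, panel, 3)
    for method in ("mahalanobis", "ps_weight"):
        model = fit_refinement(sets, cov, method)
        for s in refine(sets, cov, model):
            np.testing.assert_array_equal(s.weights, [1.0])


def test_ps_weight_matches_hand_computed_odds_normalisation():
    # fitted scores 0.8 and 0.2 -> odds 4 and 0.25 -> weights 4/4.25, .25/4.25
    X = pd.DataFrame({"z": [9.9, 1.0, -1.0]}, index=[0, 1, 2])
    score = LogisticScore(beta=np.array([0.0, np.log(4.0)]),
                          means=np.array([0.0]), sds=np.array([1.0]),
                          columns=["z"])
    np.testing.assert_allclose(score.predict_proba(X)[1:], [0.8, 0.2])
    from matchdid.matching import MatchedSet
    s = MatchedSet(event_id=0, unit="T", t=3,
                   member_event_ids=np.array([1, 2]),
                   member_units=np.array(["a", "b"], dtype=object),
                   weights=np.array([0.5, 0.5]))
    cov = type("C", (), {})()
    cov.X = X
    cov.meta = pd.DataFrame({"column": ["z"], "var": ["z"], "lag": [1],
                             "kind": ["value"]})
    cov.events = pd.DataFrame({"t": [3, 3, 3]}, index=[0, 1, 2])
    model = RefinementModel(method="ps_weight", score=score)
    out = refine([s], cov, model)
    np.testing.assert_allclose(out[0].weights,
                               [4 / 4.25, 0.25 / 4.25], atol=1e-12)


class TestCBPS:
    def confounded_sample(self, n=1500, seed=4):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n),
                          "c": rng.binomial(1, 0.4, size=n).astype(float)})
        lin = 1.2 * X["a"] - 0.8 * X["b"] + 0.9 * X["c"] - 0.8
        p = 1 / (1 + np.exp(-lin))
        T = rng.binomial(1, p).astype(float)
        return T, X

    def test_balance_moments_hold_at_solution(self):
        T, X = self.confounded_sample()
        score = fit_cbps(T, X)
        assert score.max_moment < 1e-8
        p = score.predict_proba(X)
        odds = p[T == 0] / (1 - p[T == 0])
        Xa = X.to_numpy()
        treated_means = Xa[T == 1].mean(axis=0)
        weighted_control = odds @ Xa[T == 0] / odds.sum()
        # odds-weighted control means reproduce the treated means exactly
        np.testing.assert_allclose(treated_means, weighted_control, atol=1e-6)

    def test_cbps_beats_raw_imbalance(self):
        T, X = self.confounded_sample()
        p = fit_cbps(T, X).predict_proba(X)
        for col in X.columns:
            x = X[col].to_numpy()
            sd = x[T == 1].std(ddof=1)
            raw = (x[T == 1].mean() - x[T == 0].mean()) / sd
            w = p[T == 0] / (1 - p[T == 0])
            post = (x[T == 1].mean() - (w @ x[T == 0]) / w.sum()) / sd
            assert abs(post) < 0.05
        # the design is genuinely confounded to begin with
        a = X["a"].to_numpy()
        assert abs((a[T == 1].mean() - a[T == 0].mean())
                   / a[T == 1].std(ddof=1)) > 0.3

    def test_identical_groups_give_near_zero_coefficients(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame({"a": rng.normal(size=400),
                             "b": rng.normal(size=400)})
        X = pd.concat([base, base], ignore_index=True)
        T = np.array([1.0] * 400 + [0.0] * 400)
        score = fit_cbps(T, X)
        np.testing.assert_allclose(score.beta[1:], 0.0, atol=1e-6)

    def test_cbps_and_mle_weights_agree_when_mle_balances(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame({"a": rng.normal(size=400),
                             "b": rng.normal(size=400)})
        X = pd.concat([base, base], ignore_index=True)
        T = np.array([1.0] * 400 + [0.0] * 400)
        # duplicated groups: the MLE already satisfies exact balance
        mle = fit_logistic_mle(T, X)
        cbps = fit_cbps(T, X)
        np.testing.assert_allclose(mle.predict_proba(X),
                                   cbps.predict_proba(X), atol=1e-5)

    def test_perfect_separation_raises(self):
        X = pd.DataFrame({"a": np.r_[np.ones(50), -np.ones(50)]
                          + 0.01 * np.arange(100)})
        T = np.r_[np.ones(50), np.zeros(50)]
        with pytest.raises(RefinementError):
            fit_cbps(T, X)

    def test_degenerate_within_group_feature_is_dropped_with_warning(self):
        T, X = self.confounded_sample()
        X = X.copy()
        X["flag"] = np.where(T == 1, 1.0,
                             np.random.default_rng(0).binomial(1, 0.9, len(T)))
        with pytest.warns(UserWarning, match="flag"):
            score = fit_cbps(T, X)
        assert "flag" not in score.columns


def test_constant_column_dropped_with_warning():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"a": rng.normal(size=100), "k": np.ones(100)})
    T = rng.binomial(1, 0.5, 100).astype(float)
    with pytest.warns(UserWarning, match="k"):
        fit_logistic_mle(T, X)


def test_unknown_method_rejected():
    with pytest.raises(RefinementError):
        RefinementModel(method="entropy")
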