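import itertools

import numpy as np
import pandas as pd
import pytest

from matchdid.cohort import (CohortError, CovariateSpec, apply_eligibility,
                             build_covariates, code_transitions,
                             harmonise_currency, _tertile_rank)
from matchdid.panel import Panel

from conftest import random_panel


def history_panel():
    """One unit per length-3 employment history, fully observed."""
    years = (2006, 2008, 2010)
    rows = []
    for h, bits in enumerate(itertools.product([0, 1], repeat=3)):
        for w, y in enumerate(years):
            rows.append({"unit": f"h{h}", "year": y, "employed": bits[w],
                         "outcome": 25})
    return Panel(pd.DataFrame(rows), years)


def brute_force_classify(bits, t, direction):
    """Independent statement of the transition rules."""
    prev, cur = bits[t - 1], bits[t]
    origin = 0 if direction == "entry" else 1
    if prev != origin:
        return None
    return cur != origin  # True = treated, False = control


class TestCodeTransitions:
    @pytest.mark.parametrize("direction", ["entry", "exit"])
    def test_all_eight_histories_match_rule_enumeration(self, direction):
        panel = history_panel()
        events, _ = code_transitions(panel, direction, window=(2006, 2010))
        got = {(r.unit, r.t): r.treated for r in events.itertuples()}
        for h, bits in enumerate(itertools.product([0, 1], repeat=3)):
            for t in (1, 2):
                expect = brute_force_classify(bits, t, direction)
                if expect is None:
                    assert (f"h{h}", t) not in got
                else:
                    assert got[(f"h{h}", t)] == expect

    def test_entry_treated_and_exit_treated_from_oscillating_history(self):
        panel = history_panel()
        entry, _ = code_transitions(panel, "entry", window=(2006, 2010))
        exit_, _ = code_transitions(panel, "exit", window=(2006, 2010))
        # (1,0,1) is unit h5: exit treated at t=1, entry treated at t=2
        e = entry[(entry["unit"] == "h5") & entry["treated"]]
        x = exit_[(exit_["unit"] == "h5") & exit_["treated"]]
        assert list(e["t"]) == [2] and list(x["t"]) == [1]

    def test_always_out_unit_is_entry_control_each_wave(self):
        panel = history_panel()
        entry, _ = code_transitions(panel, "entry", window=(2006, 2010))
        h0 = entry[entry["unit"] == "h0"]
        assert list(h0["t"]) == [1, 2] and not h0["treated"].any()

    def test_unobserved_employment_is_skipped_and_tallied(self, rng):
        panel = random_panel(rng, p_missing_emp=0.3)
        events, tally = code_transitions(panel, "entry",
                                         window=(2006, 2020))
        assert tally["candidates"] == (tally["unobserved_employment"]
                                       + tally["wrong_origin"] + len(events))

    def test_window_restricts_treatment_years(self, tiny_panel):
        events, _ = code_transitions(tiny_panel, "entry",
                                     window=(2012, 2012))
        assert set(events["year"]) <= {2012}


class TestEligibility:
    def test_event_with_full_span_kept_and_short_span_dropped(self, tiny_panel):
        events, _ = code_transitions(tiny_panel, "entry", window=(2012, 2014))
        kept, tally = apply_eligibility(tiny_panel, events, lags=3, leads=1,
                                        min_age=None)
        # t=3 (2012) spans waves 0..4: kept; t=4 (2014) would need wave 5
        assert set(kept["t"]) == {3}
        assert tally["input"] == tally["kept"] + sum(
            v for k, v in tally.items() if k not in ("input", "kept"))

    def test_fewer_lags_keep_superset_of_events(self, rng):
        for _ in range(10):
            panel = random_panel(rng)
            events, _ = code_transitions(panel, "entry", window=(2006, 2020))
            k3, _ = apply_eligibility(panel, events, lags=3, leads=1,
                                      min_age=None)
            k2, _ = apply_eligibility(panel, events, lags=2, leads=1,
                                      min_age=None)
            s3 = set(zip(k3["unit"], k3["t"]))
            s2 = set(zip(k2["unit"], k2["t"]))
            assert s3 <= s2

    def test_zero_lags_zero_leads_keeps_events_with_observed_outcome(self, rng):
        panel = random_panel(rng)
        events, _ = code_transitions(panel, "entry", window=(2006, 2020))
        kept, _ = apply_eligibility(panel, events, lags=0, leads=0,
                                    min_age=None)
        O = panel.matrix("outcome")
        expect = [not np.isnan(O[panel.unit_rows(r.unit)[0], r.t])
                  for r in events.itertuples()]
        assert len(kept) == sum(expect)

    def test_min_age_filter(self, tiny_panel):
        events, _ = code_transitions(tiny_panel, "entry", window=(2012, 2014))
        kept_all, _ = apply_eligibility(tiny_panel, events, 1, 0, min_age=None)
        kept_old, tally = apply_eligibility(tiny_panel, events, 1, 0,
                                            min_age=75)
        assert len(kept_old) == 0 and tally["below_min_age"] == len(kept_all)


class TestCovariates:
    def spec(self, **kw):
        base = dict(time_invariant=["age"], time_varying=["x1", "x2"],
                    lags=3, include_lagged_outcome=True)
        base.update(kw)
        return CovariateSpec(**base)

    def test_tertile_of_six_equally_spaced_values(self):
        assert list(_tertile_rank(np.arange(1.0, 7.0))) == [1, 1, 2, 2, 3, 3]

    def test_tertile_invariant_to_monotone_transform(self, rng):
        v = rng.normal(size=40)
        assert np.array_equal(_tertile_rank(v), _tertile_rank(np.exp(v)))

    def test_time_varying_slot_count(self, rng):
        panel = random_panel(rng, p_missing_row=0.0, p_missing_emp=0.0,
                             p_missing_out=0.0)
        events, _ = code_transitions(panel, "entry", window=(2006, 2020))
        events, _ = apply_eligibility(panel, events, 3, 0, min_age=None)
        cov = build_covariates(panel, events, self.spec())
        lagged = cov.meta[cov.meta["lag"] > 0]
        # (x1, x2, outcome) x 3 lags = 9 slots
        assert len(lagged) == 9
        assert set(lagged["var"]) == {"x1", "x2", "outcome"}

    def test_missing_value_becomes_zero_with_indicator(self):
        years = (2006, 2008, 2010, 2012)
        rows = []
        for u in ("T", "C"):
            for w, y in enumerate(years):
                rows.append({"unit": u, "year": y,
                             "employed": 1 if (u == "T" and w == 3) else 0,
                             "outcome": 25, "age": 66.0,
                             "x1": np.nan if (u == "T" and w == 1) else 5.0})
        panel = Panel(pd.DataFrame(rows), years)
        events, _ = code_transitions(panel, "entry", window=(2012, 2012))
        events, _ = apply_eligibility(panel, events, 3, 0, min_age=None)
        spec = CovariateSpec(time_varying=["x1"], lags=3,
                             include_lagged_outcome=False,
                             missing_indicator_vars=["x1"])
        cov = build_covariates(panel, events, spec)
        row = cov.X.loc[events.index[events["unit"] == "T"][0]]
        assert row["x1_lag2"] == 0.0 and row["x1_lag2_obs"] == 0.0
        assert row["x1_lag1"] == 5.0 and row["x1_lag1_obs"] == 1.0

    def test_all_missing_covariate_raises(self, rng):
        panel = random_panel(rng, p_missing_row=0.0, p_missing_emp=0.0,
                             p_missing_out=0.0)
        panel.data["x1"] = np.nan
        panel._mats.clear()
        events, _ = code_transitions(panel, "entry", window=(2006, 2020))
        events, _ = apply_eligibility(panel, events, 3, 0, min_age=None)
        with pytest.raises(CohortError, match="x1"):
            build_covariates(panel, events,
                             self.spec(missing_indicator_vars=["x1"]))

    def test_categorical_one_hot_with_reference(self, rng):
        panel = random_panel(rng, p_missing_row=0.0, p_missing_emp=0.0,
                             p_missing_out=0.0)
        panel.data["edu"] = (panel.unit_rows(panel.data["unit"]) % 3).astype(float)
        panel._mats.clear()
        events, _ = code_transitions(panel, "entry", window=(2006, 2020))
        events, _ = apply_eligibility(panel, events, 3, 0, min_age=None)
        spec = CovariateSpec(time_invariant=["edu"], lags=3,
                             include_lagged_outcome=False,
                             categorical={"edu": [0.0, 1.0, 2.0]})
        cov = build_covariates(panel, events, spec)
        assert set(cov.X.columns) == {"edu=1.0", "edu=2.0"}
        assert cov.X.isin([0.0, 1.0]).all().all()

    def test_variable_in_both_lists_rejected(self):
        with pytest.raises(CohortError):
            CovariateSpec(time_invariant=["a"], time_varying=["a"])


class TestHarmoniseCurrency:
    def test_million_at_ppp_1000_is_one(self):
        assert harmonise_currency([1_000_000], 1000, 1)[0] == 1.0

    def test_deflator_scales_linearly(self):
        v = np.array([3.0, 7.0])
        np.testing.assert_allclose(harmonise_currency(v, 2.0, 1.1),
                                   1.1 * harmonise_currency(v, 2.0, 1.0))

    def test_tertile_order_invariant_under_harmonisation(self, rng):
        v = rng.lognormal(size=30)
        assert np.array_equal(_tertile_rank(v),
                              _tertile_rank(harmonise_currency(v, 917.0, 1.23)))

    def test_non_positive_factors_rejected(self):
        with pytest.raises(CohortError):
            harmonise_currency([1.0], 0, 1)
        with pytest.raises(CohortError):
            harmonise_currency([1.0], 1, -2)
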