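"""Lagged analysis: bin assignment, per-survey fits, the lag-as-moderator
regression with person-clustered sandwich SEs, and the max-stable-lag rule."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from rtscale import (LocationScaleSpec, PanelConfig, assign_lag_bins,
                     classify_effect_size, cluster_robust_cov,
                     estimate_time_intensities, fit_per_survey_components,
                     generate_panel, lag_moderator_regression, log_transform,
                     max_stable_lag, regress_components)
from rtscale.lagged import LagRegressionResult


def _ps_row(pid, days_before, value, sid=0):
    test = pd.Timestamp("2021-06-01")
    return {"person_id": pid, "survey_id": sid,
            "survey_date": test - pd.Timedelta(days=days_before),
            "mean_rt": value, "rt_adjustment": 0.1, "log_resid_var": -1.0}


def _scores(pids, scores=None):
    return pd.DataFrame({
        "person_id": pids,
        "score": scores if scores is not None else 50.0,
        "test_name": "t",
        "test_date": pd.Timestamp("2021-06-01"),
    })


class TestLagBins:
    @pytest.mark.parametrize("days,expected_bin", [
        (0, 1),
        (110, 1),                       # 0.30 years
        (182, 1),                       # 0.498 years: still bin 1
        (184, 2),                       # 0.504 years: just past the boundary
        (366, 3),                       # just past 1.0 years
        (2373, 13),                     # 6.497 years: last bin
    ])
    def test_boundaries(self, days, expected_bin):
        ps = pd.DataFrame([_ps_row(1, days, 1.0)])
        out = assign_lag_bins(ps, _scores([1]))
        assert out["lag_bin"].tolist() == [expected_bin]

    def test_beyond_window_dropped(self):
        ps = pd.DataFrame([_ps_row(1, int(6.7 * 365.25), 1.0)])
        assert assign_lag_bins(ps, _scores([1])).empty

    def test_survey_after_test_dropped(self):
        ps = pd.DataFrame([_ps_row(1, -30, 1.0)])
        assert assign_lag_bins(ps, _scores([1])).empty

    def test_within_bin_averaging(self):
        ps = pd.DataFrame([_ps_row(1, d, v, sid=i) for i, (d, v) in
                           enumerate([(37, 1.0), (73, 2.0), (146, 6.0)])])
        out = assign_lag_bins(ps, _scores([1]))
        assert len(out) == 1
        assert out["mean_rt"].iloc[0] == pytest.approx(3.0)
        assert out["n_surveys_in_bin"].iloc[0] == 3

    def test_rows_conserved_and_unique(self):
        rng = np.random.default_rng(2)
        ps = pd.DataFrame([
            _ps_row(p, int(rng.integers(0, 2300)), rng.normal(), sid=s)
            for p in range(30) for s in range(12)])
        out = assign_lag_bins(ps, _scores(np.arange(30)))
        assert out.duplicated(["person_id", "lag_bin"]).sum() == 0
        assert out["n_surveys_in_bin"].sum() == len(ps)


class TestSandwich:
    def test_matches_brute_force_cluster_sums(self):
        """Clustered covariance equals the explicit per-cluster score-sum
        sandwich on a fixed 50-person toy, to 1e-8."""
        rng = np.random.default_rng(9)
        n, k, G = 150, 4, 50
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = X @ rng.normal(size=k) + rng.normal(size=n)
        cl = np.repeat(np.arange(G), 3)
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ b
        V = cluster_robust_cov(X, e, cl)

        bread = np.linalg.inv(X.T @ X)
        meat = np.zeros((k, k))
        for g in range(G):
            sg = (X[cl == g] * e[cl == g, None]).sum(axis=0)
            meat += np.outer(sg, sg)
        expected = bread @ meat @ bread * G / (G - 1)
        np.testing.assert_allclose(V, expected, atol=1e-8)

    def test_matches_statsmodels_cluster(self):
        rng = np.random.default_rng(10)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([1.0, 0.5, -0.3]) + rng.normal(size=n)
        cl = rng.integers(0, 40, n)
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        V = cluster_robust_cov(X, y - X @ b, cl, small_sample=False)
        smfit = sm.OLS(y, X).fit(cov_type="cluster",
                                 cov_kwds={"groups": cl,
                                           "use_correction": False})
        np.testing.assert_allclose(V, smfit.cov_params(), atol=1e-10)

    def test_single_observation_clusters_reduce_to_hc0(self):
        rng = np.random.default_rng(11)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([2.0, 1.0]) + rng.normal(size=n)
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ b
        V = cluster_robust_cov(X, e, np.arange(n), small_sample=False)
        bread = np.linalg.inv(X.T @ X)
        hc0 = bread @ (X.T * e ** 2) @ X @ bread
        np.testing.assert_allclose(V, hc0, atol=1e-12)


class TestLagRegression:
    def _sim_bins(self, rng, J=300, B=5, effect=0.4, noise=0.7):
        u = rng.standard_normal(J)
        score = 50 + 10 * (effect * u + rng.standard_normal(J)
                           * np.sqrt(1 - effect ** 2))
        rows = []
        for j in range(J):
            for b in range(1, B + 1):
                rows.append({"person_id": j, "lag_bin": b,
                             "mean_rt": u[j] + noise * rng.standard_normal(),
                             "rt_adjustment": rng.standard_normal(),
                             "log_resid_var": rng.standard_normal(),
                             "n_surveys_in_bin": 1})
        scores = pd.DataFrame({"person_id": np.arange(J), "score": score,
                               "test_name": "t"})
        return pd.DataFrame(rows), scores

    def test_single_bin_reduces_to_plain_regression(self):
        rng = np.random.default_rng(12)
        bins, scores = self._sim_bins(rng, J=200, B=1)
        lag = lag_moderator_regression(bins, scores)
        plain = regress_components(scores, bins.drop(columns=["lag_bin"]))
        for c in plain.betas:
            assert lag.betas[c][1] == pytest.approx(plain.betas[c],
                                                    abs=1e-10)

    def test_interaction_type_one_error_near_nominal(self):
        """Lag-constant generator: the component-by-lag Wald test rejects at
        ~5% over 200 replicates (binomial 99% bounds)."""
        rng = np.random.default_rng(13)
        reps, rejections = 200, 0
        for _ in range(reps):
            bins, scores = self._sim_bins(rng, J=150, B=4)
            res = lag_moderator_regression(bins, scores)
            rejections += res.interaction_p["mean_rt"] < 0.05
        lo = scipy.stats.binom.ppf(0.005, reps, 0.05)
        hi = scipy.stats.binom.ppf(0.995, reps, 0.05)
        assert lo <= rejections <= hi, rejections

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(14)
        bins, scores = self._sim_bins(rng)
        res = lag_moderator_regression(bins, scores)
        for c in res.components:
            for b in res.bins:
                assert res.ci_low[c][b] <= res.betas[c][b] <= res.ci_high[c][b]

    def test_sparse_bin_excluded(self):
        rng = np.random.default_rng(15)
        bins, scores = self._sim_bins(rng, J=50, B=3)
        lone = pd.DataFrame([{"person_id": 0, "lag_bin": 9, "mean_rt": 0.0,
                              "rt_adjustment": 0.0, "log_resid_var": 0.0,
                              "n_surveys_in_bin": 1}])
        res = lag_moderator_regression(pd.concat([bins, lone]), scores)
        assert 9 in res.excluded_bins
        assert 9 not in res.bins


class TestMaxStableLag:
    def _result(self, ci_pattern):
        bins = list(range(1, len(ci_pattern) + 1))
        lo = {b: (0.1 if sig else -0.1) for b, sig in zip(bins, ci_pattern)}
        hi = {b: 0.5 for b in bins}
        empty = {b: 0.0 for b in bins}
        return LagRegressionResult(
            outcome="t", components=["mean_rt"], bins=bins,
            bin_years={b: 0.5 * b for b in bins},
            betas={"mean_rt": {b: 0.3 for b in bins}},
            se={"mean_rt": empty}, tvalues={"mean_rt": empty},
            ci_low={"mean_rt": lo}, ci_high={"mean_rt": hi},
            main_F={}, main_p={}, interaction_F={}, interaction_p={},
            interaction_df={}, n_clusters=100, n_rows=100)

    def test_all_bins_significant_gives_full_span(self):
        res = self._result([True] * 13)
        assert max_stable_lag(res)["mean_rt"] == 6.5

    def test_consecutive_rule_stops_at_first_gap(self):
        res = self._result([True, True, False, True])
        assert max_stable_lag(res)["mean_rt"] == 1.0

    def test_first_bin_nonsignificant_gives_zero(self):
        res = self._result([False, True, True])
        assert max_stable_lag(res)["mean_rt"] == 0.0


@pytest.mark.parametrize("value,label", [
    (0.50, "large"), (-0.30, "medium"), (0.10, "small"), (0.05, "negligible"),
    (-0.75, "large"), (0.299, "small"), (-0.09, "negligible"),
])
def test_effect_size_conventions(value, label):
    assert classify_effect_size(value) == label


class TestPerSurveyFits:
    @pytest.fixture(scope="class")
    def survey_panel(self):
        cfg = PanelConfig(n_persons=100, n_surveys=6, items_per_survey=12,
                          seed=19)
        return generate_panel(cfg)

    def test_components_track_truth_per_survey(self, survey_panel):
        clean = log_transform(survey_panel.rt_records)
        ti = estimate_time_intensities(clean, method="reml")
        spec = LocationScaleSpec(chains=2, iterations=1000, burn_in=400,
                                 seed=22)
        ps, skipped = fit_per_survey_components(clean, ti.ti, spec)
        assert not skipped
        merged = ps.merge(survey_panel.person_truth, on="person_id")
        for _, grp in merged.groupby("survey_id"):
            assert np.corrcoef(grp["mean_rt"], grp["alpha"])[0, 1] >= 0.8

    def test_identical_surveys_identical_estimates(self, survey_panel):
        """Two surveys with copied data get identical component estimates
        because per-survey seeds depend only on the survey order."""
        clean = log_transform(survey_panel.rt_records)
        one = clean[clean["survey_id"] == 0]
        two = one.assign(survey_id=1)
        both = pd.concat([one, two], ignore_index=True)
        ti = estimate_time_intensities(clean, method="reml")
        spec = LocationScaleSpec(chains=2, iterations=800, burn_in=300,
                                 seed=23)
        ps, _ = fit_per_survey_components(both, ti.ti, spec)
        a = ps[ps["survey_id"] == 0].set_index("person_id")
        b = ps[ps["survey_id"] == 1].set_index("person_id")
        assert not np.allclose(a["mean_rt"], b["mean_rt"])  # different seeds
        # refit survey 0 alone with the same master seed: exact match
        ps2, _ = fit_per_survey_components(one, ti.ti, spec)
        c = ps2.set_index("person_id")
        np.testing.assert_allclose(a["mean_rt"], c["mean_rt"], atol=0)

    def test_constant_ti_survey_falls_back_to_plain_model(self, survey_panel):
        clean = log_transform(survey_panel.rt_records)
        ti = estimate_time_intensities(clean, method="reml").ti.copy()
        items0 = clean.loc[clean["survey_id"] == 0, "item_id"].unique()
        ti.loc[ti["item_id"].isin(items0), "ti_centered"] = 0.5
        spec = LocationScaleSpec(chains=2, iterations=600, burn_in=250,
                                 seed=24)
        ps, skipped = fit_per_survey_components(clean, ti, spec)
        flagged = [s for s in skipped if "slope omitted" in s["reason"]]
        assert [s["survey_id"] for s in flagged] == [0]
        sub = ps[ps["survey_id"] == 0]
        assert sub["rt_adjustment"].isna().all()
        assert ps[ps["survey_id"] == 1]["rt_adjustment"].notna().all()

    def test_small_survey_skipped(self, survey_panel):
        clean = log_transform(survey_panel.rt_records)
        ti = estimate_time_intensities(clean, method="reml")
        spec = LocationScaleSpec(chains=2, iterations=600, burn_in=250,
                                 seed=25)
        with pytest.raises(ValueError, match="minimum"):
            # every survey has only 12 distinct items
            fit_per_survey_components(clean, ti.ti, spec, min_items=20)
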