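"""Cross-sectional association: correlation/regression identities against
from-scratch linear algebra, recovery of generator effects, moderation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from rtscale import (PanelConfig, correlate, generate_panel,
                     latent_correlations_for_targets, moderated_regression,
                     regress_components, tau_with_correlations)

BETA = (-0.28, 0.50, -0.15)
R_TARGET = (-0.09, 0.43, -0.12)


def _truth_components(panel):
    return panel.person_truth.rename(columns={
        "u0": "mean_rt", "u1": "rt_adjustment", "u2": "log_resid_var"
    })[["person_id", "mean_rt", "rt_adjustment", "log_resid_var"]]


@pytest.fixture(scope="module")
def assoc_panel():
    corr = latent_correlations_for_targets(BETA, R_TARGET)
    tau = tau_with_correlations([0.16, 0.04, 0.25], corr)
    cfg = PanelConfig(n_persons=5000, n_surveys=1, items_per_survey=2,
                      tau=tau, beta_cog=BETA, r2_cog=0.26, seed=77)
    return generate_panel(cfg)


class TestCorrelate:
    def test_exact_linear_score_gives_unit_correlation(self):
        comp = pd.DataFrame({"person_id": np.arange(50),
                             "mean_rt": np.linspace(-1, 1, 50)})
        scores = pd.DataFrame({"person_id": np.arange(50),
                               "test_name": "t",
                               "score": 3 - 2 * np.linspace(-1, 1, 50)})
        out = correlate(comp, scores)
        assert out["r"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_sign_pattern_matches_generator(self, assoc_panel):
        out = correlate(_truth_components(assoc_panel),
                        assoc_panel.cognitive_scores)
        got = out.set_index("component")["r"]
        for comp, target in zip(("mean_rt", "rt_adjustment", "log_resid_var"),
                                R_TARGET):
            assert np.sign(got[comp]) == np.sign(target)
            assert got[comp] == pytest.approx(target, abs=0.05)

    def test_zero_variance_flagged(self):
        comp = pd.DataFrame({"person_id": np.arange(10),
                             "mean_rt": np.ones(10)})
        scores = pd.DataFrame({"person_id": np.arange(10), "test_name": "t",
                               "score": np.random.default_rng(0).normal(size=10)})
        out = correlate(comp, scores)
        assert np.isnan(out["r"].iloc[0])
        assert out["note"].iloc[0] == "zero variance"

    def test_permuted_components_lose_association(self, assoc_panel):
        """Permuting the component against scores sends |r| below the 95%
        null quantile in >= 90% of 100 permutations."""
        comp = _truth_components(assoc_panel).iloc[:1000]
        scores = assoc_panel.cognitive_scores.iloc[:1000]
        rng = np.random.default_rng(6)
        null_crit = 1.96 / np.sqrt(len(comp))
        hits = 0
        x = comp["rt_adjustment"].to_numpy()
        y = scores["score"].to_numpy()
        for _ in range(100):
            r = np.corrcoef(rng.permutation(x), y)[0, 1]
            hits += abs(r) < null_crit
        assert hits >= 90


class TestRegression:
    def test_single_predictor_beta_equals_r(self, assoc_panel):
        comp = _truth_components(assoc_panel)[["person_id", "mean_rt"]]
        res = regress_components(assoc_panel.cognitive_scores, comp)
        r = np.corrcoef(
            _truth_components(assoc_panel)["mean_rt"],
            assoc_panel.cognitive_scores["score"])[0, 1]
        assert res.betas["mean_rt"] == pytest.approx(r, abs=1e-10)

    def test_generator_betas_and_r2_recovered(self, assoc_panel):
        res = regress_components(assoc_panel.cognitive_scores,
                                 _truth_components(assoc_panel))
        for comp, target in zip(("mean_rt", "rt_adjustment", "log_resid_var"),
                                BETA):
            assert res.betas[comp] == pytest.approx(target, abs=0.05)
        assert res.r2 == pytest.approx(0.26, abs=0.03)

    def test_matches_from_scratch_linear_algebra(self, assoc_panel):
        """F, t, R^2 agree with a hand-rolled X'X solve to 1e-8."""
        comp = _truth_components(assoc_panel).iloc[:400]
        scores = assoc_panel.cognitive_scores.iloc[:400]
        res = regress_components(scores, comp)

        cols = ["mean_rt", "rt_adjustment", "log_resid_var"]
        Z = comp[cols].to_numpy()
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        y = scores["score"].to_numpy()
        y = (y - y.mean()) / y.std(ddof=1)
        X = np.column_stack([np.ones(len(y)), Z])
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ X.T @ y
        resid = y - X @ b
        n, k = X.shape
        s2 = resid @ resid / (n - k)
        se = np.sqrt(np.diag(XtX_inv) * s2)
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        F = (r2 / (k - 1)) / ((1 - r2) / (n - k))
        for i, c in enumerate(cols, start=1):
            assert res.betas[c] == pytest.approx(b[i], abs=1e-8)
            assert res.tvalues[c] == pytest.approx(b[i] / se[i], abs=1e-8)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.f_stat == pytest.approx(F, abs=1e-8)
        assert res.df_model == k - 1 and res.df_resid == n - k

    def test_noise_covariates_leave_betas_alone(self, assoc_panel):
        comp = _truth_components(assoc_panel)
        res0 = regress_components(assoc_panel.cognitive_scores, comp)
        rng = np.random.default_rng(8)
        cov = pd.DataFrame({"person_id": comp["person_id"],
                            "junk1": rng.normal(size=len(comp)),
                            "junk2": rng.normal(size=len(comp))})
        res1 = regress_components(assoc_panel.cognitive_scores, comp,
                                  covariates=cov)
        assert res1.r2 >= res0.r2 - 1e-12
        for c in res0.betas:
            assert res1.betas[c] == pytest.approx(res0.betas[c], abs=0.02)

    def test_demographic_covariates_run(self, assoc_panel):
        res = regress_components(
            assoc_panel.cognitive_scores, _truth_components(assoc_panel),
            covariates=assoc_panel.demographics[
                ["person_id", "age", "gender", "education", "income"]])
        assert 0.0 <= res.r2 <= 1.0
        assert res.n == 5000

    def test_collinear_design_rejected(self, assoc_panel):
        comp = _truth_components(assoc_panel).copy()
        comp["rt_adjustment"] = 2.0 * comp["mean_rt"]
        with pytest.raises(ValueError, match="collinear"):
            regress_components(assoc_panel.cognitive_scores, comp)

    def test_too_few_rows_rejected(self, assoc_panel):
        comp = _truth_components(assoc_panel).iloc[:4]
        with pytest.raises(ValueError, match="too small"):
            regress_components(assoc_panel.cognitive_scores, comp)


class TestModeration:
    def test_relabelled_identical_groups_give_zero_difference(self):
        """The same persons duplicated into both age groups: the group
        difference t vanishes."""
        rng = np.random.default_rng(5)
        n = 300
        comp = pd.DataFrame({
            "person_id": np.arange(2 * n),
            "mean_rt": np.tile(rng.normal(size=n), 2),
            "rt_adjustment": np.tile(rng.normal(size=n), 2),
            "log_resid_var": np.tile(rng.normal(size=n), 2)})
        scores = pd.DataFrame({
            "person_id": np.arange(2 * n), "test_name": "t",
            "score": np.tile(50 + 5 * rng.normal(size=n), 2)})
        age = pd.DataFrame({"person_id": np.arange(2 * n),
                            "age": np.r_[np.full(n, 30), np.full(n, 60)]})
        res = moderated_regression(scores, comp, age)
        for c in res.diff_tvalues:
            assert abs(res.diff_tvalues[c]) < 1e-8

    def test_no_moderation_type_one_error(self):
        """age_moderation = 1: the mean-RT group-difference test rejects at
        the nominal 5% rate over 200 replicates (binomial 99% bounds)."""
        rejections = 0
        reps = 200
        for i in range(reps):
            cfg = PanelConfig(n_persons=250, n_surveys=1, items_per_survey=2,
                              beta_cog=BETA, r2_cog=0.26, seed=10_000 + i)
            panel = generate_panel(cfg)
            res = moderated_regression(panel.cognitive_scores,
                                       _truth_components(panel),
                                       panel.demographics)
            rejections += res.diff_pvalues["mean_rt"] < 0.05
        lo = scipy.stats.binom.ppf(0.005, reps, 0.05)
        hi = scipy.stats.binom.ppf(0.995, reps, 0.05)
        assert lo <= rejections <= hi, rejections

    def test_doubled_old_effect_detected(self):
        """u0->score effect doubled for 40+: the difference test fires in
        >= 80% of replicates at n=1500."""
        hits = 0
        reps = 30
        for i in range(reps):
            cfg = PanelConfig(n_persons=1500, n_surveys=1, items_per_survey=2,
                              beta_cog=BETA, r2_cog=0.26, age_moderation=2.0,
                              seed=20_000 + i)
            panel = generate_panel(cfg)
            res = moderated_regression(panel.cognitive_scores,
                                       _truth_components(panel),
                                       panel.demographics)
            hits += res.diff_pvalues["mean_rt"] < 0.05
        assert hits >= 0.8 * reps

    def test_empty_group_rejected(self, assoc_panel):
        age = assoc_panel.demographics[["person_id"]].assign(age=30)
        with pytest.raises(ValueError, match="empty age group"):
            moderated_regression(assoc_panel.cognitive_scores,
                                 _truth_components(assoc_panel), age)
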