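"""Prospective (time-lagged) analysis of RT components and cognition.

The expanded location-scale model is refit separately per survey, giving each
person a per-survey estimate of the three RT components.  Component estimates
are averaged within half-year lag bins before the person's cognitive test
(bin k covers lags in (0.5(k-1), 0.5k] years, bin 1 closed at 0, up to 6.5
years), and the binned components predict the cognitive score in a pooled
"lag as moderator" regression: one row per person x bin with the outcome
repeated, bin-specific component slopes, and cluster-robust (person-
clustered) sandwich standard errors with a G/(G-1) small-sample factor.
Because the outcome repeats across a person's rows, clustering on persons is
mandatory, not optional.

The maximum stable lag per component is the longest run of consecutive bins,
starting at bin 1, whose 95% confidence intervals exclude zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .association import COMPONENT_COLUMNS, _component_cols, _zscore
from .location_scale import LocationScaleSpec, fit_expanded_location_scale, fit_location_scale

__all__ = [
    "fit_per_survey_components",
    "assign_lag_bins",
    "LagRegressionResult",
    "lag_moderator_regression",
    "cluster_robust_cov",
    "max_stable_lag",
    "classify_effect_size",
]

DAYS_PER_YEAR = 365.25


def fit_per_survey_components(
    records: pd.DataFrame,
    ti: pd.DataFrame,
    spec: LocationScaleSpec | None = None,
    min_items: int = 10,
    min_persons: int = 10,
) -> tuple[pd.DataFrame, list[dict]]:
    """Fit the expanded location-scale model separately for each survey.

    Surveys below ``min_items`` distinct items or ``min_persons`` respondents
    are skipped; surveys whose items share a single TI value have no
    identified slope and are fit with the non-expanded model (slope reported
    as missing).  Global TIs (estimated once on all data) are reused for
    every survey.  Each survey's chains are seeded from the sampler seed and the
    survey index, so individual surveys are reproducible in isolation.

    Returns (long components table with survey_id/survey_date, skipped list).
    """
    spec = spec or LocationScaleSpec()
    out = []
    skipped: list[dict] = []
    for k, (sid, grp) in enumerate(sorted(records.groupby("survey_id"),
                                          key=lambda kv: str(kv[0]))):
        n_items = grp["item_id"].nunique()
        n_persons = grp["person_id"].nunique()
        if n_items < min_items or n_persons < min_persons:
            skipped.append({"survey_id": sid, "n_items": int(n_items),
                            "n_persons": int(n_persons),
                            "reason": "below minimum size"})
            continue
        sub_seed = int(np.random.SeedSequence([spec.seed, k]).generate_state(1)[0]
                       % (2 ** 31))
        sub_spec = LocationScaleSpec(
            chains=spec.chains, iterations=spec.iterations,
            burn_in=spec.burn_in, thin=spec.thin, seed=sub_seed,
            fixed_effect_prior_var=spec.fixed_effect_prior_var,
            adapt_target=spec.adapt_target, psr_threshold=spec.psr_threshold)
        ti_sub = ti[ti["item_id"].isin(grp["item_id"].unique())]
        if np.ptp(ti_sub["ti_centered"].to_numpy()) < 1e-12:
            fit = fit_location_scale(grp, sub_spec)
            skipped.append({"survey_id": sid, "n_items": int(n_items),
                            "n_persons": int(n_persons),
                            "reason": "constant TI; slope omitted"})
        else:
            fit = fit_expanded_location_scale(grp, ti, sub_spec)
        comp = fit.person_post.copy()
        comp["survey_id"] = sid
        comp["survey_date"] = grp["survey_date"].iloc[0]
        out.append(comp)
    if not out:
        raise ValueError("no survey met the minimum size requirements")
    return pd.concat(out, ignore_index=True), skipped


def assign_lag_bins(
    per_survey_components: pd.DataFrame,
    scores: pd.DataFrame,
    bin_width_years: float = 0.5,
    max_lag_years: float = 6.5,
) -> pd.DataFrame:
    """Average per-survey components within person x half-year lag bin.

    Lag = (test_date - survey_date) / 365.25 years.  Bin k covers
    (width*(k-1), width*k]; bin 1 is closed at lag 0.  Surveys after the test
    (lag < 0) or beyond ``max_lag_years`` are dropped; persons with no
    eligible surveys are omitted.
    """
    comp_cols = [c for c in COMPONENT_COLUMNS if c in per_survey_components.columns]
    merged = per_survey_components.merge(
        scores[["person_id", "test_date"]].drop_duplicates("person_id"),
        on="person_id")
    lag = (pd.to_datetime(merged["test_date"]) -
           pd.to_datetime(merged["survey_date"])).dt.total_seconds() \
        / (DAYS_PER_YEAR * 86400.0)
    keep = (lag >= 0) & (lag <= max_lag_years)
    merged = merged[keep].copy()
    lag = lag[keep]
    merged["lag_bin"] = np.maximum(
        np.ceil(lag / bin_width_years - 1e-12).astype(int), 1)
    grouped = merged.groupby(["person_id", "lag_bin"])
    out = grouped[comp_cols].mean().reset_index()
    out["n_surveys_in_bin"] = grouped.size().to_numpy()
    return out


def cluster_robust_cov(
    X: np.ndarray, resid: np.ndarray, clusters: np.ndarray,
    small_sample: bool = True,
) -> np.ndarray:
    """Cluster-robust (CR0-type) sandwich covariance with an optional
    G/(G-1) small-sample factor.  With one observation per cluster this
    equals the HC0 heteroskedasticity-robust covariance times the factor.
    """
    XtX_inv = np.linalg.inv(X.T @ X)
    codes, uniq = pd.factorize(clusters)
    G = len(uniq)
    Xe = X * resid[:, None]
    # per-cluster score sums, then the meat Sum_g s_g s_g'
    S = np.zeros((G, X.shape[1]))
    np.add.at(S, codes, Xe)
    meat = S.T @ S
    cov = XtX_inv @ meat @ XtX_inv
    if small_sample:
        if G < 2:
            raise ValueError("cluster-robust covariance needs >= 2 clusters")
        cov *= G / (G - 1)
    return cov


@dataclass
class LagRegressionResult:
    outcome: str
    components: list[str]
    bins: list[int]
    bin_years: dict[int, float]
    betas: dict[str, dict[int, float]]          # component -> bin -> beta
    se: dict[str, dict[int, float]]
    tvalues: dict[str, dict[int, float]]
    ci_low: dict[str, dict[int, float]]
    ci_high: dict[str, dict[int, float]]
    main_F: dict[str, float]
    main_p: dict[str, float]
    interaction_F: dict[str, float]
    interaction_p: dict[str, float]
    interaction_df: dict[str, tuple[int, int]]
    n_clusters: int
    n_rows: int
    excluded_bins: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "bins": self.bins,
            "betas": self.betas,
            "ci": {c: {b: [self.ci_low[c][b], self.ci_high[c][b]]
                       for b in self.bins} for c in self.components},
            "main_F": self.main_F,
            "interaction_F": self.interaction_F,
            "interaction_p": self.interaction_p,
            "n_clusters": self.n_clusters,
            "n_rows": self.n_rows,
        }


def lag_moderator_regression(
    bins: pd.DataFrame,
    scores: pd.DataFrame,
    bin_width_years: float = 0.5,
    small_sample: bool = True,
) -> LagRegressionResult:
    """Pooled lag-as-moderator regression with person-clustered sandwich SEs.

    Stacks one row per person x lag bin (outcome repeated across a person's
    rows), with bin-specific intercepts and bin-specific component slopes.
    Per-bin standardized betas and 95% CIs come straight from this fully
    interacted parameterization; the component main effect (mean slope = 0)
    and the component x lag interaction (all slopes equal) are cluster-robust
    Wald tests with F reference df (q, G-1).
    """
    comp_cols = _component_cols(bins)
    data = bins.merge(scores[["person_id", "score", "test_name"]]
                      .drop_duplicates("person_id"), on="person_id").dropna(
        subset=comp_cols + ["score"])
    outcome = data["test_name"].iloc[0] if len(data) else "score"

    counts = data.groupby("lag_bin")["person_id"].nunique()
    good_bins = sorted(counts[counts >= 2].index.tolist())
    excluded = sorted(counts[counts < 2].index.tolist())
    data = data[data["lag_bin"].isin(good_bins)]
    if len(good_bins) < 1:
        raise ValueError("no lag bin has >= 2 clusters")

    y = _zscore(data["score"].to_numpy(dtype=float))
    zcomp = {c: _zscore(data[c].to_numpy(dtype=float)) for c in comp_cols}
    bin_arr = data["lag_bin"].to_numpy()

    col_names: list[str] = []
    cols: list[np.ndarray] = []
    for b in good_bins:
        ind = (bin_arr == b).astype(float)
        col_names.append(f"bin{b}")
        cols.append(ind)
    for c in comp_cols:
        for b in good_bins:
            col_names.append(f"{c}@bin{b}")
            cols.append(zcomp[c] * (bin_arr == b))
    X = np.column_stack(cols)

    beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta_hat
    clusters = data["person_id"].to_numpy()
    V = cluster_robust_cov(X, resid, clusters, small_sample=small_sample)
    G = data["person_id"].nunique()
    se_all = np.sqrt(np.diag(V))
    tcrit = scipy.stats.t.ppf(0.975, G - 1)

    idx = {nm: k for k, nm in enumerate(col_names)}
    betas, ses, ts, lo, hi = {}, {}, {}, {}, {}
    main_F, main_p, inter_F, inter_p, inter_df = {}, {}, {}, {}, {}
    nb = len(good_bins)
    for c in comp_cols:
        ks = [idx[f"{c}@bin{b}"] for b in good_bins]
        betas[c] = {b: float(beta_hat[k]) for b, k in zip(good_bins, ks)}
        ses[c] = {b: float(se_all[k]) for b, k in zip(good_bins, ks)}
        ts[c] = {b: float(beta_hat[k] / se_all[k]) for b, k in zip(good_bins, ks)}
        lo[c] = {b: float(beta_hat[k] - tcrit * se_all[k])
                 for b, k in zip(good_bins, ks)}
        hi[c] = {b: float(beta_hat[k] + tcrit * se_all[k])
                 for b, k in zip(good_bins, ks)}
        # main effect: average slope equals zero (1 restriction)
        L = np.zeros((1, X.shape[1]))
        L[0, ks] = 1.0 / nb
        F, p = _wald_F(L, beta_hat, V, G)
        main_F[c], main_p[c] = F, p
        # interaction: all bin slopes equal (nb - 1 restrictions)
        if nb > 1:
            L = np.zeros((nb - 1, X.shape[1]))
            for r in range(nb - 1):
                L[r, ks[r]] = 1.0
                L[r, ks[r + 1]] = -1.0
            F, p = _wald_F(L, beta_hat, V, G)
        else:
            F, p = np.nan, np.nan
        inter_F[c], inter_p[c] = F, p
        inter_df[c] = (nb - 1, G - 1)

    return LagRegressionResult(
        outcome=outcome, components=comp_cols, bins=good_bins,
        bin_years={b: b * bin_width_years for b in good_bins},
        betas=betas, se=ses, tvalues=ts, ci_low=lo, ci_high=hi,
        main_F=main_F, main_p=main_p,
        interaction_F=inter_F, interaction_p=inter_p, interaction_df=inter_df,
        n_clusters=int(G), n_rows=len(data), excluded_bins=excluded,
    )


def _wald_F(L: np.ndarray, beta: np.ndarray, V: np.ndarray, G: int):
    q = L.shape[0]
    Lb = L @ beta
    W = float(Lb @ np.linalg.solve(L @ V @ L.T, Lb))
    F = W / q
    p = float(scipy.stats.f.sf(F, q, max(G - 1, 1)))
    return float(F), p


def max_stable_lag(result: LagRegressionResult,
                   bin_width_years: float = 0.5) -> dict[str, float]:
    """Longest run of consecutive bins from bin 1 whose 95% CI excludes 0,
    in years (0 when bin 1's CI includes 0)."""
    out = {}
    for c in result.components:
        years = 0.0
        for k, b in enumerate(sorted(result.bins), start=1):
            if b != k:  # a missing bin breaks the consecutive run
                break
            if result.ci_low[c][b] > 0 or result.ci_high[c][b] < 0:
                years = b * bin_width_years
            else:
                break
        out[c] = years
    return out


def classify_effect_size(value: float) -> str:
    """Standardized-coefficient magnitude conventions:
    |b| >= .50 large, >= .30 medium, >= .10 small, else negligible."""
    if not np.isfinite(value):
        raise ValueError("effect size must be finite")
    a = abs(value)
    if a >= 0.50:
        return "large"
    if a >= 0.30:
        return "medium"
    if a >= 0.10:
        return "small"
    return "negligible"
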