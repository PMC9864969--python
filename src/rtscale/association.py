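"""Cross-sectional linkage of person-level RT components to cognitive scores.

Provides bivariate correlations, standardized multiple regression of a
cognitive score on the RT components (optionally with demographic
covariates), and a moderated regression comparing the component-score
relationships between younger (< 40 years) and older (40+) respondents.

Conventions: the outcome and the continuous predictors are z-scored on the
listwise-complete analysis sample, so component coefficients are standardized
betas; categorical covariates enter as unstandardized indicator contrasts.
No multiple-testing correction is applied; results carry the test count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "COMPONENT_COLUMNS",
    "RegressionResult",
    "ModerationResult",
    "correlate",
    "regress_components",
    "moderated_regression",
]

COMPONENT_COLUMNS = ("mean_rt", "rt_adjustment", "log_resid_var")


def _component_cols(components: pd.DataFrame) -> list[str]:
    cols = [c for c in COMPONENT_COLUMNS if c in components.columns]
    if not cols:
        raise ValueError(
            f"no RT component columns found (expected some of {COMPONENT_COLUMNS})")
    return cols


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance; cannot standardize")
    return (x - x.mean()) / sd


@dataclass
class RegressionResult:
    outcome: str
    predictors: list[str]
    betas: dict[str, float]       # standardized betas for the RT components
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    f_stat: float
    df_model: int
    df_resid: int
    r2: float
    f_pvalue: float
    n: int
    n_tests: int
    params: pd.Series = field(repr=False, default=None)
    cov_params: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "betas": self.betas,
            "tvalues": self.tvalues,
            "pvalues": self.pvalues,
            "F": self.f_stat,
            "df": [self.df_model, self.df_resid],
            "R2": self.r2,
            "p": self.f_pvalue,
            "n": self.n,
        }


@dataclass
class ModerationResult:
    outcome: str
    cut: float
    group_betas: dict[str, dict[str, float]]   # component -> {young, old}
    group_tvalues: dict[str, dict[str, float]]
    group_pvalues: dict[str, dict[str, float]]
    diff_tvalues: dict[str, float]
    diff_pvalues: dict[str, float]
    f_stat: float
    r2: float
    n_young: int
    n_old: int

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "age_cut": self.cut,
            "betas": self.group_betas,
            "diff_t": self.diff_tvalues,
            "diff_p": self.diff_pvalues,
            "F": self.f_stat,
            "R2": self.r2,
            "n": {"young": self.n_young, "old": self.n_old},
        }


def correlate(components: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations (with two-sided p) between each RT component and
    each cognitive test, pairwise-complete on person_id."""
    cols = _component_cols(components)
    rows = []
    for test, sc in scores.groupby("test_name"):
        merged = components.merge(sc[["person_id", "score"]], on="person_id")
        for c in cols:
            sub = merged[[c, "score"]].dropna()
            if len(sub) < 3:
                rows.append((c, test, np.nan, np.nan, len(sub), "fewer than 3 pairs"))
                continue
            if sub[c].std() == 0 or sub["score"].std() == 0:
                rows.append((c, test, np.nan, np.nan, len(sub), "zero variance"))
                continue
            r, p = scipy.stats.pearsonr(sub[c], sub["score"])
            rows.append((c, test, float(r), float(p), len(sub), ""))
    return pd.DataFrame(rows, columns=["component", "test_name", "r", "p", "n", "note"])


def _build_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Continuous covariates z-scored; categorical as indicator contrasts."""
    out = {}
    for col in covariates.columns:
        if col == "person_id":
            continue
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 10:
            out[col] = _zscore(s.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            for dc in dummies.columns:
                out[dc] = dummies[dc].to_numpy(dtype=float)
    return pd.DataFrame(out, index=covariates.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, R, piv = scipy.linalg.qr(arr, pivoting=True, mode="economic")
        bad = [X.columns[p] for p in piv[rank:]]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def regress_components(
    scores: pd.DataFrame,
    components: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    test_name: str | None = None,
) -> RegressionResult:
    """OLS of the z-scored cognitive score on z-scored RT components (plus
    optional covariates).  Component coefficients are standardized betas."""
    cols = _component_cols(components)
    sc = scores if test_name is None else scores[scores["test_name"] == test_name]
    if sc["test_name"].nunique() > 1:
        raise ValueError("scores contain multiple tests; pass test_name")
    outcome = sc["test_name"].iloc[0] if len(sc) else "score"
    data = components[["person_id"] + cols].merge(
        sc[["person_id", "score"]], on="person_id")
    if covariates is not None:
        data = data.merge(covariates, on="person_id")
    data = data.dropna()
    n = len(data)

    Xd = {c: _zscore(data[c].to_numpy(dtype=float)) for c in cols}
    if covariates is not None:
        cov_block = _build_covariates(data[[c for c in covariates.columns]])
        for c in cov_block.columns:
            Xd[c] = cov_block[c].to_numpy()
    X = pd.DataFrame(Xd)
    if n <= X.shape[1] + 1:
        raise ValueError(f"n={n} too small for {X.shape[1]} predictors")
    _check_rank(X)
    y = _zscore(data["score"].to_numpy(dtype=float))
    model = sm.OLS(y, sm.add_constant(X)).fit()

    return RegressionResult(
        outcome=outcome,
        predictors=list(X.columns),
        betas={c: float(model.params[c]) for c in cols},
        tvalues={c: float(model.tvalues[c]) for c in cols},
        pvalues={c: float(model.pvalues[c]) for c in cols},
        f_stat=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        r2=float(model.rsquared),
        f_pvalue=float(model.f_pvalue),
        n=n,
        n_tests=len(cols) + 1,
        params=model.params,
        cov_params=model.cov_params(),
    )


def moderated_regression(
    scores: pd.DataFrame,
    components: pd.DataFrame,
    age: pd.DataFrame,
    cut: float = 40.0,
    test_name: str | None = None,
) -> ModerationResult:
    """Single moderated model with age-group x component interactions.

    Uses the group-specific parameterization (separate component slopes for
    the under-``cut`` and ``cut``-plus groups, plus a group main effect), so
    within-group standardized betas are read off directly; the group
    difference per component is tested with a linear contrast on the
    coefficient covariance (equivalent to the interaction t-test).
    """
    cols = _component_cols(components)
    sc = scores if test_name is None else scores[scores["test_name"] == test_name]
    outcome = sc["test_name"].iloc[0] if len(sc) else "score"
    data = components[["person_id"] + cols].merge(
        sc[["person_id", "score"]], on="person_id").merge(
        age[["person_id", "age"]], on="person_id").dropna()
    old = (data["age"].to_numpy(dtype=float) >= cut)
    n_young, n_old = int((~old).sum()), int(old.sum())
    if n_young == 0 or n_old == 0:
        raise ValueError(f"empty age group at cut {cut} "
                         f"(young n={n_young}, old n={n_old})")
    if min(n_young, n_old) < len(cols) + 2:
        raise ValueError("a group is smaller than predictors + 2")

    y = _zscore(data["score"].to_numpy(dtype=float))
    Xd = {"old": old.astype(float)}
    for c in cols:
        z = _zscore(data[c].to_numpy(dtype=float))
        Xd[f"{c}:young"] = z * (~old)
        Xd[f"{c}:old"] = z * old
    X = pd.DataFrame(Xd)
    model = sm.OLS(y, sm.add_constant(X)).fit()

    V = model.cov_params()
    group_betas, group_t, group_p, diff_t, diff_p = {}, {}, {}, {}, {}
    for c in cols:
        ky, ko = f"{c}:young", f"{c}:old"
        group_betas[c] = {"young": float(model.params[ky]),
                          "old": float(model.params[ko])}
        group_t[c] = {"young": float(model.tvalues[ky]),
                      "old": float(model.tvalues[ko])}
        group_p[c] = {"young": float(model.pvalues[ky]),
                      "old": float(model.pvalues[ko])}
        diff = model.params[ko] - model.params[ky]
        se = np.sqrt(V.loc[ko, ko] + V.loc[ky, ky] - 2 * V.loc[ko, ky])
        t = float(diff / se)
        diff_t[c] = t
        diff_p[c] = float(2 * scipy.stats.t.sf(abs(t), model.df_resid))

    return ModerationResult(
        outcome=outcome, cut=cut,
        group_betas=group_betas, group_tvalues=group_t, group_pvalues=group_p,
        diff_tvalues=diff_t, diff_pvalues=diff_p,
        f_stat=float(model.fvalue), r2=float(model.rsquared),
        n_young=n_young, n_old=n_old,
    )
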