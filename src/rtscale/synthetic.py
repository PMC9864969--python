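"""Synthetic survey panel generator.

Emulates a long-running internet panel in which each respondent answers many
survey items over several years, with per-screen response times (RTs) recorded
as paradata, and later completes a cognitive test scored on a T-score metric
(mean 50, SD 10).

The generative model for log RTs is a person-level location-scale model with a
random slope on item time intensity (TI):

    log RT_ij = gamma00 + u0j + (gamma10 + u1j) * (TI_i - ln 10) + r_ij,
    r_ij ~ N(0, exp(omega + u2j)),   (u0j, u1j, u2j) ~ MVN(0, tau).

All logs are natural logs of seconds.  Item TIs are drawn from a truncated
normal on the log-seconds scale.  Cognitive scores are linear in the
standardized latent person effects plus Gaussian noise whose share of variance
is controlled by ``r2_cog``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

__all__ = [
    "PanelConfig",
    "SyntheticPanel",
    "generate_panel",
    "write_panel",
    "read_panel",
    "tau_with_correlations",
    "latent_correlations_for_targets",
    "DEFAULT_DEMOGRAPHIC_MARGINALS",
]

LN10 = float(np.log(10.0))

#: Category proportions for the demographic draws (panel-representative
#: marginals for a large US internet panel; ages are bands in years).
DEFAULT_DEMOGRAPHIC_MARGINALS: dict[str, dict[str, float]] = {
    "age_band": {
        "18-34": 0.2063, "35-44": 0.2061, "45-54": 0.1801,
        "55-64": 0.1955, "65-74": 0.1482, "75+": 0.0637,
    },
    "gender": {"man": 0.4112, "woman": 0.5888},
    "race_ethnicity": {
        "non_hispanic_white": 0.6361, "hispanic": 0.1778, "other_mixed": 0.1860,
    },
    "education": {
        "hs_or_less": 0.2327, "some_college": 0.3745, "college_grad": 0.3928,
    },
    "income": {
        "lt_25k": 0.2064, "25k-49k": 0.2204, "50k-74k": 0.1863,
        "75k-99k": 0.1333, "100k_plus": 0.2536,
    },
}

_AGE_BAND_RANGES = {
    "18-34": (18, 35), "35-44": (35, 45), "45-54": (45, 55),
    "55-64": (55, 65), "65-74": (65, 75), "75+": (75, 86),
}


def tau_with_correlations(variances, corr) -> np.ndarray:
    """Build a covariance matrix from variances and a correlation matrix."""
    sd = np.sqrt(np.asarray(variances, dtype=float))
    return np.asarray(corr, dtype=float) * np.outer(sd, sd)


def latent_correlations_for_targets(beta, r) -> np.ndarray:
    """Solve for the 3x3 latent correlation matrix consistent with target
    standardized regression coefficients ``beta`` and bivariate correlations
    ``r`` of the three RT components with a cognitive outcome (R_x beta = r).
    """
    beta = np.asarray(beta, float)
    r = np.asarray(r, float)
    A = np.array([
        [beta[1], beta[2], 0.0],
        [beta[0], 0.0, beta[2]],
        [0.0, beta[0], beta[1]],
    ])
    rho = np.linalg.solve(A, r - beta)
    C = np.eye(3)
    C[0, 1] = C[1, 0] = rho[0]
    C[0, 2] = C[2, 0] = rho[1]
    C[1, 2] = C[2, 1] = rho[2]
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("implied latent correlation matrix is not PSD")
    return C


def _default_tau() -> np.ndarray:
    return np.diag([0.16, 0.04, 0.25])


def _ti_variance(ti_mean, ti_sd, ti_range) -> float:
    if ti_sd <= 0:
        return 0.0
    a = (ti_range[0] - ti_mean) / ti_sd
    b = (ti_range[1] - ti_mean) / ti_sd
    return float(truncnorm.var(a, b, loc=ti_mean, scale=ti_sd))


@dataclass
class PanelConfig:
    """Conditions of the synthetic panel.

    Defaults reproduce the marginal structure of a large US probability
    internet panel: mean log RT 2.33 (SD 0.79), mean item TI 2.29 log seconds
    with range [1.14, 4.04], surveys at ~2-month intervals spanning 6.5+ years.
    """

    n_persons: int = 500
    n_surveys: int = 42
    items_per_survey: int = 28
    survey_interval_days: int = 60
    entry_window_days: int = 730
    gamma00: float = 2.33
    gamma10: float = 1.0
    omega: float | None = None  # derived from marginal SD 0.79 when None
    tau: np.ndarray = field(default_factory=_default_tau)
    ti_mean: float = 2.29
    ti_sd: float = 0.5
    ti_range: tuple[float, float] = (1.14, 4.04)
    beta_cog: tuple[float, float, float] = (-0.28, 0.50, -0.15)
    r2_cog: float = 0.26
    contamination_rate: float = 0.0
    contamination_multiplier: tuple[float, float] = (10.0, 50.0)
    age_moderation: float = 1.0
    age_cut: float = 40.0
    test_name: str = "number_series"
    marginal_log_rt_sd: float = 0.79
    base_date: str = "2014-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        if self.tau.shape != (3, 3):
            raise ValueError("tau must be 3x3 (u0, u1, u2)")
        if not np.allclose(self.tau, self.tau.T, atol=1e-10):
            raise ValueError(f"tau must be symmetric, got\n{self.tau}")
        eig = np.linalg.eigvalsh(self.tau)
        if eig.min() < -1e-10:
            raise ValueError(
                f"tau is not positive semidefinite (min eigenvalue {eig.min():.3g}):\n{self.tau}"
            )
        if not 0.0 <= self.contamination_rate < 0.1:
            raise ValueError("contamination_rate must be in [0, 0.1)")
        if not 0.0 <= self.r2_cog <= 1.0:
            raise ValueError("r2_cog must be in [0, 1]")
        if not self.ti_range[0] < self.ti_range[1]:
            raise ValueError("ti_range must be increasing")
        if self.omega is None:
            self.omega = self.derived_omega()

    def derived_omega(self) -> float:
        """omega such that the marginal SD of log RT matches
        ``marginal_log_rt_sd`` under the variance decomposition
        Var = tau00 + (gamma10^2 + tau11) * var(TI) + E[exp(omega + u2)].
        """
        s2_ti = _ti_variance(self.ti_mean, self.ti_sd, self.ti_range)
        resid = (
            self.marginal_log_rt_sd ** 2
            - self.tau[0, 0]
            - (self.gamma10 ** 2 + self.tau[1, 1]) * s2_ti
        )
        if resid <= 0:
            raise ValueError(
                "marginal_log_rt_sd too small for the person/TI variance components"
            )
        return float(np.log(resid) - self.tau[2, 2] / 2.0)

    def marginal_log_rt_variance(self) -> float:
        """Closed-form marginal variance of log RT implied by the config."""
        s2_ti = _ti_variance(self.ti_mean, self.ti_sd, self.ti_range)
        return float(
            self.tau[0, 0]
            + (self.gamma10 ** 2 + self.tau[1, 1]) * s2_ti
            + np.exp(self.omega + self.tau[2, 2] / 2.0)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tau"] = self.tau.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        d = dict(d)
        if "tau" in d:
            d["tau"] = np.asarray(d["tau"], dtype=float)
        for key in ("ti_range", "beta_cog", "contamination_multiplier"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticPanel:
    """A generated panel: RT records with full latent truth."""

    rt_records: pd.DataFrame  # person_id, item_id, survey_id, survey_date, rt_seconds, contaminated
    items: pd.DataFrame       # item_id, survey_id, single_page, open_ended
    item_truth: pd.DataFrame  # item_id, ti_log
    person_truth: pd.DataFrame  # person_id, u0..u2, alpha, beta, log_sigma2
    cognitive_scores: pd.DataFrame  # person_id, test_name, score, test_date
    demographics: pd.DataFrame
    survey_dates: pd.DataFrame  # person_id, survey_id, survey_date
    config: PanelConfig


def _draw_latents(rng: np.random.Generator, tau: np.ndarray, n: int) -> np.ndarray:
    # eigendecomposition handles singular tau (degenerate random effects)
    w, V = np.linalg.eigh(tau)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((n, 3))
    return z @ (V * np.sqrt(w)).T


def _draw_demographics(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"person_id": np.arange(n)}
    for var, marg in DEFAULT_DEMOGRAPHIC_MARGINALS.items():
        cats = list(marg)
        p = np.array([marg[c] for c in cats])
        cols[var] = rng.choice(cats, size=n, p=p / p.sum())
    df = pd.DataFrame(cols)
    lo = np.array([_AGE_BAND_RANGES[b][0] for b in df["age_band"]])
    hi = np.array([_AGE_BAND_RANGES[b][1] for b in df["age_band"]])
    df["age"] = np.floor(lo + rng.random(n) * (hi - lo)).astype(int)
    return df


def generate_panel(config: PanelConfig) -> SyntheticPanel:
    """Generate a full synthetic panel.  Bit-reproducible given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    J, S, K = cfg.n_persons, cfg.n_surveys, cfg.items_per_survey
    n_items = S * K

    demographics = _draw_demographics(rng, J)

    u = _draw_latents(rng, cfg.tau, J)  # (J, 3)
    alpha = cfg.gamma00 + u[:, 0]
    beta = cfg.gamma10 + u[:, 1]
    log_sigma2 = cfg.omega + u[:, 2]

    # item TIs on the log-seconds scale, truncated normal
    if cfg.ti_sd > 0:
        a = (cfg.ti_range[0] - cfg.ti_mean) / cfg.ti_sd
        b = (cfg.ti_range[1] - cfg.ti_mean) / cfg.ti_sd
        ti = truncnorm.rvs(a, b, loc=cfg.ti_mean, scale=cfg.ti_sd,
                           size=n_items, random_state=rng)
    else:
        ti = np.full(n_items, cfg.ti_mean)
    item_id = np.arange(n_items)
    item_survey = np.repeat(np.arange(S), K)

    # survey calendar: staggered entry, fixed cadence thereafter
    base = pd.Timestamp(cfg.base_date)
    entry = rng.integers(0, max(cfg.entry_window_days, 1), size=J)
    survey_offsets = np.arange(S) * cfg.survey_interval_days
    sdates = entry[:, None] + survey_offsets[None, :]  # (J, S) days since base

    # long-format RT records: every person answers every item of every survey
    pid = np.repeat(np.arange(J), n_items)
    iid = np.tile(item_id, J)
    sid = np.tile(item_survey, J)
    ti_long = np.tile(ti, J)
    sigma = np.exp(0.5 * log_sigma2)
    log_rt = (
        alpha[pid]
        + beta[pid] * (ti_long - LN10)
        + rng.standard_normal(J * n_items) * sigma[pid]
    )
    rt_seconds = np.exp(log_rt)

    contaminated = np.zeros(J * n_items, dtype=bool)
    if cfg.contamination_rate > 0:
        contaminated = rng.random(J * n_items) < cfg.contamination_rate
        mult = rng.uniform(*cfg.contamination_multiplier, size=int(contaminated.sum()))
        rt_seconds = rt_seconds.copy()
        rt_seconds[contaminated] *= mult

    day_long = sdates[pid, sid]
    rt_records = pd.DataFrame({
        "person_id": pid,
        "item_id": iid,
        "survey_id": sid,
        "survey_date": base + pd.to_timedelta(day_long, unit="D"),
        "rt_seconds": rt_seconds,
        "contaminated": contaminated,
    })

    items = pd.DataFrame({
        "item_id": item_id,
        "survey_id": item_survey,
        "single_page": 1,
        "open_ended": 0,
    })
    item_truth = pd.DataFrame({"item_id": item_id, "ti_log": ti})

    # cognitive scores: T-score = 50 + 10*(signal + noise)
    sd_u = np.sqrt(np.diag(cfg.tau))
    z = np.where(sd_u > 0, u / np.where(sd_u > 0, sd_u, 1.0), 0.0)
    bvec = np.asarray(cfg.beta_cog, float)
    b0 = np.where(demographics["age"].to_numpy() >= cfg.age_cut,
                  bvec[0] * cfg.age_moderation, bvec[0])
    signal = b0 * z[:, 0] + bvec[1] * z[:, 1] + bvec[2] * z[:, 2]
    corr = np.zeros((3, 3))
    nz = sd_u > 0
    if nz.any():
        corr[np.ix_(nz, nz)] = cfg.tau[np.ix_(nz, nz)] / np.outer(sd_u[nz], sd_u[nz])
    var_signal = float(bvec @ corr @ bvec)
    if cfg.r2_cog >= 1.0:
        noise_sd = 0.0
    elif cfg.r2_cog <= 0.0:
        noise_sd = 1.0 if var_signal == 0 else np.sqrt(var_signal)
        signal = np.zeros_like(signal)
    else:
        noise_sd = np.sqrt(max(var_signal, 1e-30) * (1 - cfg.r2_cog) / cfg.r2_cog)
    score = 50.0 + 10.0 * (signal + noise_sd * rng.standard_normal(J))

    last_survey_day = sdates[:, -1]
    test_day = last_survey_day + rng.integers(1, cfg.survey_interval_days + 1, size=J)
    cognitive_scores = pd.DataFrame({
        "person_id": np.arange(J),
        "test_name": cfg.test_name,
        "score": score,
        "test_date": base + pd.to_timedelta(test_day, unit="D"),
    })

    person_truth = pd.DataFrame({
        "person_id": np.arange(J),
        "u0": u[:, 0], "u1": u[:, 1], "u2": u[:, 2],
        "alpha": alpha, "beta": beta, "log_sigma2": log_sigma2,
        "z_u0": z[:, 0], "z_u1": z[:, 1], "z_u2": z[:, 2],
    })

    survey_dates = pd.DataFrame({
        "person_id": np.repeat(np.arange(J), S),
        "survey_id": np.tile(np.arange(S), J),
        "survey_date": base + pd.to_timedelta(sdates.ravel(), unit="D"),
    })

    return SyntheticPanel(
        rt_records=rt_records, items=items, item_truth=item_truth,
        person_truth=person_truth, cognitive_scores=cognitive_scores,
        demographics=demographics, survey_dates=survey_dates, config=cfg,
    )


_FILES = {
    "rt_records": "rt_records.csv",
    "items": "items.csv",
    "item_truth": "truth/items.csv",
    "person_truth": "truth/persons.csv",
    "cognitive_scores": "scores.csv",
    "demographics": "demographics.csv",
    "survey_dates": "survey_dates.csv",
}


def write_panel(panel: SyntheticPanel, directory: str | Path) -> list[Path]:
    """Write all panel tables as CSV (plus the config as YAML); lossless
    round trip via :func:`read_panel`."""
    directory = Path(directory)
    (directory / "truth").mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in _FILES.items():
        path = directory / fname
        getattr(panel, attr).to_csv(path, index=False)
        written.append(path)
    cfg_path = directory / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(panel.config.to_dict(), fh, sort_keys=False)
    written.append(cfg_path)
    return written


def read_panel(directory: str | Path) -> SyntheticPanel:
    directory = Path(directory)
    tables = {}
    for attr, fname in _FILES.items():
        df = pd.read_csv(directory / fname)
        for col in ("survey_date", "test_date"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        tables[attr] = df
    with open(directory / "config.yaml") as fh:
        cfg = PanelConfig.from_dict(yaml.safe_load(fh))
    return SyntheticPanel(config=cfg, **tables)
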