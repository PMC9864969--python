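"""Item time-intensity (TI) estimation.

The TI of a survey item is the latent expected log time the item requires —
the RT analogue of item difficulty.  TIs are estimated from cleaned log RTs
with a cross-classified (crossed persons x items) random-effects model

    log RT_ij = mu + p_j + q_i + e_ij,
    p_j ~ N(0, sigma_p^2),  q_i ~ N(0, sigma_q^2),  e_ij ~ N(0, sigma_e^2),

and reported as ``ti_log = mu_hat + EB(q_i)`` where EB is the empirical-Bayes
(posterior mean) item effect.  TIs are then centered at a 10-second reference
(``ti_centered = ti_log - ln 10``) before entering the expanded
location-scale model as a fixed covariate; estimation uncertainty is not
propagated downstream (the two-stage procedure is deliberate).

Two estimators are provided: a fully conjugate Gibbs sampler (default) and a
profiled-REML fit of the same model through dense Henderson mixed-model
equations, used as a fast cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TimeIntensityFit",
    "estimate_time_intensities",
    "center_ti",
    "eb_crossed",
    "reml_crossed",
]

LN10 = float(np.log(10.0))


@dataclass
class TimeIntensityFit:
    """Estimated item TIs plus the variance components behind them."""

    ti: pd.DataFrame  # item_id, ti_log, ti_centered, ti_se, n_obs, flagged
    mu: float
    sigma_p2: float
    sigma_q2: float
    sigma_e2: float
    method: str


def _check_design(person_idx: np.ndarray, item_idx: np.ndarray,
                  n_persons: int, n_items: int) -> None:
    if n_items < 2:
        raise ValueError("TI estimation needs at least 2 items")
    if n_persons < 2:
        raise ValueError("TI estimation needs at least 2 persons")
    rows = np.concatenate([person_idx, item_idx + n_persons])
    cols = np.concatenate([item_idx + n_persons, person_idx])
    adj = scipy.sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_persons + n_items,) * 2
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"person-item design is disconnected: {n_comp} components "
            f"with sizes {sorted(sizes.tolist(), reverse=True)[:5]}"
        )


def eb_crossed(
    y: np.ndarray,
    person_idx: np.ndarray,
    item_idx: np.ndarray,
    sigma_p2: float,
    sigma_q2: float,
    sigma_e2: float,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """GLS fixed intercept and EB random effects at fixed variance components.

    Solves the Henderson mixed-model equations densely.  Returns
    ``(mu_hat, p_hat, q_hat, se_q)`` where ``se_q`` is the prediction SE of
    ``mu + q_i`` from the joint (mu, q) covariance block.
    """
    J = int(person_idx.max()) + 1
    I = int(item_idx.max()) + 1
    n = y.size
    Zp = scipy.sparse.coo_matrix((np.ones(n), (np.arange(n), person_idx)), shape=(n, J))
    Zq = scipy.sparse.coo_matrix((np.ones(n), (np.arange(n), item_idx)), shape=(n, I))
    # coefficient order: [mu, p (J), q (I)]
    dim = 1 + J + I
    C = np.zeros((dim, dim))
    nj = np.bincount(person_idx, minlength=J).astype(float)
    ni = np.bincount(item_idx, minlength=I).astype(float)
    Npq = (Zp.T @ Zq).toarray()
    C[0, 0] = n
    C[0, 1:1 + J] = nj
    C[0, 1 + J:] = ni
    C[1:1 + J, 0] = nj
    C[1 + J:, 0] = ni
    C[1:1 + J, 1:1 + J] = np.diag(nj)
    C[1 + J:, 1 + J:] = np.diag(ni)
    C[1:1 + J, 1 + J:] = Npq
    C[1 + J:, 1:1 + J] = Npq.T
    C /= sigma_e2
    # ridge from the random-effect priors
    lam = np.concatenate([[0.0], np.full(J, 1.0 / max(sigma_p2, 1e-12)),
                          np.full(I, 1.0 / max(sigma_q2, 1e-12))])
    C[np.diag_indices(dim)] += lam
    rhs = np.concatenate([
        [y.sum()], np.bincount(person_idx, weights=y, minlength=J),
        np.bincount(item_idx, weights=y, minlength=I),
    ]) / sigma_e2
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    mu_hat = float(sol[0])
    p_hat = sol[1:1 + J]
    q_hat = sol[1 + J:]
    # prediction variance of mu + q_i
    var = Cinv[0, 0] + np.diag(Cinv)[1 + J:] + 2.0 * Cinv[0, 1 + J:]
    return mu_hat, p_hat, q_hat, np.sqrt(np.maximum(var, 0.0))


def reml_crossed(
    y: np.ndarray, person_idx: np.ndarray, item_idx: np.ndarray,
) -> tuple[float, float, float]:
    """Profiled REML estimates of (sigma_p2, sigma_q2, sigma_e2) for the
    crossed model, via the Woodbury identity on dense normal equations."""
    J = int(person_idx.max()) + 1
    I = int(item_idx.max()) + 1
    n = y.size
    nj = np.bincount(person_idx, minlength=J).astype(float)
    ni = np.bincount(item_idx, minlength=I).astype(float)
    Zp = scipy.sparse.coo_matrix((np.ones(n), (np.arange(n), person_idx)), shape=(n, J))
    Zq = scipy.sparse.coo_matrix((np.ones(n), (np.arange(n), item_idx)), shape=(n, I))
    Npq = (Zp.T @ Zq).toarray()
    ZtZ = np.block([[np.diag(nj), Npq], [Npq.T, np.diag(ni)]])
    Ztx = np.concatenate([nj, ni])
    Zty = np.concatenate([
        np.bincount(person_idx, weights=y, minlength=J),
        np.bincount(item_idx, weights=y, minlength=I),
    ])
    yty = float(y @ y)
    xty = float(y.sum())

    def neg_reml(logpars: np.ndarray) -> float:
        sp2, sq2, se2 = np.exp(np.clip(logpars, -30, 30))
        g = np.concatenate([np.full(J, sp2), np.full(I, sq2)])
        Q = ZtZ / se2 + np.diag(1.0 / g)
        try:
            L = np.linalg.cholesky(Q)
        except np.linalg.LinAlgError:
            return 1e12
        logdetQ = 2.0 * np.log(np.diag(L)).sum()
        logdetV = n * np.log(se2) + np.log(g).sum() + logdetQ
        a = np.linalg.solve(L, np.column_stack([Ztx, Zty]))
        xvx = (n - (a[:, 0] @ a[:, 0]) / se2) / se2
        xvy = (xty - (a[:, 0] @ a[:, 1]) / se2) / se2
        yvy = (yty - (a[:, 1] @ a[:, 1]) / se2) / se2
        if xvx <= 0:
            return 1e12
        ypy = yvy - xvy ** 2 / xvx
        return 0.5 * (logdetV + np.log(xvx) + ypy)

    y_var = float(np.var(y)) or 1.0
    x0 = np.log([y_var / 4, y_var / 4, y_var / 2])
    res = scipy.optimize.minimize(neg_reml, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 600})
    sp2, sq2, se2 = np.exp(res.x)
    return float(sp2), float(sq2), float(se2)


def _gibbs_crossed(
    y: np.ndarray, person_idx: np.ndarray, item_idx: np.ndarray,
    iterations: int, burn_in: int, seed: int,
) -> tuple[float, np.ndarray, np.ndarray, dict[str, float]]:
    """Fully conjugate Gibbs sampler; returns posterior means of mu, mu+q_i,
    their posterior SDs and variance components."""
    rng = np.random.default_rng(seed)
    J = int(person_idx.max()) + 1
    I = int(item_idx.max()) + 1
    n = y.size
    nj = np.bincount(person_idx, minlength=J).astype(float)
    ni = np.bincount(item_idx, minlength=I).astype(float)

    mu = float(y.mean())
    p = np.zeros(J)
    q = np.zeros(I)
    sp2 = sq2 = se2 = max(float(np.var(y)) / 3.0, 1e-4)
    a0 = b0 = 1e-3  # diffuse inverse-gamma hyperparameters

    keep = iterations - burn_in
    ti_sum = np.zeros(I)
    ti_sumsq = np.zeros(I)
    acc = {"mu": 0.0, "sigma_p2": 0.0, "sigma_q2": 0.0, "sigma_e2": 0.0}
    for it in range(iterations):
        # mu | rest (flat prior)
        resid0 = y - p[person_idx] - q[item_idx]
        mu = rng.normal(resid0.mean(), np.sqrt(se2 / n))
        # p | rest
        rp = np.bincount(person_idx, weights=y - mu - q[item_idx], minlength=J)
        prec = nj / se2 + 1.0 / sp2
        p = rng.normal((rp / se2) / prec, np.sqrt(1.0 / prec))
        # q | rest
        rq = np.bincount(item_idx, weights=y - mu - p[person_idx], minlength=I)
        prec = ni / se2 + 1.0 / sq2
        q = rng.normal((rq / se2) / prec, np.sqrt(1.0 / prec))
        # variance components | rest
        sp2 = 1.0 / rng.gamma(a0 + J / 2.0, 1.0 / (b0 + 0.5 * p @ p))
        sq2 = 1.0 / rng.gamma(a0 + I / 2.0, 1.0 / (b0 + 0.5 * q @ q))
        e = y - mu - p[person_idx] - q[item_idx]
        se2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * e @ e))
        if it >= burn_in:
            ti = mu + q
            ti_sum += ti
            ti_sumsq += ti * ti
            acc["mu"] += mu
            acc["sigma_p2"] += sp2
            acc["sigma_q2"] += sq2
            acc["sigma_e2"] += se2
    ti_mean = ti_sum / keep
    ti_sd = np.sqrt(np.maximum(ti_sumsq / keep - ti_mean ** 2, 0.0))
    for k in acc:
        acc[k] /= keep
    return acc.pop("mu"), ti_mean, ti_sd, acc


def estimate_time_intensities(
    records: pd.DataFrame,
    method: str = "mcmc",
    reference_seconds: float = 10.0,
    iterations: int = 1500,
    burn_in: int = 500,
    seed: int = 0,
    min_obs_flag: int = 10,
) -> TimeIntensityFit:
    """Estimate per-item TIs from cleaned records (requires ``log_rt``).

    ``method="mcmc"`` (default) uses the conjugate Gibbs sampler;
    ``method="reml"`` uses profiled REML plus EB at the REML variances.
    Deterministic given ``seed``.
    """
    y = records["log_rt"].to_numpy(dtype=float)
    person_codes, _ = pd.factorize(records["person_id"])
    item_codes, item_ids = pd.factorize(records["item_id"])
    J = person_codes.max() + 1 if len(records) else 0
    I = item_codes.max() + 1 if len(records) else 0
    _check_design(person_codes, item_codes, J, I)

    if method == "mcmc":
        mu, ti_log, ti_se, vcomp = _gibbs_crossed(
            y, person_codes, item_codes, iterations, burn_in, seed)
    elif method == "reml":
        sp2, sq2, se2 = reml_crossed(y, person_codes, item_codes)
        mu, _, q_hat, se_q = eb_crossed(y, person_codes, item_codes, sp2, sq2, se2)
        ti_log = mu + q_hat
        ti_se = se_q
        vcomp = {"sigma_p2": sp2, "sigma_q2": sq2, "sigma_e2": se2}
    else:
        raise ValueError("method must be 'mcmc' or 'reml'")

    n_obs = np.bincount(item_codes, minlength=I)
    ti = pd.DataFrame({
        "item_id": item_ids,
        "ti_log": ti_log,
        "ti_centered": ti_log - np.log(reference_seconds),
        "ti_se": ti_se,
        "n_obs": n_obs,
        "flagged": n_obs < min_obs_flag,
    })
    return TimeIntensityFit(ti=ti, mu=float(mu), method=method, **vcomp)


def center_ti(ti: pd.DataFrame, reference_seconds: float = 10.0) -> pd.DataFrame:
    """Recompute ``ti_centered = ti_log - ln(reference_seconds)``."""
    if reference_seconds <= 0:
        raise ValueError("reference_seconds must be positive")
    out = ti.copy()
    out["ti_centered"] = out["ti_log"] - np.log(reference_seconds)
    return out
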