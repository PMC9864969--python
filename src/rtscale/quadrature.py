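"""Adaptive Gauss-Hermite (AGH) marginal likelihood for the location-scale
models, and a maximum-marginal-likelihood (MML) fitter built on it.

This is the independent, sampler-free route to the same models fit by MCMC in
:mod:`rtscale.location_scale`: the person random effects are integrated out
numerically (person by person, with the quadrature grid recentered and
rescaled at each person's posterior mode), and the fixed effects plus tau can
be estimated by direct maximization of the integrated likelihood.  Intended
for small data sets (<= 3 random-effect dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import logsumexp

from .location_scale import PersonStats, person_stats

__all__ = [
    "LocationScaleParams",
    "marginal_loglik_quadrature",
    "marginal_loglik_stats",
    "fit_mml",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LocationScaleParams:
    """Point parameters of a (possibly expanded) location-scale model."""

    gamma00: float
    omega: float
    tau: np.ndarray
    gamma10: float | None = None

    def __post_init__(self) -> None:
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        d = 3 if self.gamma10 is not None else 2
        if self.tau.shape != (d, d):
            raise ValueError(f"tau must be {d}x{d} for this model")
        if not np.allclose(self.tau, self.tau.T, atol=1e-10):
            raise ValueError("tau must be symmetric")
        if np.linalg.eigvalsh(self.tau).min() < -1e-10:
            raise ValueError(f"tau is not positive semidefinite:\n{self.tau}")

    @property
    def expanded(self) -> bool:
        return self.gamma10 is not None


def _loglik_terms(stats: PersonStats, alpha, beta, s):
    """Per-person log density of the data given person parameters.

    All of ``alpha``, ``beta``, ``s`` broadcast against the (J,)-shaped
    sufficient statistics (extra trailing axes allowed).
    """
    n = stats.n
    while n.ndim < np.ndim(alpha):
        n = n[..., None]
    rss = _bcast_rss(stats, alpha, beta)
    with np.errstate(over="ignore"):  # -inf log density is a valid rejection
        return -0.5 * n * (_LOG2PI + s) - 0.5 * rss * np.exp(-s)


def _bcast_rss(stats: PersonStats, alpha, beta):
    def exp_dims(a):
        a = np.asarray(a, float)
        while a.ndim < np.ndim(alpha):
            a = a[..., None]
        return a

    Syy, Sy, n = exp_dims(stats.Syy), exp_dims(stats.Sy), exp_dims(stats.n)
    if beta is None:
        return Syy - 2 * alpha * Sy + alpha ** 2 * n
    Sxy, Sx, Sxx = exp_dims(stats.Sxy), exp_dims(stats.Sx), exp_dims(stats.Sxx)
    return (Syy - 2 * alpha * Sy - 2 * beta * Sxy + alpha ** 2 * n
            + 2 * alpha * beta * Sx + beta ** 2 * Sxx)


def _closed_form_loglik(stats: PersonStats, params: LocationScaleParams) -> float:
    """No random effects: independent normal errors, exact."""
    alpha = np.full(stats.n_persons, params.gamma00)
    beta = (np.full(stats.n_persons, params.gamma10)
            if params.expanded else None)
    s = np.full(stats.n_persons, params.omega)
    return float(_loglik_terms(stats, alpha, beta, s).sum())


def _find_modes(stats: PersonStats, params: LocationScaleParams,
                tau_inv: np.ndarray, dl: int,
                u_init: np.ndarray | None = None):
    """Vectorized damped Newton search for each person's posterior mode of
    the random-effect vector u (location dims first, scale last).

    ``u_init`` (e.g. modes from a nearby parameter value) short-circuits the
    search to a couple of Newton steps.
    """
    J = stats.n_persons
    d = dl + 1
    if u_init is not None and u_init.shape == (J, d):
        u = u_init.copy()
    else:
        # warm start near the per-person least-squares solution (shrunk halfway)
        u = np.zeros((J, d))
        mean_y = stats.Sy / np.maximum(stats.n, 1.0)
        if stats.expanded:
            det = stats.n * stats.Sxx - stats.Sx ** 2
            ok = det > 1e-10
            b_ols = np.where(ok, (stats.n * stats.Sxy - stats.Sx * stats.Sy)
                             / np.where(ok, det, 1.0), 0.0)
            a_ols = (stats.Sy - b_ols * stats.Sx) / np.maximum(stats.n, 1.0)
            u[:, 0] = 0.5 * (a_ols - params.gamma00)
            u[:, 1] = 0.5 * (b_ols - params.gamma10)
            rss0 = stats.rss(a_ols, b_ols)
        else:
            u[:, 0] = 0.5 * (mean_y - params.gamma00)
            rss0 = stats.rss(mean_y, None)
        s_ols = np.log(np.maximum(rss0 / np.maximum(stats.n, 1.0), 1e-10))
        u[:, dl] = 0.5 * np.clip(s_ols - params.omega, -5.0, 5.0)

    if stats.expanded:
        C = np.empty((J, 2, 2))
        C[:, 0, 0] = stats.n
        C[:, 0, 1] = C[:, 1, 0] = stats.Sx
        C[:, 1, 1] = stats.Sxx
        bvec = np.column_stack([stats.Sy, stats.Sxy])
        gamma_loc = np.array([params.gamma00, params.gamma10])
    else:
        C = stats.n.reshape(J, 1, 1)
        bvec = stats.Sy[:, None]
        gamma_loc = np.array([params.gamma00])

    def negh(u):
        theta = gamma_loc[None, :] + u[:, :dl]
        s = params.omega + u[:, dl]
        ll = _loglik_terms(stats, theta[:, 0],
                           theta[:, 1] if stats.expanded else None, s)
        prior = -0.5 * np.einsum("ja,ab,jb->j", u, tau_inv, u)
        return -(ll + prior)

    def grad_hess(u):
        theta = gamma_loc[None, :] + u[:, :dl]
        s = params.omega + u[:, dl]
        es = np.exp(-s)
        Ct_b = np.einsum("jab,jb->ja", C, theta) - bvec
        rss = _bcast_rss(stats, theta[:, 0],
                         theta[:, 1] if stats.expanded else None)
        g = np.empty((J, d))
        g[:, :dl] = es[:, None] * Ct_b
        g[:, dl] = 0.5 * stats.n - 0.5 * rss * es
        g += u @ tau_inv
        H = np.zeros((J, d, d))
        H[:, :dl, :dl] = C * es[:, None, None]
        H[:, :dl, dl] = H[:, dl, :dl] = -es[:, None] * Ct_b
        H[:, dl, dl] = 0.5 * rss * es
        H += tau_inv[None, :, :]
        return g, H

    h = negh(u)
    for _ in range(60):
        g, H = grad_hess(u)
        if np.max(np.abs(g)) < 1e-8:
            break
        # eigenvalue clipping: away from the mode the joint log-density is
        # not concave, so force a positive-definite curvature to guarantee a
        # descent direction, then backtrack
        w, Q = np.linalg.eigh(H)
        w = np.maximum(w, 1e-6 * np.abs(w).max(axis=1, keepdims=True))
        delta = np.einsum("jab,jb->ja", Q, np.einsum("jab,ja->jb", Q, g) / w)
        step = np.ones(J)
        for _ in range(30):
            u_new = u - step[:, None] * delta
            h_new = negh(u_new)
            worse = ~np.isfinite(h_new) | (h_new > h - 1e-14)
            if not worse.any():
                break
            step[worse] *= 0.5
        u_new = u - step[:, None] * delta
        h_new = negh(u_new)
        improved = np.isfinite(h_new) & (h_new <= h)
        u = np.where(improved[:, None], u_new, u)
        h = np.where(improved, h_new, h)
        if not improved.any():
            break

    _, H = grad_hess(u)  # final Hessian at the mode (undamped)
    return u, H, gamma_loc


def marginal_loglik_stats(
    stats: PersonStats, params: LocationScaleParams, nodes: int = 15,
    mode_cache: dict | None = None,
) -> float:
    """AGH integrated log likelihood from per-person sufficient statistics.

    ``mode_cache`` (a mutable dict) carries the person modes between calls at
    nearby parameter values, as during MML optimization.
    """
    if nodes < 1:
        raise ValueError("nodes must be >= 1")
    tau = params.tau
    d = tau.shape[0]
    dl = d - 1
    diag = np.diag(tau)
    if np.all(diag < 1e-12):
        return _closed_form_loglik(stats, params)
    if np.any(diag < 1e-12):
        raise ValueError(
            "mixed degenerate/non-degenerate tau diagonals are not supported; "
            "drop the degenerate random effect from the model instead")

    tau_chol = np.linalg.cholesky(tau + 1e-300 * np.eye(d))
    tau_inv = np.linalg.inv(tau)
    logdet_tau = 2.0 * np.log(np.diag(tau_chol)).sum()

    u_init = mode_cache.get("u") if mode_cache is not None else None
    u_mode, H, gamma_loc = _find_modes(stats, params, tau_inv, dl, u_init=u_init)
    if mode_cache is not None:
        mode_cache["u"] = u_mode
    # guard against indefinite curvature when a person's mode is flat
    w, Q = np.linalg.eigh(H)
    floor = 1e-8 * np.maximum(np.abs(w).max(axis=1, keepdims=True), 1.0)
    w = np.maximum(w, floor)
    H = np.einsum("jab,jb,jcb->jac", Q, w, Q)

    z1, w1 = np.polynomial.hermite.hermgauss(nodes)
    grids = np.meshgrid(*([z1] * d), indexing="ij")
    zg = np.column_stack([g.ravel() for g in grids])       # (K, d)
    wgrids = np.meshgrid(*([np.log(w1)] * d), indexing="ij")
    logw = (np.sum(np.column_stack([g.ravel() for g in wgrids]), axis=1)
            + np.sum(zg ** 2, axis=1))

    L = np.linalg.cholesky(H)
    B = np.linalg.inv(np.swapaxes(L, 1, 2))                # B B' = H^-1
    logdetB = -np.log(L[:, np.arange(d), np.arange(d)]).sum(axis=1)

    pts = u_mode[:, None, :] + np.sqrt(2.0) * np.einsum("jab,kb->jka", B, zg)
    theta = gamma_loc[None, None, :] + pts[:, :, :dl]
    s = params.omega + pts[:, :, d - 1]
    alpha = theta[:, :, 0]
    beta = theta[:, :, 1] if stats.expanded else None
    ll = _loglik_terms(stats, alpha, beta, s)
    quad = np.einsum("jka,ab,jkb->jk", pts, tau_inv, pts)
    logprior = -0.5 * (d * _LOG2PI + logdet_tau) - 0.5 * quad
    per_person = (0.5 * d * np.log(2.0) + logdetB
                  + logsumexp(logw[None, :] + ll + logprior, axis=1))
    return float(per_person.sum())


def marginal_loglik_quadrature(
    records: pd.DataFrame,
    params: LocationScaleParams,
    nodes: int = 15,
    ti: pd.DataFrame | None = None,
) -> float:
    """AGH integrated log likelihood of cleaned records under ``params``.

    The expanded model is assumed when ``params.gamma10`` is set (``ti`` is
    then required).  Exact (no integration) when tau == 0.
    """
    stats = person_stats(records, ti=ti, expanded=params.expanded)
    return marginal_loglik_stats(stats, params, nodes=nodes)


def _pack_tau(tau: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(tau + 1e-8 * np.eye(tau.shape[0]))
    d = tau.shape[0]
    out = [np.log(L[i, i]) for i in range(d)]
    out += [L[i, j] for i in range(d) for j in range(i)]
    return np.array(out)


def _unpack_tau(x: np.ndarray, d: int) -> np.ndarray:
    L = np.zeros((d, d))
    L[np.arange(d), np.arange(d)] = np.exp(np.clip(x[:d], -15, 15))
    k = d
    for i in range(d):
        for j in range(i):
            L[i, j] = x[k]
            k += 1
    return L @ L.T


def fit_mml(
    records: pd.DataFrame,
    expanded: bool = False,
    ti: pd.DataFrame | None = None,
    nodes: int | None = None,
    maxiter: int = 4000,
) -> dict:
    """Maximum marginal likelihood point estimates via AGH quadrature.

    Optimizes fixed effects and the log-Cholesky factor of tau by
    Nelder-Mead.  Returns a dict with ``gamma00``, ``gamma10`` (expanded
    only), ``omega``, ``tau``, ``loglik`` and ``converged``.
    """
    stats = person_stats(records, ti=ti, expanded=expanded)
    d = 3 if expanded else 2
    if nodes is None:
        nodes = 15 if d == 2 else 11

    # moment starting values from per-person least squares
    if expanded:
        det = stats.n * stats.Sxx - stats.Sx ** 2
        ok = det > 1e-10
        beta = np.where(ok, (stats.n * stats.Sxy - stats.Sx * stats.Sy)
                        / np.where(ok, det, 1.0), 0.0)
        alpha = (stats.Sy - beta * stats.Sx) / stats.n
        vhat = np.column_stack([alpha, beta])
        p = 2
    else:
        vhat = (stats.Sy / stats.n)[:, None]
        p = 1
    rss = stats.rss(vhat[:, 0], vhat[:, 1] if expanded else None)
    sig2 = np.maximum(rss / np.maximum(stats.n - p, 1.0), 1e-4)
    v = np.column_stack([vhat, np.log(sig2)])
    mu0 = v.mean(axis=0)
    # moment start: subtract the average sampling variance of each person
    # estimate from the raw between-person variance
    tau0 = np.cov(v.T)
    noise = np.zeros(d)
    noise[0] = np.mean(sig2 / stats.n)
    if expanded:
        xvar = np.maximum(stats.Sxx / stats.n - (stats.Sx / stats.n) ** 2, 1e-8)
        noise[1] = np.mean(sig2 / (stats.n * xvar))
    noise[d - 1] = np.mean(2.0 / np.maximum(stats.n - p, 1.0))
    tau0 = tau0 - np.diag(noise)
    w0, Q0 = np.linalg.eigh(tau0)
    tau0 = Q0 @ np.diag(np.maximum(w0, 1e-3)) @ Q0.T

    x0 = np.concatenate([mu0, _pack_tau(tau0)])
    cache: dict = {}

    def objective(x: np.ndarray) -> float:
        mu = x[:d]
        tau = _unpack_tau(x[d:], d)
        params = LocationScaleParams(
            gamma00=mu[0], omega=mu[d - 1], tau=tau,
            gamma10=mu[1] if expanded else None)
        try:
            return -marginal_loglik_stats(stats, params, nodes=nodes,
                                          mode_cache=cache)
        except np.linalg.LinAlgError:
            return 1e12

    res = scipy.optimize.minimize(
        objective, x0, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7})
    # polish with a short simplex pass in case finite-difference gradients
    # stalled early
    res = scipy.optimize.minimize(
        objective, res.x, method="Nelder-Mead",
        options={"maxiter": 400, "xatol": 1e-5, "fatol": 1e-8})
    mu = res.x[:d]
    tau = _unpack_tau(res.x[d:], d)
    out = {
        "gamma00": float(mu[0]),
        "omega": float(mu[d - 1]),
        "tau": tau,
        "loglik": float(-res.fun),
        "converged": bool(res.success),
    }
    if expanded:
        out["gamma10"] = float(mu[1])
    return out
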