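"""Poisson regression with a log-gamma random effect, fitted per bin.

The count for sample i is modelled as Y_i ~ Poisson(lambda_i) with
log(lambda_i) = mu + X beta + e_i, where e_i = log w_i and
w_i ~ Gamma(psi, psi) has mean 1.  Integrating out w_i gives the marginal
log likelihood

    sum_i [ Y_i (mu + X beta) + psi log psi + log Gamma(Y_i + psi)
            - log Y_i! - log Gamma(psi)
            - (Y_i + psi) log(e^{mu + X beta} + psi) ],

which is exactly a negative binomial with shape psi and mean
e^{mu + X beta}; psi controls the overdispersion (variance m + m^2/psi).
Parameters are estimated by gradient ascent with a backtracking
(Armijo) line search, with psi optimized on the log scale to keep it
positive.  The group coefficient beta_0 is tested with a Wald statistic
whose standard error comes from the observed Fisher information
(negative Hessian of the marginal log likelihood at the MLE, obtained by
central finite differences of the analytic gradient).

All fitting routines are vectorized over bins: every bin shares the same
design matrix, and parameter vectors are stacked row-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_ETA_MAX = 500.0  # overflow guard on the linear predictor


@dataclass
class OptimizerConfig:
    """Gradient-ascent settings (Armijo backtracking line search)."""

    tol: float = 1e-8          # convergence on |delta logL|
    max_iter: int = 1000
    armijo_c: float = 1e-4
    shrink: float = 0.5
    init_step: float = 1.0
    max_backtracks: int = 60


def _validate_counts(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if (Y < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(Y, np.round(Y)):
        raise ValueError("counts must be integers (Poisson likelihood)")
    return Y


def marginal_loglik(
    Y: np.ndarray, X: np.ndarray, mu: float, beta: np.ndarray, psi: float
) -> float:
    """Marginal log likelihood of one bin's counts.

    Parameters
    ----------
    Y : array of shape (n,)
        Non-negative integer counts.
    X : array of shape (n, p)
        Design matrix (group indicator first, covariates after); the
        intercept mu is handled separately.
    mu, beta, psi : parameters; ``psi`` must be positive.
    """
    Y = _validate_counts(Y)
    if psi <= 0:
        raise ValueError(f"psi must be positive, got {psi}")
    eta = mu + np.asarray(X, float) @ np.atleast_1d(np.asarray(beta, float))
    return float(_loglik_eta(Y, eta, float(psi)))


def _loglik_eta(Y: np.ndarray, eta: np.ndarray, psi) -> np.ndarray:
    """Log likelihood given linear predictors; broadcasts over leading axes."""
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    lam = np.exp(eta)
    psi = np.asarray(psi, float)
    p = psi[..., None] if psi.ndim else psi
    terms = (
        Y * eta
        + p * np.log(p)
        + special.gammaln(Y + p)
        - special.gammaln(Y + 1.0)
        - special.gammaln(p)
        - (Y + p) * np.log(lam + p)
    )
    return terms.sum(axis=-1)


def loglik_gradient(
    Y: np.ndarray, X: np.ndarray, mu: float, beta: np.ndarray, psi: float
) -> np.ndarray:
    """Analytic gradient of the marginal log likelihood over (mu, beta, psi).

    d/d beta_k = sum_i [Y_i - (Y_i + psi) lam_i / (lam_i + psi)] X_ik
    d/d mu     = the same sum without the X weight
    d/d psi    = sum_i [log psi + 1 - (Y_i + psi)/(lam_i + psi)
                        - log(lam_i + psi)
                        + digamma(Y_i + psi) - digamma(psi)]
    """
    Y = _validate_counts(Y)
    if psi <= 0:
        raise ValueError(f"psi must be positive, got {psi}")
    X = np.asarray(X, float)
    beta = np.atleast_1d(np.asarray(beta, float))
    eta = np.clip(mu + X @ beta, -_ETA_MAX, _ETA_MAX)
    lam = np.exp(eta)
    common = Y - (Y + psi) * lam / (lam + psi)
    g_mu = common.sum()
    g_beta = common @ X
    g_psi = (
        np.log(psi) + 1.0
        - (Y + psi) / (lam + psi)
        - np.log(lam + psi)
        + special.digamma(Y + psi)
        - special.digamma(psi)
    ).sum()
    return np.concatenate([[g_mu], g_beta, [g_psi]])


def _moment_psi(Y: np.ndarray) -> np.ndarray:
    """Method-of-moments start for psi, clipped to [0.1, 1e4]."""
    m = Y.mean(axis=-1)
    v = Y.var(axis=-1)
    psi0 = m**2 / np.maximum(v - m, 1e-8)
    return np.clip(psi0, 0.1, 1e4)


def fit_bins(
    Y: np.ndarray,
    X: np.ndarray,
    config: OptimizerConfig | None = None,
) -> dict[str, np.ndarray]:
    """Maximize the marginal likelihood for many bins sharing one design.

    Parameters
    ----------
    Y : array of shape (n_bins, n_samples)
        Integer counts per bin.
    X : array of shape (n_samples, p)
        Shared design matrix (no intercept column).

    Returns
    -------
    dict with arrays ``mu`` (B,), ``beta`` (B, p), ``psi`` (B,),
    ``loglik`` (B,), ``n_iter`` (B,), ``converged`` (B,) bool.

    Notes
    -----
    Plain gradient ascent: theta <- theta + s * grad with the step size s
    chosen per bin by backtracking until the Armijo sufficient-increase
    condition holds, so no accepted step ever decreases the objective.
    psi is carried as log psi (chain rule multiplies its gradient
    component by psi), which enforces positivity without projection.
    """
    cfg = config or OptimizerConfig()
    Y = _validate_counts(np.atleast_2d(Y))
    X = np.asarray(X, float)
    B, n = Y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError(f"design has {X.shape[0]} rows for {n} samples")

    mu = np.log(Y.mean(axis=1) + 0.5)
    beta = np.zeros((B, p))
    logpsi = np.log(_moment_psi(Y))

    def loglik(mu_, beta_, logpsi_, active):
        eta = mu_[:, None] + beta_ @ X.T
        return _loglik_eta(Y[active], eta, np.exp(logpsi_))

    act = np.arange(B)
    ll = loglik(mu, beta, logpsi, act)
    n_iter = np.zeros(B, dtype=np.int64)
    converged = np.zeros(B, dtype=bool)
    step = np.full(B, cfg.init_step)

    for it in range(cfg.max_iter):
        act = np.nonzero(~converged)[0]
        if act.size == 0:
            break
        mu_a, beta_a, lp_a = mu[act], beta[act], logpsi[act]
        psi_a = np.exp(lp_a)
        eta = np.clip(mu_a[:, None] + beta_a @ X.T, -_ETA_MAX, _ETA_MAX)
        lam = np.exp(eta)
        Ya = Y[act]
        common = Ya - (Ya + psi_a[:, None]) * lam / (lam + psi_a[:, None])
        g_mu = common.sum(axis=1)
        g_beta = common @ X
        g_psi = (
            np.log(psi_a)[:, None] + 1.0
            - (Ya + psi_a[:, None]) / (lam + psi_a[:, None])
            - np.log(lam + psi_a[:, None])
            + special.digamma(Ya + psi_a[:, None])
            - special.digamma(psi_a)[:, None]
        ).sum(axis=1)
        g_lp = g_psi * psi_a  # chain rule for log psi
        gnorm2 = g_mu**2 + (g_beta**2).sum(axis=1) + g_lp**2

        # backtracking line search per active bin
        s = np.minimum(step[act] * 2.0, cfg.init_step)
        ll_a = ll[act]
        accepted = np.zeros(act.size, dtype=bool)
        new_mu, new_beta, new_lp = mu_a.copy(), beta_a.copy(), lp_a.copy()
        new_ll = ll_a.copy()
        for _ in range(cfg.max_backtracks):
            trial = np.nonzero(~accepted)[0]
            if trial.size == 0:
                break
            t_mu = mu_a[trial] + s[trial] * g_mu[trial]
            t_beta = beta_a[trial] + s[trial, None] * g_beta[trial]
            t_lp = np.clip(lp_a[trial] + s[trial] * g_lp[trial], -20.0, 25.0)
            with np.errstate(over="ignore", invalid="ignore"):
                eta_t = t_mu[:, None] + t_beta @ X.T
                ll_t = _loglik_eta(Y[act[trial]], eta_t, np.exp(t_lp))
            ok = np.isfinite(ll_t) & (
                ll_t >= ll_a[trial] + cfg.armijo_c * s[trial] * gnorm2[trial]
            )
            idx_ok = trial[ok]
            new_mu[idx_ok] = t_mu[ok]
            new_beta[idx_ok] = t_beta[ok]
            new_lp[idx_ok] = t_lp[ok]
            new_ll[idx_ok] = ll_t[ok]
            accepted[idx_ok] = True
            s[trial[~ok]] *= cfg.shrink

        delta = new_ll - ll_a
        mu[act], beta[act], logpsi[act] = new_mu, new_beta, new_lp
        ll[act] = new_ll
        step[act] = s
        n_iter[act] = it + 1
        converged[act[accepted & (np.abs(delta) < cfg.tol)]] = True
        # bins where no step passes Armijo are stationary to machine precision
        converged[act[~accepted]] = True

    return {
        "mu": mu,
        "beta": beta,
        "psi": np.exp(logpsi),
        "loglik": ll,
        "n_iter": n_iter,
        "converged": converged,
    }


def observed_information(
    Y: np.ndarray, X: np.ndarray, mu: np.ndarray, beta: np.ndarray, psi: np.ndarray
) -> np.ndarray:
    """Observed Fisher information (B, P, P) on the (mu, beta, psi) scale.

    Central finite differences of the analytic gradient with step
    1e-5 * (1 + |theta_j|), symmetrized.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    X = np.asarray(X, float)
    mu = np.atleast_1d(mu)
    beta = np.atleast_2d(beta)
    psi = np.atleast_1d(psi)
    B, p = beta.shape
    P = p + 2
    theta = np.column_stack([mu, beta, psi])

    def grad_at(th):
        m, b, ps = th[:, 0], th[:, 1 : 1 + p], np.maximum(th[:, -1], 1e-10)
        eta = np.clip(m[:, None] + b @ X.T, -_ETA_MAX, _ETA_MAX)
        lam = np.exp(eta)
        common = Y - (Y + ps[:, None]) * lam / (lam + ps[:, None])
        g = np.empty((B, P))
        g[:, 0] = common.sum(axis=1)
        g[:, 1 : 1 + p] = common @ X
        g[:, -1] = (
            np.log(ps)[:, None] + 1.0
            - (Y + ps[:, None]) / (lam + ps[:, None])
            - np.log(lam + ps[:, None])
            + special.digamma(Y + ps[:, None])
            - special.digamma(ps)[:, None]
        ).sum(axis=1)
        return g

    H = np.empty((B, P, P))
    for j in range(P):
        h = 1e-5 * (1.0 + np.abs(theta[:, j]))
        tp, tm = theta.copy(), theta.copy()
        tp[:, j] += h
        tm[:, j] -= h
        H[:, :, j] = (grad_at(tp) - grad_at(tm)) / (2.0 * h)[:, None]
    H = 0.5 * (H + np.swapaxes(H, 1, 2))
    return -H


def wald_test(
    Y: np.ndarray,
    X: np.ndarray,
    mu: np.ndarray,
    beta: np.ndarray,
    psi: np.ndarray,
    coef_index: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Wald z and two-sided p for one coefficient, vectorized over bins.

    The standard error is sqrt of the corresponding diagonal element of
    the inverse observed information.  Singular information matrices give
    se = inf, z = 0, p = 1 and are flagged.

    Returns (z, p, se, ok_flag).
    """
    info = observed_information(Y, X, mu, beta, psi)
    B = info.shape[0]
    se = np.full(B, np.inf)
    ok = np.zeros(B, dtype=bool)
    j = 1 + coef_index  # position in (mu, beta..., psi)
    for b in range(B):
        try:
            cov = np.linalg.inv(info[b])
        except np.linalg.LinAlgError:
            continue
        v = cov[j, j]
        if np.isfinite(v) and v > 0:
            se[b] = np.sqrt(v)
            ok[b] = True
    beta0 = np.atleast_2d(beta)[:, coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ok, beta0 / se, 0.0)
    pvals = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return z, pvals, se, ok


class PoissonGammaRegression(BaseEstimator):
    """Count regression with a multiplicative gamma random effect.

    scikit-learn-style estimator for a single response vector: ``fit(X, y)``
    maximizes the marginal (negative binomial, shape ``dispersion_``)
    likelihood of integer counts ``y`` given design ``X`` (no intercept
    column; the intercept is estimated separately as ``intercept_``).

    Parameters
    ----------
    tol : float, default 1e-8
        Convergence tolerance on the log-likelihood increase.
    max_iter : int, default 1000
        Maximum gradient-ascent iterations.

    Attributes
    ----------
    intercept_ : float
        Estimated baseline log mean (mu).
    coef_ : ndarray of shape (p,)
        Estimated regression coefficients (beta).
    dispersion_ : float
        Estimated random-effect scale psi (NB shape).
    se_ : ndarray of shape (p,)
        Wald standard errors of ``coef_``.
    loglik_ : float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 1000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, p) aligned with y")
        if y.shape[0] < 4:
            raise ValueError("need at least 4 observations")
        cfg = OptimizerConfig(tol=self.tol, max_iter=self.max_iter)
        res = fit_bins(y[None, :], X, cfg)
        self.intercept_ = float(res["mu"][0])
        self.coef_ = res["beta"][0]
        self.dispersion_ = float(res["psi"][0])
        self.loglik_ = float(res["loglik"][0])
        self.n_iter_ = int(res["n_iter"][0])
        self.converged_ = bool(res["converged"][0])
        se = np.empty(X.shape[1])
        for k in range(X.shape[1]):
            _, _, se_k, _ = wald_test(
                y[None, :], X, res["mu"], res["beta"], res["psi"], coef_index=k
            )
            se[k] = se_k[0]
        self.se_ = se
        return self

    def predict(self, X):
        """Expected counts e^{mu + X beta} (random effect has mean 1)."""
        X = np.asarray(X, float)
        return np.exp(self.intercept_ + X @ self.coef_)

    def score(self, X, y):
        """Marginal log likelihood of ``y`` under the fitted parameters."""
        return marginal_loglik(y, X, self.intercept_, self.coef_, self.dispersion_)
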