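"""Bayesian test for heteroskedasticity (BTH).

The trait is modelled as

    y_i ~ Normal(beta0 + beta * x_i,  sigma2 * alpha^(-x_i)),

with priors beta ~ Normal(0, 1/gamma), sigma2 ~ InvGamma(theta1, theta2),
log(alpha) ~ Cauchy(x0, nu) and a flat (improper) prior on beta0.  The
Bayes factor compares the alternative (alpha free, i.e. the trait
variance is a monotone function of the covariate) against the point null
alpha = 1:

    BF(y, x) = Pr(y | x, alpha != 1) / Pr(y | x, alpha = 1),

reported on the log10 scale.  The mean effect beta is integrated out in
closed form by Gaussian conjugacy; the remaining parameters
(beta0, log sigma2 and, under the alternative, log alpha) are integrated
by a joint-mode multivariate Laplace approximation.

Because the flat beta0 prior is shared by numerator and denominator its
(undefined) normalizing constant cancels in the BF; the individual
``log_marginal`` values are therefore only meaningful as differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .exceptions import InvalidArgumentError, NumericalError

__all__ = [
    "BthHyperparams",
    "LaplaceFit",
    "BfResult",
    "log_marginal_beta_integrated",
    "laplace_log_marginal",
    "bth_bayes_factor",
]

#: Gradient max-norm below which a Laplace fit is declared converged.
GRAD_TOL = 1e-5

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class BthHyperparams:
    """Prior hyperparameters of the BTH model.

    cauchy_location / cauchy_scale
        Location (x0 = 0) and scale (nu = 5) of the Cauchy prior on
        log(alpha).
    invgamma_shape / invgamma_scale
        theta1 = 1 and theta2 = 2 of the inverse-gamma prior on sigma2.
    beta_prior_precision
        Precision gamma = 1 of the zero-mean Gaussian prior on the mean
        effect beta.
    """

    cauchy_location: float = 0.0
    cauchy_scale: float = 5.0
    invgamma_shape: float = 1.0
    invgamma_scale: float = 2.0
    beta_prior_precision: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cauchy_scale", "invgamma_shape", "invgamma_scale",
                     "beta_prior_precision"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")


@dataclass
class LaplaceFit:
    """Mode, curvature and Laplace evidence of one model fit.

    ``mode`` is (beta0_hat, log_sigma2_hat) under the null and
    (beta0_hat, log_sigma2_hat, log_alpha_hat) under the alternative.
    """

    mode: np.ndarray
    log_det_hessian: float
    log_marginal: float
    converged: bool
    iterations: int
    grad_max_norm: float = math.nan


@dataclass
class BfResult:
    """log10 Bayes factor with the two underlying Laplace fits."""

    log10_bf: float
    fit_alt: LaplaceFit
    fit_null: LaplaceFit
    n: int

    @property
    def beta0_hat(self) -> float:
        return float(self.fit_alt.mode[0])

    @property
    def sigma2_hat(self) -> float:
        return float(np.exp(self.fit_alt.mode[1]))

    @property
    def log_alpha_hat(self) -> float:
        return float(self.fit_alt.mode[2])

    @property
    def converged(self) -> bool:
        return self.fit_alt.converged and self.fit_null.converged


def _validate_pair(y, x) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or x.ndim != 1 or y.size != x.size:
        raise InvalidArgumentError("y and x must be 1-D vectors of equal length")
    if y.size < 4:
        raise InvalidArgumentError("need at least 4 samples")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise InvalidArgumentError("y and x must be finite")
    return y, x


def log_marginal_beta_integrated(
    y, x, beta0: float, sigma2: float, log_alpha: float,
    hyper: BthHyperparams = BthHyperparams(),
) -> float:
    """Log marginal likelihood with the mean effect beta integrated out.

    With observation precisions w_i = alpha^{x_i} / sigma2 and
    residuals r_i = y_i - beta0, Gaussian conjugacy gives

        log p(y | beta0, sigma2, alpha)
          = -n/2 log(2 pi) + 1/2 sum log w_i + 1/2 log gamma
            - 1/2 log A - 1/2 sum w_i r_i^2 + b^2 / (2 A),

    where A = gamma + sum w_i x_i^2 and b = sum w_i x_i r_i.
    """
    y, x = _validate_pair(y, x)
    if sigma2 <= 0:
        raise InvalidArgumentError("sigma2 must be > 0")
    return _log_marginal_core(
        y, x, beta0, math.log(sigma2), log_alpha,
        hyper.beta_prior_precision,
    )


def _log_marginal_core(y, x, beta0, log_sigma2, log_alpha, gamma_prec):
    n = y.size
    logw = log_alpha * x - log_sigma2
    w = np.exp(logw)
    r = y - beta0
    wr = w * r
    S = float(np.dot(w * x, x))
    A = gamma_prec + S
    b = float(np.dot(wr, x))
    Q = float(np.dot(wr, r))
    return (
        -0.5 * n * _LOG_2PI
        + 0.5 * float(np.sum(logw))
        + 0.5 * math.log(gamma_prec)
        - 0.5 * math.log(A)
        - 0.5 * Q
        + b * b / (2.0 * A)
    )


def _objective_and_grad(theta, y, x, hyper, alpha_free):
    """Log posterior kernel g(theta) and its gradient.

    theta = (beta0, log sigma2[, log alpha]).  g is the beta-integrated
    log likelihood plus the log priors on sigma2 (with the Jacobian of
    sigma2 -> log sigma2) and, when alpha is free, on log alpha.  The
    flat beta0 prior contributes nothing.
    """
    beta0, ls = theta[0], theta[1]
    la = theta[2] if alpha_free else 0.0
    n = y.size
    gamma_prec = hyper.beta_prior_precision
    th1, th2 = hyper.invgamma_shape, hyper.invgamma_scale
    nu, x0 = hyper.cauchy_scale, hyper.cauchy_location

    logw = la * x - ls
    w = np.exp(logw)
    r = y - beta0
    wr = w * r
    wx = w * x
    S = float(np.dot(wx, x))
    A = gamma_prec + S
    b = float(np.dot(wr, x))
    Q = float(np.dot(wr, r))

    g = (
        -0.5 * n * _LOG_2PI
        + 0.5 * float(np.sum(logw))
        + 0.5 * math.log(gamma_prec)
        - 0.5 * math.log(A)
        - 0.5 * Q
        + b * b / (2.0 * A)
    )
    # InvGamma(sigma2; th1, th2) density plus log-Jacobian sigma2 -> log sigma2:
    # th1*log th2 - lgamma(th1) - (th1+1)*ls - th2*exp(-ls) + ls
    g += th1 * math.log(th2) - special.gammaln(th1) - th1 * ls \
        - th2 * math.exp(-ls)

    d_beta0 = float(np.sum(wr)) - (b / A) * float(np.sum(wx))
    d_ls = (
        -0.5 * n + S / (2.0 * A) + 0.5 * Q
        - b * b / A + b * b * S / (2.0 * A * A)
        - th1 + th2 * math.exp(-ls)
    )
    if not alpha_free:
        return g, np.array([d_beta0, d_ls])

    u = (la - x0) / nu
    g += -math.log(math.pi * nu) - math.log1p(u * u)
    S3 = float(np.dot(wx * x, x))        # sum w x^3
    T = float(np.dot(wx, r * r))         # sum w x r^2
    U = float(np.dot(wx * x, r))         # sum w x^2 r
    d_la = (
        0.5 * float(np.sum(x))
        - S3 / (2.0 * A)
        - 0.5 * T
        + (b / A) * U
        - b * b * S3 / (2.0 * A * A)
        - (2.0 * u / nu) / (1.0 + u * u)
    )
    return g, np.array([d_beta0, d_ls, d_la])


def _fd_hessian(theta, y, x, hyper, alpha_free):
    """Hessian of g by central finite differences of the analytic gradient,
    step 1e-4 * max(1, |theta_j|)."""
    d = theta.size
    H = np.empty((d, d))
    for j in range(d):
        h = 1e-4 * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _objective_and_grad(tp, y, x, hyper, alpha_free)
        _, gm = _objective_and_grad(tm, y, x, hyper, alpha_free)
        H[j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


# fixed perturbations applied to the OLS-based start on restart
_RESTART_OFFSETS = (
    np.array([0.0, 0.5, 0.5]),
    np.array([0.0, -0.5, -0.5]),
    np.array([0.5, 1.0, 0.0]),
)


def laplace_log_marginal(
    y, x, hyper: BthHyperparams = BthHyperparams(), alpha_free: bool = True,
) -> LaplaceFit:
    """Laplace approximation of the model evidence (up to the shared flat
    beta0 prior constant).

    Maximizes g(beta0, log sigma2[, log alpha]) with a quasi-Newton
    optimizer started at the OLS intercept, the log OLS residual
    variance and log alpha = 0, with up to three deterministic restarts
    from perturbed starts, and returns

        log_marginal = g(mode) + d/2 log(2 pi) - 1/2 log det(-H(mode)).
    """
    y, x = _validate_pair(y, x)
    if np.ptp(x) == 0:
        raise InvalidArgumentError("covariate has zero variance")

    # OLS start
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rv = float(np.dot(resid, resid)) / max(y.size - 2, 1)
    rv = max(rv, 1e-12)
    d = 3 if alpha_free else 2
    start = np.array([coef[0], math.log(rv), 0.0])[:d]

    def negg(theta):
        g, grad = _objective_and_grad(theta, y, x, hyper, alpha_free)
        if not np.isfinite(g):
            raise NumericalError("non-finite objective in Laplace fit")
        return -g, -grad

    best = None
    iters = 0
    for attempt in range(1 + len(_RESTART_OFFSETS)):
        x0 = start if attempt == 0 else start + _RESTART_OFFSETS[attempt - 1][:d]
        res = optimize.minimize(
            negg, x0, jac=True, method="BFGS",
            options={"gtol": 1e-8, "maxiter": 200},
        )
        iters += res.nit
        gmax = float(np.max(np.abs(res.jac)))
        if best is None or res.fun < best[0].fun - 1e-12:
            best = (res, gmax)
        if gmax <= GRAD_TOL:
            best = min([best, (res, gmax)], key=lambda t: t[0].fun)
            break
    res, gmax = best
    mode = res.x
    H = _fd_hessian(mode, y, x, hyper, alpha_free)  # Hessian of g (concave: H < 0)
    sign, logdet = np.linalg.slogdet(-H)
    converged = bool(gmax <= GRAD_TOL and sign > 0)
    if sign <= 0:
        # saddle or flat curvature: fall back to eigenvalue clipping so a
        # finite (if unreliable) evidence is still reported
        eig = np.linalg.eigvalsh(-H)
        logdet = float(np.sum(np.log(np.maximum(eig, 1e-10))))
    g_mode, _ = _objective_and_grad(mode, y, x, hyper, alpha_free)
    log_marginal = g_mode + 0.5 * d * _LOG_2PI - 0.5 * logdet
    return LaplaceFit(
        mode=mode,
        log_det_hessian=float(logdet),
        log_marginal=float(log_marginal),
        converged=converged,
        iterations=int(iters),
        grad_max_norm=gmax,
    )


def bth_bayes_factor(
    y, x, hyper: BthHyperparams = BthHyperparams(),
) -> BfResult:
    """log10 Bayes factor of the heteroskedastic alternative against the
    homoskedastic point null (alpha = 1) for one (trait, covariate) pair."""
    y, x = _validate_pair(y, x)
    if np.ptp(x) == 0:
        raise InvalidArgumentError("covariate has zero variance")
    if np.ptp(y) == 0:
        raise InvalidArgumentError("trait has zero variance")
    fit_alt = laplace_log_marginal(y, x, hyper, alpha_free=True)
    fit_null = laplace_log_marginal(y, x, hyper, alpha_free=False)
    log10_bf = (fit_alt.log_marginal - fit_null.log_marginal) / math.log(10.0)
    return BfResult(
        log10_bf=float(log10_bf),
        fit_alt=fit_alt,
        fit_null=fit_null,
        n=y.size,
    )
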