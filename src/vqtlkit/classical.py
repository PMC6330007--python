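"""Classical tests for heteroskedasticity: Levene, Brown-Forsythe,
Bartlett, CLS and the iterative double-GLM (dglm) test.

All tests share one result contract (:class:`TestResult`).  The Levene
family and Bartlett require a categorical covariate; continuous input is
rejected rather than silently rounded (a separate :func:`round_dosage`
utility exists for idealized imputation experiments).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InvalidArgumentError, NumericalError

logger = logging.getLogger(__name__)

METHODS = ("levene", "brown_forsythe", "bartlett", "cls", "dglm", "bth")


@dataclass
class TestResult:
    """Outcome of one (trait, covariate) heteroskedasticity test.

    Exactly one of ``p_value`` (frequentist methods) and ``log10_bf``
    (BTH) is set.  ``score`` converts either into a common
    larger-is-more-significant scale.
    """

    method: str
    statistic: float = math.nan
    p_value: float | None = None
    log10_bf: float | None = None
    df: tuple | None = None
    converged: bool = True
    n: int = 0
    extras: dict = field(default_factory=dict)

    __test__ = False  # not a pytest collection target

    @property
    def score(self) -> float:
        """-log10 p for p-value methods, log10 BF for BTH; 0 when the
        test did not converge."""
        if not self.converged:
            return 0.0
        if self.log10_bf is not None:
            return float(self.log10_bf)
        if self.p_value is None:
            return 0.0
        return float(-np.log10(max(self.p_value, 1e-300)))


def _check_pair(y, x, min_n=4):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or x.ndim != 1 or y.size != x.size:
        raise InvalidArgumentError("y and x must be 1-D vectors of equal length")
    if y.size < min_n:
        raise InvalidArgumentError(f"need at least {min_n} samples")
    return y, x


def is_categorical(x, max_levels: int = 10) -> bool:
    """True when x looks like a categorical/genotype covariate: all values
    integral and at most ``max_levels`` distinct levels."""
    x = np.asarray(x, dtype=float)
    if not np.allclose(x, np.round(x), atol=1e-12):
        return False
    return np.unique(x).size <= max_levels

def round_dosage(x) -> np.ndarray:
    """Round continuous dosages to the nearest genotype in {0, 1, 2}.

    Provided only to reproduce idealized imputation simulations; rounding
    real dosage data discards imputation uncertainty and is discouraged.
    """
    return np.clip(np.round(np.asarray(x, dtype=float)), 0, 2)


def _groups(y, x):
    levels = np.unique(x)
    return levels, [y[x == lv] for lv in levels]


def levene_family_test(y, x, center: str = "mean") -> TestResult:
    """Levene (center='mean') or Brown-Forsythe (center='median') test.

    With absolute deviations z_ts = |w_t(s) - center(w_t)| the statistic is

        W = (n - k) sum_t n_t (zbar_t - zbar)^2
            / [ (k - 1) sum_t sum_s (z_ts - zbar_t)^2 ],

    referred to an F(k-1, n-k) distribution.  A zero denominator (all
    deviations equal within every group) yields statistic 0 and p = 1.
    """
    if center not in ("mean", "median"):
        raise InvalidArgumentError("center must be 'mean' or 'median'")
    y, x = _check_pair(y, x)
    if not is_categorical(x):
        raise InvalidArgumentError(
            "Levene-family tests require a categorical covariate; "
            "round_dosage() exists for idealized dosage data"
        )
    levels, groups = _groups(y, x)
    k = len(levels)
    n = y.size
    if k < 2:
        raise InvalidArgumentError("need at least 2 covariate groups")
    if any(g.size < 2 for g in groups):
        raise InvalidArgumentError("every group needs at least 2 samples")
    centerfn = np.mean if center == "mean" else np.median
    z = [np.abs(g - centerfn(g)) for g in groups]
    zbar_t = np.array([zt.mean() for zt in z])
    zbar = float(np.concatenate(z).mean())
    nt = np.array([g.size for g in groups], dtype=float)
    num = float(np.dot(nt, (zbar_t - zbar) ** 2))
    den = float(sum(((zt - zb) ** 2).sum() for zt, zb in zip(z, zbar_t)))
    if den <= 0:
        method = "levene" if center == "mean" else "brown_forsythe"
        return TestResult(method=method, statistic=0.0, p_value=1.0,
                          df=(k - 1, n - k), n=n)
    W = (n - k) * num / ((k - 1) * den)
    p = float(stats.f.sf(W, k - 1, n - k))
    method = "levene" if center == "mean" else "brown_forsythe"
    return TestResult(method=method, statistic=float(W), p_value=p,
                      df=(k - 1, n - k), n=n)


def bartlett_test(y, x) -> TestResult:
    """Bartlett's chi-square test on pooled group variances.

    Sensitive to departures from normality; included as a comparison
    baseline.  A zero-variance group makes the statistic undefined and
    raises :class:`NumericalError`.
    """
    y, x = _check_pair(y, x)
    if not is_categorical(x):
        raise InvalidArgumentError("Bartlett requires a categorical covariate")
    levels, groups = _groups(y, x)
    k = len(levels)
    if k < 2:
        raise InvalidArgumentError("need at least 2 covariate groups")
    if any(g.size < 2 for g in groups):
        raise InvalidArgumentError("every group needs at least 2 samples")
    if any(np.var(g, ddof=1) == 0 for g in groups):
        raise NumericalError("a group has zero variance; Bartlett undefined")
    stat, p = stats.bartlett(*groups)
    return TestResult(method="bartlett", statistic=float(stat),
                      p_value=float(p), df=(k - 1,), n=y.size)


def _spearman_exact_p(a_ranks, b_ranks, rho_obs):
    """Exact two-sided permutation p-value of Spearman's rho (tiny n)."""
    n = a_ranks.size
    denom = np.sqrt(np.var(a_ranks) * np.var(b_ranks))
    if denom == 0:
        return 1.0
    count = 0
    total = 0
    a_c = a_ranks - a_ranks.mean()
    b_c = b_ranks - b_ranks.mean()
    for perm in itertools.permutations(range(n)):
        rho = float(np.dot(a_c[list(perm)], b_c)) / (n * denom)
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def cls_test(y, x) -> TestResult:
    """Correlation least squares (CLS) test.

    Fits y = beta0 + beta*x by least squares and Spearman-correlates the
    squared residuals with x (average ranks for ties).  The p-value uses
    the t approximation on n - 2 degrees of freedom; for n < 10 an exact
    permutation p-value is used instead.  Fully tied squared residuals
    (including a perfect mean fit) give statistic 0, p = 1.
    """
    y, x = _check_pair(y, x)
    if np.ptp(x) == 0:
        raise InvalidArgumentError("covariate has zero variance")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r2 = (y - X @ coef) ** 2
    if np.ptp(r2) < 1e-300 or np.unique(r2).size == 1:
        return TestResult(method="cls", statistic=0.0, p_value=1.0, n=y.size)
    n = y.size
    rho, p = stats.spearmanr(r2, x)
    if not np.isfinite(rho):
        return TestResult(method="cls", statistic=0.0, p_value=1.0, n=n)
    if n < 10:
        p = _spearman_exact_p(stats.rankdata(r2), stats.rankdata(x), rho)
    return TestResult(method="cls", statistic=float(rho), p_value=float(p),
                      df=(n - 2,), n=n)


def _gaussian_loglik(y, mu, phi):
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * phi) + (y - mu) ** 2 / phi))


def _gamma_irls_log_link(d, X, start, max_iter=50, tol=1e-10):
    """IRLS for a gamma GLM with log link and constant prior weights.

    With log link and gamma variance V(mu) = mu^2 the IRLS weights are
    proportional to the (constant) prior weights, so each step reduces
    to an ordinary least-squares solve of the working response
    z = eta + (d - mu)/mu.  Returns the coefficient vector; raises
    ``NumericalError`` on divergence.
    """
    lam = start.copy()
    for _ in range(max_iter):
        eta = X @ lam
        eta = np.clip(eta, -300, 300)
        mu = np.exp(eta)
        z = eta + (d - mu) / mu
        new, *_ = np.linalg.lstsq(X, z, rcond=None)
        if not np.all(np.isfinite(new)):
            raise NumericalError("gamma IRLS diverged")
        step = float(np.max(np.abs(new - lam)))
        lam = new
        if step < tol:
            return lam
    return lam


def dglm_test(y, x, max_iter: int = 50, tol: float = 1e-8) -> TestResult:
    """Double generalized linear model test for a dispersion effect.

    Alternates (a) weighted least squares for the mean y ~ 1 + x with
    weights equal to the reciprocal fitted dispersions, and (b) a gamma
    GLM with log link for the dispersion, response = squared mean-model
    residuals d_i, linear predictor lambda0 + lambda1 * x, prior weights
    1/2 (d_i ~ phi_i * chi2_1; constant prior weights drop out of the
    log-link IRLS, which is run directly).  Iteration stops when the
    change in the Gaussian log-likelihood of the fitted mean/dispersion
    model is below ``tol``.  The statistic is the 1-df likelihood-ratio
    chi-square against the constant-dispersion submodel.
    """
    y, x = _check_pair(y, x, min_n=6)
    if np.ptp(x) == 0:
        raise InvalidArgumentError("covariate has zero variance")
    n = y.size
    X = np.column_stack([np.ones_like(x), x])
    eps_floor = np.finfo(float).eps * max(1.0, float(np.var(y)))

    # null model: OLS mean, constant dispersion (closed form)
    coef0, *_ = np.linalg.lstsq(X, y, rcond=None)
    d0 = (y - X @ coef0) ** 2
    phi0 = max(float(d0.mean()), eps_floor)
    ll_null = _gaussian_loglik(y, X @ coef0, np.full(n, phi0))

    # full model: alternate WLS mean and gamma dispersion GLM
    phi = np.full(n, phi0)
    lam = np.array([math.log(phi0), 0.0])
    ll_prev = -np.inf
    converged = False
    try:
        for _ in range(max_iter):
            w = 1.0 / phi
            WX = X * w[:, None]
            coef = np.linalg.solve(X.T @ WX, WX.T @ y)
            d = (y - X @ coef) ** 2
            if np.any(d < eps_floor):
                logger.debug("dglm: flooring %d zero squared residuals",
                             int(np.sum(d < eps_floor)))
                d = np.maximum(d, eps_floor)
            lam = _gamma_irls_log_link(d, X, lam)
            phi = np.maximum(np.exp(np.clip(X @ lam, -300, 300)), eps_floor)
            ll = _gaussian_loglik(y, X @ coef, phi)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
    except (NumericalError, np.linalg.LinAlgError) as exc:
        logger.debug("dglm failed to converge: %s", exc)
        return TestResult(method="dglm", statistic=math.nan, p_value=None,
                          converged=False, n=n)
    if not converged:
        return TestResult(method="dglm", statistic=math.nan, p_value=None,
                          converged=False, n=n)
    stat = max(2.0 * (ll - ll_null), 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(method="dglm", statistic=float(stat), p_value=p,
                      df=(1,), n=n, extras={"lambda": lam})


def run_test(method: str, y, x, hyper=None, **options) -> TestResult:
    """Uniform dispatcher over all six tests.

    Levene/Brown-Forsythe/Bartlett refuse continuous covariates; BTH is
    delegated to :mod:`vqtlkit.bth`.
    """
    if method not in METHODS:
        raise InvalidArgumentError(f"unknown method {method!r}")
    if method == "levene":
        return levene_family_test(y, x, center="mean")
    if method == "brown_forsythe":
        return levene_family_test(y, x, center="median")
    if method == "bartlett":
        return bartlett_test(y, x)
    if method == "cls":
        return cls_test(y, x)
    if method == "dglm":
        return dglm_test(y, x, **options)
    from .bth import BthHyperparams, bth_bayes_factor

    res = bth_bayes_factor(y, x, hyper or BthHyperparams())
    return TestResult(
        method="bth",
        statistic=res.log10_bf,
        log10_bf=res.log10_bf,
        converged=res.converged,
        n=res.n,
        extras={
            "beta0_hat": res.beta0_hat,
            "sigma2_hat": res.sigma2_hat,
            "log_alpha_hat": res.log_alpha_hat,
        },
    )
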