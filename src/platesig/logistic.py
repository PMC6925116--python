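"""Maximum-likelihood logistic regression by IRLS, with the small-sample
diagnostics the screening stage needs.

With 19 matched pairs and thousands of candidate genes, (quasi-)separation
is an everyday event rather than an edge case, so the fitter never raises
on it: it stops at a finite-precision estimate, flags the fit, and leaves
interval construction to the profile likelihood, whose bounds may be
infinite.  Convergence is declared on a relative log-likelihood change
below ``tol`` (default 1e-8) within ``max_iter`` (default 100) Newton
steps; separation is declared when a coefficient magnitude exceeds
``separation_bound`` (default 20, on the log-odds-per-log2-unit scale)
while the likelihood is still improving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

MAX_ITER = 100
TOL = 1e-8
SEPARATION_BOUND = 20.0


@dataclass
class LogisticFit:
    """Result of one ML logistic fit on a design matrix with intercept."""

    beta: np.ndarray          # coefficients, intercept first
    cov: np.ndarray           # inverse observed information at beta
    loglik: float
    loglik_null: float
    converged: bool
    separated: bool
    singular: bool            # information matrix required a pseudo-inverse
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov))


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), stable via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    separation_bound: float = SEPARATION_BOUND,
) -> LogisticFit:
    """Fit ``logit P(y=1) = X beta`` by iteratively reweighted least squares.

    ``X`` must already contain the intercept column.  ``y`` is coded 0/1
    with both classes present.  Never raises on separation or collinearity;
    see module docstring for the stopping rules.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have incompatible lengths")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
        raise ValueError("y must contain both classes coded 0/1")

    beta = np.zeros(p)
    ll = _loglik(X @ beta, y)
    ybar = y.mean()
    ll_null = float(n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))
    converged = separated = singular = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            singular = True
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving keeps the likelihood monotone
        new_beta, new_ll = beta + step, -np.inf
        for _ in range(30):
            new_ll = _loglik(X @ new_beta, y)
            if new_ll >= ll - 1e-13:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        improving = new_ll > ll
        rel_change = abs(new_ll - ll) / (0.1 + abs(new_ll))
        beta, ll = new_beta, new_ll
        if np.max(np.abs(beta[1:] if p > 1 else beta)) > separation_bound and improving:
            separated = True
            break
        if rel_change < tol:
            converged = True
            break

    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        singular = True
        cov = np.linalg.pinv(info)
    return LogisticFit(
        beta=beta, cov=cov, loglik=ll, loglik_null=ll_null,
        converged=bool(converged), separated=bool(separated),
        singular=bool(singular), n_iter=it,
    )


def wald_pvalues(fit: LogisticFit) -> np.ndarray:
    """Two-sided Wald p-values for every coefficient."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.beta / fit.se
    return 2.0 * norm.sf(np.abs(z))


def lr_pvalue_slope(x: np.ndarray, y: np.ndarray, fit: LogisticFit) -> float:
    """Likelihood-ratio p-value for the slope of an intercept+slope fit."""
    lr = 2.0 * (fit.loglik - fit.loglik_null)
    return float(chi2.sf(max(lr, 0.0), df=1))


def _profile_loglik(b: float, x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood maximized over the intercept at fixed slope ``b``."""
    offset = b * x
    ybar = float(y.mean())
    # start where the mean linear predictor matches the observed case rate;
    # starting at 0 can underflow every IRLS weight when b * mean(x) is large
    a = float(np.log(ybar / (1.0 - ybar)) - offset.mean())
    ll = _loglik(a + offset, y)
    for _ in range(200):
        eta = a + offset
        mu = expit(eta)
        w = float((mu * (1.0 - mu)).sum())
        g = float((y - mu).sum())
        if w < 1e-300:
            break
        step = float(np.clip(g / w, -10.0, 10.0))
        new_a, new_ll = a + step, -np.inf
        for _ in range(30):
            new_ll = _loglik(new_a + offset, y)
            if new_ll >= ll - 1e-13:
                break
            new_a = a + (new_a - a) / 2.0
        if abs(new_ll - ll) / (0.1 + abs(new_ll)) < 1e-12:
            a, ll = new_a, new_ll
            break
        a, ll = new_a, new_ll
    return ll


def profile_ci_slope(
    x: np.ndarray,
    y: np.ndarray,
    beta_hat: float,
    loglik_hat: float,
    level: float = 0.95,
    search_limit: float = 500.0,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a univariate slope.

    Inverts the likelihood-ratio test: the interval is every ``b`` with
    ``2*(llmax - profile_ll(b)) <= chi2_{1,level}``.  Under separation the
    profile likelihood has a finite asymptote, so a bound can be infinite;
    the search stops at ``±search_limit`` on the log-odds scale and reports
    ``inf`` beyond it.
    """
    from scipy.optimize import brentq

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cut = chi2.ppf(level, df=1) / 2.0
    target = loglik_hat - cut

    def f(b: float) -> float:
        return _profile_loglik(b, x, y) - target

    bounds = []
    for direction in (-1.0, 1.0):
        step = 0.5
        b = beta_hat
        found = None
        while abs(b - beta_hat) < search_limit:
            b_next = b + direction * step
            if f(b_next) < 0.0:
                found = brentq(f, min(b, b_next), max(b, b_next), xtol=1e-10)
                break
            b = b_next
            step *= 2.0
        bounds.append(found if found is not None else direction * np.inf)
    return bounds[0], bounds[1]
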