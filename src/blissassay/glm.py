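"""Binomial GLMs on binary survival outcomes, with the constrained
maximum-likelihood fit the log link requires.

A log-binomial (relative-risk) regression models log survival probability as
a linear function of exposure indicators:

    log(p_surv) = X beta,        p_surv = exp(X beta) <= 1,

so coefficients are log survival-probability ratios and the model is only
well-defined on the half-space where every linear predictor is non-positive.
Standard IRLS/Fisher scoring fails at or near that boundary, so the fit here
is an explicitly constrained concave maximization: SLSQP over the linear
constraints eta <= 0 per distinct covariate pattern, followed by interior
Newton polishing when no constraint is active.

The Bernoulli log-likelihood depends on the data only through per-pattern
survivor counts, so fits aggregate to covariate patterns first; designs with
a handful of groups and trials fit in milliseconds regardless of n.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DesignMatrix",
    "BinomialGlmFit",
    "GlmError",
    "DegenerateGroupError",
    "NonConvergenceError",
    "fit_binomial_glm",
    "bernoulli_log_likelihood",
    "log_likelihood",
    "lr_statistic",
    "chi2_upper_tail",
]

BOUNDARY_TOL = 1e-6
_BETA_DIVERGENCE = 30.0  # |beta| beyond this signals a -inf MLE direction


class GlmError(RuntimeError):
    pass


class DegenerateGroupError(GlmError):
    """A covariate pattern/group with zero survivors makes the log-link MLE
    diverge to -infinity; the test is undefined on such data."""


class NonConvergenceError(GlmError):
    pass


@dataclass(frozen=True)
class DesignMatrix:
    """0/1 design matrix with named columns in a fixed, recorded order."""

    matrix: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != len(self.columns):
            raise ValueError("matrix shape does not match column names")
        if not np.isin(m, (0.0, 1.0)).all():
            raise ValueError("design entries must be 0 or 1")
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise GlmError("design matrix is rank deficient")

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BinomialGlmFit:
    """Result of a binomial GLM fit.

    ``beta`` is ordered as the design columns; for the log link the fitted
    survival probabilities are ``exp(matrix @ beta)`` and every linear
    predictor satisfies eta <= 0 (within tolerance).  ``boundary`` is True
    when some constraint is active at the optimum, where standard chi-square
    asymptotics for likelihood-ratio statistics are approximate.
    """

    link: str
    columns: tuple[str, ...]
    beta: np.ndarray
    loglik: float
    fitted: np.ndarray
    converged: bool
    boundary: bool
    cov: np.ndarray | None = None
    n_obs: int = 0

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])

    def to_dict(self) -> dict:
        return {
            "link": self.link,
            "columns": list(self.columns),
            "beta": [float(b) for b in self.beta],
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "n_obs": int(self.n_obs),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def bernoulli_log_likelihood(p, y) -> float:
    """Sum of y*log(p) + (1-y)*log(1-p), tolerating p in {0,1} where exact."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y == 1, np.log(p), np.log1p(-p))
    if not np.isfinite(terms).all():
        return -np.inf
    return float(terms.sum())


def log_likelihood(fit: BinomialGlmFit, design: DesignMatrix, outcomes) -> float:
    """Bernoulli log-likelihood of ``outcomes`` at the fitted coefficients."""
    y = np.asarray(outcomes, dtype=float)
    eta = design.matrix @ fit.beta
    if fit.link == "log":
        p = np.exp(np.minimum(eta, 0.0))
    else:
        p = 1.0 / (1.0 + np.exp(-eta))
    return bernoulli_log_likelihood(p, y)


def _aggregate(design: DesignMatrix, y: np.ndarray):
    """Collapse rows to distinct covariate patterns with (n, k) counts."""
    pats, inv = np.unique(design.matrix, axis=0, return_inverse=True)
    n = np.bincount(inv, minlength=len(pats)).astype(float)
    k = np.bincount(inv, weights=y, minlength=len(pats)).astype(float)
    return pats, n, k


def _log_nll(beta, P, n, k):
    """Negative aggregated log-likelihood for the log link, with gradient."""
    eta = np.minimum(P @ beta, -1e-12)
    e = np.exp(eta)
    one_m = -np.expm1(eta)  # 1 - exp(eta), accurate near 0
    ll = k @ eta + (n - k) @ np.log(one_m)
    w = k - (n - k) * e / one_m
    return -ll, -(P.T @ w)


def _log_hess(beta, P, n, k):
    eta = np.minimum(P @ beta, -1e-12)
    e = np.exp(eta)
    one_m = -np.expm1(eta)
    d = (n - k) * e / one_m**2
    return P.T @ (P * d[:, None])


def _feasible_start(P, n, k):
    """Least-squares projection of shrunk empirical log-survival rates,
    shifted into the strict interior if needed."""
    p_shrunk = (k + 0.5) / (n + 1.0)
    eta0 = np.log(p_shrunk)
    beta0, *_ = np.linalg.lstsq(P, eta0, rcond=None)
    slack = P @ beta0
    if slack.max() > -1e-8:
        ones = np.isclose(P, 1.0).all(axis=0)
        if ones.any():
            j = int(np.argmax(ones))
            beta0[j] -= slack.max() + 0.1
        else:
            beta0 *= 0.0
            if (P @ beta0).max() > -1e-8:  # all-zero pattern: eta=0 always
                raise GlmError("no strictly feasible starting point found")
    return beta0


def _fit_log(design: DesignMatrix, y: np.ndarray, tol: float, max_iter: int):
    P, n, k = _aggregate(design, y)
    if (k == 0).any() and len(P) == len(design.columns):
        # pattern-saturated design: a zero-survivor pattern owns a coefficient
        # whose MLE is -infinity
        raise DegenerateGroupError(
            "covariate pattern with zero survivors in a saturated design"
        )
    beta0 = _feasible_start(P, n, k)
    res = optimize.minimize(
        _log_nll,
        beta0,
        args=(P, n, k),
        jac=True,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda b: -(P @ b), "jac": lambda b: -P}],
        options={"ftol": 1e-14, "maxiter": max_iter},
    )
    beta = res.x
    converged = bool(res.success)
    if not converged:
        # SLSQP line searches can stall on active constraints; trust-constr
        # is slower but robust at the boundary
        res2 = optimize.minimize(
            _log_nll,
            beta0,
            args=(P, n, k),
            jac=True,
            hess=lambda b, *a: _log_hess(b, P, n, k),
            method="trust-constr",
            constraints=[optimize.LinearConstraint(P, -np.inf, 0.0)],
            options={"gtol": 1e-10, "xtol": 1e-14, "maxiter": 4 * max_iter},
        )
        if res2.status in (1, 2) or _log_nll(res2.x, P, n, k)[0] <= res.fun:
            beta = res2.x
            converged = True

    # interior Newton polish: if no constraint is near-active, a few damped
    # Newton steps push the gradient to machine precision
    for _ in range(60):
        eta = P @ beta
        if eta.max() > -1e-7:
            break
        _, g = _log_nll(beta, P, n, k)
        if np.abs(g).max() < tol * max(1.0, n.sum()):
            converged = True
            break
        H = _log_hess(beta, P, n, k)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        f0, _ = _log_nll(beta, P, n, k)
        for _ in range(40):
            cand = beta - t * step
            if (P @ cand).max() < 0:
                f1, _ = _log_nll(cand, P, n, k)
                if f1 <= f0:
                    beta = cand
                    break
            t *= 0.5
        else:
            break
        converged = True

    if np.abs(beta).max() > _BETA_DIVERGENCE:
        raise DegenerateGroupError(
            "a coefficient diverged; some exposure group has (near-)zero survivors"
        )
    if not converged:
        raise NonConvergenceError(
            f"log-link fit did not converge within {max_iter} iterations: "
            f"{res.message}"
        )
    eta_pat = P @ beta
    boundary = bool(eta_pat.max() > -BOUNDARY_TOL)
    eta_all = np.minimum(design.matrix @ beta, 0.0)
    fitted = np.exp(eta_all)
    ll = bernoulli_log_likelihood(fitted, y)
    cov = None
    if not boundary:
        try:
            cov = np.linalg.inv(_log_hess(beta, P, n, k))
        except np.linalg.LinAlgError:
            cov = None
    return beta, ll, fitted, converged, boundary, cov


def _fit_logit(design: DesignMatrix, y: np.ndarray, tol: float, max_iter: int):
    P, n, k = _aggregate(design, y)
    beta = np.zeros(P.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = P @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = P.T @ (k - n * mu)
        if np.abs(g).max() < tol * max(1.0, n.sum()):
            converged = True
            break
        W = n * mu * (1 - mu)
        H = P.T @ (P * W[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise NonConvergenceError(f"singular Hessian in logit fit: {exc}")
        # damped Newton against overshoot under separation
        norm = np.abs(step).max()
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.abs(beta).max() > _BETA_DIVERGENCE:
            raise DegenerateGroupError(
                "logit coefficients diverged (complete separation)"
            )
    if not converged:
        raise NonConvergenceError(f"logit fit did not converge in {max_iter} steps")
    if np.abs(P @ beta).max() > 15.0:
        # a fitted pattern probability indistinguishable from 0 or 1 means the
        # logit MLE is at infinity (complete/quasi-complete separation)
        raise DegenerateGroupError(
            "logit fit separated: a covariate pattern has (near-)zero deaths "
            "or survivors"
        )
    eta_all = design.matrix @ beta
    fitted = 1.0 / (1.0 + np.exp(-eta_all))
    ll = bernoulli_log_likelihood(fitted, y)
    mu = 1.0 / (1.0 + np.exp(-(P @ beta)))
    H = P.T @ (P * (n * mu * (1 - mu))[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return beta, ll, fitted, converged, False, cov


def fit_binomial_glm(
    design: DesignMatrix,
    outcomes,
    link: str = "log",
    tol: float = 1e-10,
    max_iter: int = 500,
) -> BinomialGlmFit:
    """Maximum-likelihood binomial GLM fit.

    Parameters
    ----------
    design :
        Full-column-rank 0/1 :class:`DesignMatrix`.
    outcomes :
        Binary vector, 1 = survived, 0 = died; must contain both values.
    link :
        ``"log"`` (constrained: every linear predictor <= 0) or ``"logit"``.
    tol, max_iter :
        Convergence tolerance (relative gradient) and iteration cap.

    The fit is deterministic: a fixed feasible initialization and
    deterministic optimizer yield bit-identical coefficients across runs.

    Raises
    ------
    DegenerateGroupError
        Under the log link, when a zero-survivor covariate pattern makes a
        coefficient diverge to -infinity.
    NonConvergenceError
        When the optimizer fails within ``max_iter`` (never silent).
    """
    y = np.asarray(outcomes, dtype=float)
    if y.shape != (design.n_obs,):
        raise ValueError("outcomes not conformable with design")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcomes must contain at least one 0 and one 1")
    if link == "log":
        beta, ll, fitted, converged, boundary, cov = _fit_log(design, y, tol, max_iter)
    elif link == "logit":
        beta, ll, fitted, converged, boundary, cov = _fit_logit(
            design, y, tol, max_iter
        )
    else:
        raise ValueError(f"unknown link {link!r}")
    return BinomialGlmFit(
        link=link,
        columns=design.columns,
        beta=beta,
        loglik=ll,
        fitted=fitted,
        converged=converged,
        boundary=boundary,
        cov=cov,
        n_obs=design.n_obs,
    )


def lr_statistic(full: BinomialGlmFit, reduced: BinomialGlmFit) -> float:
    """Likelihood-ratio statistic 2*(ll_full - ll_reduced) for nested fits."""
    if full.link != reduced.link:
        raise ValueError("fits use different links")
    if not set(reduced.columns) < set(full.columns):
        raise ValueError(
            "reduced model columns must be a strict subset of the full model's"
        )
    lr = 2.0 * (full.loglik - reduced.loglik)
    if lr < 0:
        if lr > -1e-6:
            warnings.warn(f"clamping tiny negative LR {lr:.2e} to 0")
            lr = 0.0
        else:
            raise GlmError(
                f"negative LR statistic {lr:.3g}: full fit worse than reduced "
                "(optimization failure)"
            )
    return lr


def chi2_upper_tail(stat: float, df: int = 1) -> float:
    """P(chi-square_df > stat), the reference p-value for an LR statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not np.isfinite(stat) or stat < 0:
        raise ValueError("stat must be finite and >= 0")
    return float(stats.chi2.sf(stat, df))
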