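"""Two-part hurdle model for follow-on service counts.

Part 1 is a logistic regression for whether a patient undergoes any
follow-on service. Part 2 is a zero-truncated negative binomial (NB2)
regression, fitted by maximum likelihood on the testers only, for how many
services she undergoes. The parts share one design matrix convention
(:mod:`planshare.design`).

The zero-truncated NB2 log-likelihood for counts ``y >= 1`` with mean
``mu = exp(X b)`` and dispersion ``alpha`` (Var = mu + alpha mu^2) is

    sum_i [ log f(y_i; mu_i, alpha) - log(1 - f(0; mu_i, alpha)) ]

with f the untruncated NB2 pmf. All terms are evaluated in log space;
``log(1 - f(0))`` uses the log1p/expm1 split so tiny ``f(0)`` and ``f(0)``
near 1 are both handled stably.

Marginal effects of plan type are average marginal effects over the part-2
estimation sample: switch every tester's plan-type indicator to the contrast
type and to the reference type, and average the difference of the
zero-truncated mean ``m = mu / (1 - f(0; mu, alpha))``. With Duan smearing
on, ``mu`` is first multiplied by the smearing factor — the mean of the
exponentiated log-scale residuals among testers — before truncation.
Standard errors come from the delta method, propagating the part-2
observed-information covariance through the AME.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, gammaln

from .design import DesignSpec, build_design
from .errors import ConvergenceError, InvalidInputError

__all__ = [
    "HurdleFit",
    "MarginalEffect",
    "ztnb_logpmf",
    "ztnb_loglik",
    "fit_ztnb",
    "fit_logistic",
    "fit_hurdle",
    "marginal_effects",
    "duan_smearing_factor",
]


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _log1mexp(a: np.ndarray) -> np.ndarray:
    """log(1 - exp(a)) for a < 0, numerically stable on both ends."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = a < -np.log(2.0)
    out[small] = np.log1p(-np.exp(a[small]))
    out[~small] = np.log(-np.expm1(a[~small]))
    return out


def ztnb_logpmf(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Log pmf of the zero-truncated NB2 distribution at counts y >= 1."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 1):
        raise InvalidInputError("zero counts are not in the support of the truncated model")
    if alpha <= 0:
        raise InvalidInputError("alpha must be > 0")
    r = 1.0 / alpha
    log_p = -np.log1p(mu / r)          # log(r / (r + mu))
    log_q = np.log(mu) - np.log(r + mu)  # log(mu / (r + mu))
    if r > 1e6:
        # gammaln(y+r) - gammaln(r) = sum_{j<y} log(r+j); expanded to avoid
        # catastrophic cancellation near the Poisson limit
        lg_ratio = y * np.log(r) + y * (y - 1.0) / (2.0 * r)
    else:
        lg_ratio = gammaln(y + r) - gammaln(r)
    base = lg_ratio - gammaln(y + 1.0) + r * log_p + y * log_q
    log_p0 = r * log_p
    return base - _log1mexp(log_p0)


def ztnb_loglik(
    coefs: np.ndarray, alpha: float, y: np.ndarray, X: np.ndarray
) -> float:
    """Zero-truncated NB2 log-likelihood with log link mu = exp(X @ coefs)."""
    mu = np.exp(X @ np.asarray(coefs, dtype=float))
    return float(ztnb_logpmf(y, mu, alpha).sum())


def _ztnb_obj_grad(theta: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Negative loglik and gradient in theta = (beta, log alpha)."""
    beta, log_alpha = theta[:-1], theta[-1]
    alpha = np.exp(log_alpha)
    r = 1.0 / alpha
    mu = np.exp(X @ beta)
    log_p = -np.log1p(mu / r)
    log_p0 = r * log_p
    p0 = np.exp(log_p0)
    ll = ztnb_logpmf(y, mu, alpha).sum()

    # d/dmu of per-obs loglik
    denom = 1.0 - p0
    dl_dmu = y / mu - (y + r) / (mu + r) - p0 / denom * (r / (mu + r))
    grad_beta = X.T @ (dl_dmu * mu)

    # d/dr of per-obs loglik
    common = log_p + 1.0 - r / (r + mu)
    dl_dr = digamma(y + r) - digamma(r) + common - y / (r + mu)
    dl_dr += p0 / denom * common  # from -log(1 - p0)
    grad_log_alpha = float((dl_dr * (-r)).sum())  # dr/dlog(alpha) = -r
    return -float(ll), -np.concatenate([grad_beta, [grad_log_alpha]])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class HurdleFit:
    """Fitted two-part model."""

    spec: DesignSpec
    columns: list[str]
    columns_part2: list[str]
    part1_coefs: np.ndarray
    part1_vcov: np.ndarray
    part2_coefs: np.ndarray
    part2_vcov: np.ndarray  # covers (beta, log alpha)
    alpha: float
    loglik_part1: float
    loglik_part2: float
    n_obs_part1: int
    n_obs_part2: int
    converged_part1: bool
    converged_part2: bool
    smearing_factor: float = 1.0

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-term table for both parts."""
        rows = []
        for part, cols, coefs, vcov in (
            ("logit_any_use", self.columns, self.part1_coefs, self.part1_vcov),
            ("ztnb_count", self.columns_part2, self.part2_coefs, self.part2_vcov),
        ):
            se = np.sqrt(np.diag(vcov))[: len(coefs)]
            z = coefs / se
            p = 2 * stats.norm.sf(np.abs(z))
            for name, est, s, zz, pp in zip(cols, coefs, se, z, p):
                rows.append((part, name, est, s, zz, pp))
        df = pd.DataFrame(rows, columns=["part", "term", "estimate", "se", "z", "p"])
        a_se = float(np.sqrt(self.part2_vcov[-1, -1]))
        df.loc[len(df)] = ("ztnb_count", "log_alpha", np.log(self.alpha), a_se, np.nan, np.nan)
        return df


@dataclass
class MarginalEffect:
    """Delta-method contrast of one plan type against the reference."""

    contrast: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    smearing_factor: float


def fit_logistic(y: np.ndarray, X: np.ndarray):
    """Logistic MLE by iteratively reweighted least squares.

    Raises :class:`ConvergenceError` on separation or a degenerate
    (all-0 / all-1) outcome.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ConvergenceError("part-1 outcome is degenerate (all zeros or all ones)")
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels raises various types
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if np.abs(res.params).max() > 30:
        raise ConvergenceError("separation suspected in part-1 logistic fit")
    return res.params, res.cov_params(), float(res.llf), bool(res.converged)


def fit_ztnb(
    y: np.ndarray,
    X: np.ndarray,
    start: np.ndarray | None = None,
    gtol: float = 1e-6,
    ridge: float = 0.0,
):
    """Zero-truncated NB2 MLE by quasi-Newton over (beta, log alpha).

    Standard errors come from the observed information (finite-difference
    Hessian of the log-likelihood at the optimum). If the information matrix
    is not positive definite, an error advises refitting with a small
    ``ridge`` added to its diagonal.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 1):
        raise InvalidInputError("part-2 outcome must be strictly positive counts")
    n, p = X.shape
    if start is None:
        beta0 = np.zeros(p)
        beta0[0] = np.log(max(y.mean(), 1.05) - 1.0 + 0.5)
        start = np.concatenate([beta0, [np.log(0.5)]])

    # log alpha is bounded below: at tiny alpha the model degenerates to the
    # zero-truncated Poisson and the likelihood goes flat in log alpha
    bounds = [(None, None)] * p + [(np.log(1e-6), np.log(100.0))]
    res = optimize.minimize(
        _ztnb_obj_grad,
        start,
        args=(y, X),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"gtol": gtol, "ftol": 1e-12, "maxiter": 500},
    )
    theta = res.x
    alpha_at_boundary = theta[-1] < np.log(1e-4)
    # observed information = -Hessian of loglik = Hessian of objective
    from statsmodels.tools.numdiff import approx_hess3

    H = approx_hess3(theta, lambda t: _ztnb_obj_grad(t, y, X)[0])
    H = (H + H.T) / 2.0
    if ridge > 0:
        H = H + ridge * np.eye(len(theta))
    evals, evecs = np.linalg.eigh(H)
    if evals.min() <= 0:
        if alpha_at_boundary or ridge > 0:
            # flat log-alpha direction at the Poisson limit; clip its curvature
            evals = np.maximum(evals, 1e-8 * max(evals.max(), 1.0))
        else:
            raise ConvergenceError(
                "observed information is not positive definite; retry with ridge > 0"
            )
    vcov = (evecs / evals) @ evecs.T
    converged = bool(res.success) or float(np.abs(res.jac).max()) < 1e-3 * max(1.0, n / 100.0)
    return theta[:-1], float(np.exp(theta[-1])), vcov, -float(res.fun), converged


def fit_hurdle(data: pd.DataFrame, spec: DesignSpec) -> HurdleFit:
    """Fit both parts of the hurdle model on an episode/covariate table.

    ``data`` must carry the covariate columns and the outcome count column
    for ``spec.outcome``; part 1 models ``count > 0`` on all rows, part 2
    models the count on the positive rows only.
    """
    ycol = spec.outcome_column()
    if ycol not in data.columns:
        raise InvalidInputError(f"outcome column {ycol!r} missing")
    X, names = build_design(data, spec)
    y = data[ycol].to_numpy(dtype=float)
    ind = (y > 0).astype(float)
    if ind.sum() == 0 or ind.sum() == len(ind):
        raise ConvergenceError("need both zero and positive outcomes for a hurdle model")

    b1, v1, ll1, conv1 = fit_logistic(ind, X)

    pos = y > 0
    Xp = X[pos]
    # drop part-2 columns constant among testers (a level nobody who tested
    # carries can't enter the count part)
    keep = [0] + [j for j in range(1, Xp.shape[1]) if Xp[:, j].std() > 0]
    Xp = Xp[:, keep]
    names2 = [names[j] for j in keep]
    if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
        raise InvalidInputError(
            "design matrix is rank deficient among positive outcomes; "
            "coarsen covariates or pool regions"
        )
    b2, alpha, v2, ll2, conv2 = fit_ztnb(y[pos], Xp)

    mu = np.exp(Xp @ b2)
    smear = float(np.mean(y[pos] / mu))
    return HurdleFit(
        spec=spec,
        columns=names,
        columns_part2=names2,
        part1_coefs=np.asarray(b1),
        part1_vcov=np.asarray(v1),
        part2_coefs=b2,
        part2_vcov=v2,
        alpha=alpha,
        loglik_part1=ll1,
        loglik_part2=ll2,
        n_obs_part1=len(y),
        n_obs_part2=int(pos.sum()),
        converged_part1=conv1,
        converged_part2=conv2,
        smearing_factor=smear,
    )


# ---------------------------------------------------------------------------
# marginal effects
# ---------------------------------------------------------------------------

def duan_smearing_factor(y: np.ndarray, mu: np.ndarray) -> float:
    """Duan's nonparametric retransformation factor.

    Mean of the exponentiated log-scale residuals, exp(log y - log mu),
    which equals mean(y / mu).
    """
    return float(np.mean(np.asarray(y, dtype=float) / np.asarray(mu, dtype=float)))


def _truncated_mean(mu: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    log_p0 = -r * np.log1p(mu / r)
    return mu / -np.expm1(log_p0)


def _ame(
    theta: np.ndarray,
    X_on: np.ndarray,
    X_ref: np.ndarray,
    smear: float,
) -> float:
    beta, alpha = theta[:-1], float(np.exp(theta[-1]))
    m_on = _truncated_mean(smear * np.exp(X_on @ beta), alpha)
    m_ref = _truncated_mean(smear * np.exp(X_ref @ beta), alpha)
    return float(np.mean(m_on - m_ref))


def marginal_effects(
    fit: HurdleFit,
    data: pd.DataFrame,
    apply_smearing: bool = True,
    conditional: bool = True,
    contrasts: list[str] | None = None,
) -> list[MarginalEffect]:
    """Average marginal effect of each plan type vs the reference type.

    Conditional (default) effects are averages of the zero-truncated mean
    over the part-2 estimation sample — the change in expected number of
    services *among patients undergoing subsequent testing*. With
    ``conditional=False`` the part-1 probability multiplies the truncated
    mean (an unconditional two-part effect; part-1 parameters are treated as
    fixed in the delta method). CIs are Wald 95% from a normal reference.
    """
    if not (fit.converged_part1 and fit.converged_part2):
        raise ConvergenceError("cannot form marginal effects from a non-converged fit")
    ycol = fit.spec.outcome_column()
    X, names = build_design(data, fit.spec)
    if names != fit.columns:
        raise InvalidInputError("data levels do not match the fitted design")
    y = data[ycol].to_numpy(dtype=float)
    pos = y > 0
    part2_idx = [names.index(c) for c in fit.columns_part2]
    Xp = X[pos][:, part2_idx]

    plan_cols = {c: i for i, c in enumerate(fit.columns_part2) if c.startswith("plan:")}
    if contrasts is None:
        contrasts = [c.split(":", 1)[1] for c in plan_cols]
    smear = fit.smearing_factor if apply_smearing else 1.0

    p1 = None
    if not conditional:
        from scipy.special import expit

        p1 = expit(X @ fit.part1_coefs)

    theta_hat = np.concatenate([fit.part2_coefs, [np.log(fit.alpha)]])
    out = []
    for contrast in contrasts:
        col = f"plan:{contrast}"
        if col not in plan_cols:
            raise InvalidInputError(f"no design column for contrast {contrast!r}")
        X_on = Xp.copy()
        X_ref = Xp.copy()
        for c, j in plan_cols.items():
            X_on[:, j] = 1.0 if c == col else 0.0
            X_ref[:, j] = 0.0

        if conditional:
            def f(theta):
                return _ame(theta, X_on, X_ref, smear)
        else:
            w = p1[pos]

            def f(theta, w=w):
                beta, alpha = theta[:-1], float(np.exp(theta[-1]))
                m_on = _truncated_mean(smear * np.exp(X_on @ beta), alpha)
                m_ref = _truncated_mean(smear * np.exp(X_ref @ beta), alpha)
                return float(np.mean(w * (m_on - m_ref)))

        est = f(theta_hat)
        grad = _numeric_grad(f, theta_hat)
        var = float(grad @ fit.part2_vcov @ grad)
        se = np.sqrt(max(var, 0.0))
        z = est / se if se > 0 else np.inf
        out.append(
            MarginalEffect(
                contrast=f"{contrast} vs {fit.spec.plan_ref}",
                estimate=est,
                se=se,
                ci_low=est - 1.959963984540054 * se,
                ci_high=est + 1.959963984540054 * se,
                p_value=float(2 * stats.norm.sf(abs(z))),
                smearing_factor=smear,
            )
        )
    return out


def _numeric_grad(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient."""
    g = np.zeros_like(x)
    for i in range(len(x)):
        step = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2 * step)
    return g


def effects_frame(effects: list[MarginalEffect]) -> pd.DataFrame:
    """Marginal effects as a tidy table."""
    return pd.DataFrame(
        [
            {
                "contrast": e.contrast,
                "estimate": e.estimate,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "smearing_factor": e.smearing_factor,
            }
            for e in effects
        ]
    )
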