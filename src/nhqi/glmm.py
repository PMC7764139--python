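"""Risk-adjusted logistic models for facility profiling.

The random-intercept logistic model for resident *i* in facility *j* is

    logit P(y_ij = 1 | b_j) = x_ij' beta + b_j,   b_j ~ N(0, VG),

with the marginal likelihood integrated over b_j by adaptive Gauss–Hermite
quadrature: per facility the integrand is recentred at its mode and scaled by
the curvature there, so a modest quadrature order (default 15) achieves near
machine-precision likelihoods even for large facilities.  The outer
maximization runs a quasi-Newton search over (beta, sd) with sd = sqrt(VG)
bounded at zero.

The companion fixed-effects model replaces the random intercept by facility
indicator variables in sum-to-zero coding; its per-facility effect standard
errors s feed the rankability statistic VG / (VG + median(s²)).  Facilities
with zero or all events have no finite ML effect and are flagged
non-estimable rather than poisoning the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp

VR_LOGIT = np.pi**2 / 3  # residual latent-scale variance of the logit model

#: canonical risk-adjustment sets per indicator
RISK_ADJUSTERS: dict[str, tuple[str, ...]] = {
    "polypharmacy": ("cps", "care_level", "age"),
    "pain_self": ("cps", "care_level", "depression", "female"),
    "pain_observed": ("cps", "care_level", "depression", "female"),
    "restraint_trunk": ("cps", "care_level"),
    "restraint_bedrails": ("cps", "care_level"),
    "weight_loss": ("cps", "care_level"),
}


@lru_cache(maxsize=8)
def _gh_nodes(order: int):
    z, w = np.polynomial.hermite.hermgauss(order)
    return z, np.log(w)


class DegenerateDataError(ValueError):
    """Outcome is all zeros or all ones; the model is not estimable."""


class ConvergenceError(RuntimeError):
    """Model fit failed to converge."""


@dataclass(frozen=True)
class ModelSpec:
    """Model frame description: outcome, grouping and risk adjusters.

    ``adjusters=None`` selects the canonical set for the indicator;
    pass an explicit tuple (possibly empty) to override.
    """

    indicator: str
    outcome: str = "outcome"
    facility: str = "facility_id"
    adjusters: tuple[str, ...] | None = None

    def adjuster_names(self) -> tuple[str, ...]:
        if self.adjusters is not None:
            return tuple(self.adjusters)
        if self.indicator not in RISK_ADJUSTERS:
            raise KeyError(f"no canonical adjuster set for {self.indicator!r}")
        return RISK_ADJUSTERS[self.indicator]


@dataclass
class GlmmFit:
    """A fitted random-intercept logistic model."""

    indicator: str
    beta: pd.Series  # fixed effects incl. intercept, logit scale
    vg: float  # facility (group) variance on the latent scale
    loglik: float
    n_groups: int
    n_obs: int
    converged: bool
    quad_order: int
    facilities: np.ndarray = field(repr=False)
    # model frame retained for empirical Bayes / bootstrap
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    group_codes: np.ndarray = field(repr=False, default=None)

    @property
    def vr(self) -> float:
        return VR_LOGIT

    @property
    def icc1(self) -> float:
        return self.vg / (self.vg + VR_LOGIT)

    def summary(self) -> dict:
        return {
            "indicator": self.indicator,
            "coefficients": {k: float(v) for k, v in self.beta.items()},
            "vg": float(self.vg),
            "vr": float(self.vr),
            "icc1": float(self.icc1),
            "loglik": float(self.loglik),
            "n_groups": int(self.n_groups),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "quad_order": int(self.quad_order),
        }


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """(X with leading intercept, y, group codes, facility labels, names)."""
    from nhqi.coding import code_covariates

    y = data[spec.outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values; apply listwise deletion upstream")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    names = list(spec.adjuster_names())
    coded = code_covariates(data, names) if names else pd.DataFrame(index=data.index)
    if coded.isna().any().any():
        raise ValueError("missing covariate values; apply listwise deletion upstream")
    X = np.column_stack([np.ones(len(data))] + [coded[c].to_numpy() for c in names])
    codes, labels = pd.factorize(data[spec.facility], sort=True)
    return X, y, codes, np.asarray(labels), ["intercept"] + names


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite machinery


def _collapse(X: np.ndarray, y: np.ndarray, codes: np.ndarray):
    """Merge duplicate (facility, covariate-pattern, outcome) rows.

    The Bernoulli likelihood depends on such rows only through their count,
    so collapsing them into frequency weights leaves every likelihood value
    identical while shrinking the working arrays (dramatic for intercept-only
    designs, where each facility reduces to two weighted rows).
    """
    M = np.column_stack([codes, y, X])
    uniq, counts = np.unique(M, axis=0, return_counts=True)
    if len(uniq) > 0.8 * len(M):  # nothing to gain
        return X, y, codes, None
    return (
        uniq[:, 2:],
        uniq[:, 1],
        uniq[:, 0].astype(np.intp),
        counts.astype(float),
    )


def _group_modes(
    eta0: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    k: int,
    vg: float,
    weights: np.ndarray | None = None,
    b0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 50,
):
    """Newton mode + curvature of each facility's log integrand in b."""
    w = np.ones_like(y) if weights is None else weights
    b = np.zeros(k) if b0 is None else b0.copy()
    ssum = lambda v: np.bincount(codes, weights=v, minlength=k)  # noqa: E731
    for _ in range(max_iter):
        p = expit(eta0 + b[codes])
        g = ssum(w * (y - p)) - b / vg
        h = -ssum(w * p * (1 - p)) - 1.0 / vg
        # concave 1-D objective: full Newton steps, clipped against overshoot
        b = b - np.clip(g / h, -5.0, 5.0)
        if np.max(np.abs(g)) < tol:
            break
    p = expit(eta0 + b[codes])
    h = -np.bincount(codes, weights=w * p * (1 - p), minlength=k) - 1.0 / vg
    return b, h


def marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    beta: np.ndarray,
    sd: float,
    quad_order: int = 15,
    weights: np.ndarray | None = None,
    return_modes: bool = False,
):
    """Adaptive Gauss–Hermite marginal log-likelihood of the model."""
    k = int(codes.max()) + 1
    wt = np.ones_like(y) if weights is None else weights
    eta0 = X @ beta
    if sd < 1e-8:
        ll = float(np.sum(wt * (y * log_expit(eta0) + (1 - y) * log_expit(-eta0))))
        if return_modes:
            return ll, np.zeros(k), np.full(k, -np.inf)
        return ll
    vg = sd * sd
    b_hat, h = _group_modes(eta0, y, codes, k, vg, weights=weights)
    sigma = 1.0 / np.sqrt(-h)

    z, log_w = _gh_nodes(quad_order)
    # nodes: k x q
    nodes = b_hat[:, None] + np.sqrt(2.0) * sigma[:, None] * z[None, :]
    log_f = np.empty((k, quad_order))
    for q in range(quad_order):
        eta = eta0 + nodes[:, q][codes]
        ll_obs = wt * (y * log_expit(eta) + (1 - y) * log_expit(-eta))
        log_f[:, q] = np.bincount(codes, weights=ll_obs, minlength=k)
    log_f += (
        -0.5 * nodes**2 / vg - 0.5 * np.log(2 * np.pi * vg)
    )  # normal prior density
    arg = log_w[None, :] + z[None, :] ** 2 + log_f
    m = arg.max(axis=1)
    log_i = m + np.log(np.exp(arg - m[:, None]).sum(axis=1))
    log_i += 0.5 * np.log(2.0) + np.log(sigma)
    ll = float(log_i.sum())
    if return_modes:
        return ll, b_hat, h
    return ll


def brute_force_loglik(
    X: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    beta: np.ndarray,
    sd: float,
    half_width_sd: float = 8.0,
    n_points: int = 4001,
) -> float:
    """Dense-trapezoid marginal log-likelihood (independent oracle).

    Integrates each facility's likelihood over a +-``half_width_sd``·sd grid
    around zero with ``n_points`` trapezoid points.  Slow but assumption-free
    apart from the grid width; used to validate the quadrature path.
    """
    k = int(codes.max()) + 1
    eta0 = X @ beta
    if sd < 1e-12:
        return float(np.sum(y * log_expit(eta0) + (1 - y) * log_expit(-eta0)))
    grid = np.linspace(-half_width_sd * sd, half_width_sd * sd, n_points)
    log_prior = -0.5 * grid**2 / sd**2 - 0.5 * np.log(2 * np.pi * sd**2)
    log_f = np.empty((k, n_points))
    for m, b in enumerate(grid):
        eta = eta0 + b
        ll_obs = y * log_expit(eta) + (1 - y) * log_expit(-eta)
        log_f[:, m] = np.bincount(codes, weights=ll_obs, minlength=k) + log_prior[m]
    # trapezoid in log space
    dx = grid[1] - grid[0]
    inner = logsumexp(log_f[:, 1:-1], axis=1)
    ends = logsumexp(log_f[:, [0, -1]], axis=1) + np.log(0.5)
    return float((logsumexp(np.column_stack([inner, ends]), axis=1) + np.log(dx)).sum())


def _logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50):
    """ML logistic regression by damped Newton (starting values only)."""

    def loglik(b):
        eta = X @ b
        return float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta)))

    beta = np.zeros(X.shape[1])
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    ll = loglik(beta)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        g = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # halve the step until the log-likelihood does not decrease
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll = cand, ll_new
        if np.max(np.abs(g)) < 1e-10:
            break
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-10, None)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(H)
    return beta, cov, ll


def fit_random_intercept_logistic(
    data: pd.DataFrame,
    spec: ModelSpec,
    quad_order: int = 15,
    start: np.ndarray | None = None,
    gtol: float = 1e-6,
    max_iter: int = 200,
) -> GlmmFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Parameters
    ----------
    data : model frame with the outcome, facility and raw covariate columns
        (listwise deletion applied upstream — no missing values allowed).
    spec : which indicator / adjusters / columns to use.
    quad_order : adaptive Gauss–Hermite order (>= 7; default 15).
    start : optional (beta..., sd) warm start, e.g. for bootstrap refits.
    """
    if quad_order < 7:
        raise ValueError("quad_order must be >= 7")
    X, y, codes, labels, names = build_design(data, spec)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 facilities")
    if y.min() == y.max():
        raise DegenerateDataError("outcome is constant (all 0 or all 1)")

    if start is None:
        beta0, _, _ = _logistic_irls(X, y)
        x0 = np.append(beta0, 0.5)
    else:
        x0 = np.asarray(start, dtype=float)

    Xc, yc, cc, wc = _collapse(X, y, codes)

    def negll(params: np.ndarray) -> float:
        return -marginal_loglik(
            Xc, yc, cc, params[:-1], params[-1], quad_order, weights=wc
        )

    bounds = [(None, None)] * (X.shape[1]) + [(0.0, None)]
    res = minimize(
        negll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    if not res.success:
        # L-BFGS-B line searches occasionally stall near the optimum;
        # a short derivative-free polish from its iterate settles it
        polish = minimize(
            negll,
            res.x,
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-8, "fatol": 1e-10},
        )
        if polish.fun <= res.fun:
            res = polish
    beta_hat, sd_hat = res.x[:-1], float(max(res.x[-1], 0.0))
    converged = bool(res.success)
    return GlmmFit(
        indicator=spec.indicator,
        beta=pd.Series(beta_hat, index=names),
        vg=sd_hat**2,
        loglik=float(-res.fun),
        n_groups=k,
        n_obs=len(y),
        converged=converged,
        quad_order=quad_order,
        facilities=labels,
        X=X,
        y=y,
        group_codes=codes,
    )


def empirical_bayes_effects(fit: GlmmFit) -> pd.DataFrame:
    """Per-facility empirical-Bayes random intercepts.

    Returns ``facility_id, eb_estimate, eb_sd``: the posterior mode of each
    facility's random intercept given the data and the ML estimates, with the
    conditional SD taken from the curvature of the log posterior at the mode.
    """
    if not fit.converged:
        raise ConvergenceError("cannot compute EB effects from a non-converged fit")
    k = fit.n_groups
    eta0 = fit.X @ fit.beta.to_numpy()
    if fit.vg < 1e-12:
        b = np.zeros(k)
        sd = np.zeros(k)
    else:
        b, h = _group_modes(eta0, fit.y, fit.group_codes, k, fit.vg)
        sd = 1.0 / np.sqrt(-h)
    return pd.DataFrame(
        {"facility_id": fit.facilities, "eb_estimate": b, "eb_sd": sd}
    )


def fit_fixed_effects_logistic(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Fixed-effects logistic model with sum-to-zero facility contrasts.

    Returns ``facility_id, fe_estimate, fe_se, estimable``.  Facilities whose
    outcome is constant (zero or all events) have no finite ML effect; they
    are dropped from the fit, returned with ``estimable=False`` and NaN
    effect/SE, and are excluded downstream from median(s²).
    """
    X, y, codes, labels, names = build_design(data, spec)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 facilities")

    means = np.bincount(codes, weights=y, minlength=k) / np.bincount(codes, minlength=k)
    estimable = (means > 0) & (means < 1)
    keep = np.where(estimable)[0]
    if len(keep) < 2:
        raise DegenerateDataError("fewer than 2 facilities with non-degenerate outcomes")

    mask = estimable[codes]
    sub_codes, _ = pd.factorize(codes[mask], sort=True)
    m = len(keep)
    # sum-to-zero contrasts: m-1 columns; last facility = -(sum of others)
    C = np.zeros((m, m - 1))
    C[: m - 1, :] = np.eye(m - 1)
    C[m - 1, :] = -1.0
    F = C[sub_codes]
    Xs = np.column_stack([X[mask], F])
    import statsmodels.api as sm

    res = sm.Logit(y[mask], Xs).fit(disp=0, method="newton", maxiter=200, tol=1e-10)
    beta, cov = np.asarray(res.params), np.asarray(res.cov_params())

    p = X.shape[1]
    alpha = C @ beta[p:]
    cov_a = cov[p:, p:]
    var = np.einsum("ij,jk,ik->i", C, cov_a, C)
    se = np.sqrt(np.clip(var, 0, None))

    out = pd.DataFrame(
        {
            "facility_id": labels,
            "fe_estimate": np.nan,
            "fe_se": np.nan,
            "estimable": estimable,
        }
    )
    out.loc[keep, "fe_estimate"] = alpha
    out.loc[keep, "fe_se"] = se
    return out


def facility_effects(fit: GlmmFit, data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Merge empirical-Bayes and fixed-model facility effects on facility_id."""
    eb = empirical_bayes_effects(fit)
    fe = fit_fixed_effects_logistic(data, spec)
    return eb.merge(fe, on="facility_id", how="left")
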