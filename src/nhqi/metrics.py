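"""Between-provider variability and reliability metrics.

On the latent logistic scale the residual variance is fixed at π²/3, so the
facility-level intraclass correlation is

    ICC1 = VG / (VG + π²/3),

with values above 0.05 conventionally read as relevant between-provider
variability.  The reliability of the facility mean over k facilities is the
Spearman–Brown step-up

    ICC2 = VG / (VG + (π²/3) / k),

and rankability — the share of between-facility heterogeneity reflecting
true quality differences rather than estimation noise — is

    ρ = VG / (VG + median(s²)),

where s are the facility-effect standard errors from the parallel
fixed-effects logistic model.  ρ is classed low (< 0.50), moderate
(0.50–0.75) or high (> 0.75).

Uncertainty in ICC1/ICC2 is assessed by a parametric bootstrap: outcomes are
re-simulated from the fitted model, the model refitted, and the statistic
recomputed; percentile 2.5/97.5 bounds form the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from nhqi.glmm import VR_LOGIT, GlmmFit, marginal_loglik

ICC1_RELEVANCE_THRESHOLD = 0.05


def icc1(vg: float) -> float:
    """Latent-scale intraclass correlation VG / (VG + π²/3)."""
    if vg < 0:
        raise ValueError("group variance must be >= 0")
    return vg / (vg + VR_LOGIT)


def icc1_to_vg(value: float) -> float:
    """Invert ICC1 back to the latent group variance VG."""
    if not 0 <= value < 1:
        raise ValueError("icc1 must lie in [0, 1)")
    return value / (1.0 - value) * VR_LOGIT


def icc2(vg: float, k: int) -> float:
    """Group-mean reliability VG / (VG + (π²/3)/k) over k facilities.

    Equals the Spearman–Brown step-up of ICC1 with factor k, so it is
    monotone increasing in both VG and k and reduces to ICC1 at k = 1.
    """
    if vg < 0:
        raise ValueError("group variance must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    return vg / (vg + VR_LOGIT / k)


def rankability(vg: float, fe_ses) -> float:
    """ρ = VG / (VG + median(s²)) over the finite facility-effect SEs."""
    if vg < 0:
        raise ValueError("group variance must be >= 0")
    ses = np.asarray(fe_ses, dtype=float)
    ses = ses[np.isfinite(ses)]
    if ses.size == 0:
        raise ValueError("no finite facility-effect standard errors")
    med_s2 = float(np.median(ses**2))
    if vg == 0 and med_s2 == 0:
        return 0.0
    return vg / (vg + med_s2)


def classify_rankability(rho: float) -> str:
    """Band a rankability value: low < 0.50 <= moderate <= 0.75 < high."""
    if not 0 <= rho <= 1:
        raise ValueError("rankability must lie in [0, 1]")
    if rho < 0.50:
        return "low"
    if rho <= 0.75:
        return "moderate"
    return "high"


@dataclass
class BootstrapResult:
    statistic: str
    point: float
    lower: float
    upper: float
    n_boot: int
    n_failed: int
    replicates: np.ndarray


def parametric_bootstrap(
    fit: GlmmFit,
    statistic: str = "icc1",
    n_boot: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.2,
) -> BootstrapResult:
    """Percentile bootstrap interval for ICC1 or ICC2 from a fitted model.

    Each replicate redraws facility intercepts from N(0, VG) and outcomes
    from the fitted conditional probabilities, refits the model (warm-started
    at the MLE) and recomputes the statistic.
    """
    if statistic not in ("icc1", "icc2"):
        raise ValueError("statistic must be 'icc1' or 'icc2'")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not fit.converged:
        raise RuntimeError("cannot bootstrap a non-converged fit")

    rng = np.random.default_rng(seed)
    X, codes, k = fit.X, fit.group_codes, fit.n_groups
    eta0 = X @ fit.beta.to_numpy()
    sd = np.sqrt(fit.vg)
    start = np.append(fit.beta.to_numpy(), sd)
    values = []
    n_failed = 0
    for _ in range(n_boot):
        b = rng.normal(0.0, sd, size=k)
        y_star = (rng.random(fit.n_obs) < expit(eta0 + b[codes])).astype(float)
        if y_star.min() == y_star.max():
            n_failed += 1
            continue
        try:
            vg = _refit(fit, y_star, start)
        except Exception:
            n_failed += 1
            continue
        values.append(icc1(vg) if statistic == "icc1" else icc2(vg, k))
    if n_failed > max_failure_rate * n_boot:
        raise RuntimeError(
            f"bootstrap refit failure rate {n_failed}/{n_boot} exceeds "
            f"{max_failure_rate:.0%}"
        )
    arr = np.asarray(values)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    point = icc1(fit.vg) if statistic == "icc1" else icc2(fit.vg, k)
    return BootstrapResult(
        statistic=statistic,
        point=float(point),
        lower=float(lo),
        upper=float(hi),
        n_boot=n_boot,
        n_failed=n_failed,
        replicates=arr,
    )


def _refit(fit: GlmmFit, y_star: np.ndarray, start: np.ndarray) -> float:
    """Refit VG on resampled outcomes, reusing the design (fast path)."""
    from scipy.optimize import minimize

    from nhqi.glmm import _collapse

    X, y, codes, w = _collapse(fit.X, y_star, fit.group_codes)

    def negll(params):
        return -marginal_loglik(
            X, y, codes, params[:-1], params[-1], fit.quad_order, weights=w
        )

    bounds = [(None, None)] * (X.shape[1]) + [(0.0, None)]
    res = minimize(
        negll, start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "gtol": 1e-6, "ftol": 1e-12},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("refit produced non-finite log-likelihood")
    return float(max(res.x[-1], 0.0)) ** 2


def bootstrap_ci(
    fit: GlmmFit,
    statistic: str = "icc1",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Convenience wrapper returning the (lower, upper) percentile interval."""
    res = parametric_bootstrap(fit, statistic=statistic, n_boot=n_boot, seed=seed)
    return res.lower, res.upper


@dataclass
class VariabilityReport:
    """Between-provider variability and reliability summary for one indicator."""

    indicator: str
    icc1: float
    icc1_ci: tuple[float, float] | None
    icc2: float
    icc2_ci: tuple[float, float] | None
    rankability: float
    rankability_class: str
    median_s2: float
    k: int
    n_nonestimable: int = 0

    @property
    def icc1_relevant(self) -> bool:
        return self.icc1 > ICC1_RELEVANCE_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "icc1": self.icc1,
            "icc1_ci": list(self.icc1_ci) if self.icc1_ci else None,
            "icc1_relevant": self.icc1_relevant,
            "icc2": self.icc2,
            "icc2_ci": list(self.icc2_ci) if self.icc2_ci else None,
            "rankability": self.rankability,
            "rankability_class": self.rankability_class,
            "median_s2": self.median_s2,
            "k": self.k,
            "n_nonestimable": self.n_nonestimable,
        }


def variability_report(
    fit: GlmmFit,
    fe_effects: pd.DataFrame,
    n_boot: int = 0,
    seed: int = 0,
) -> VariabilityReport:
    """Assemble ICC1/ICC2/rankability (with optional bootstrap CIs)."""
    ses = fe_effects.loc[fe_effects["estimable"].fillna(False), "fe_se"]
    rho = rankability(fit.vg, ses)
    ci1 = ci2 = None
    if n_boot:
        ci1 = bootstrap_ci(fit, "icc1", n_boot=n_boot, seed=seed)
        ci2 = bootstrap_ci(fit, "icc2", n_boot=n_boot, seed=seed + 1)
    return VariabilityReport(
        indicator=fit.indicator,
        icc1=icc1(fit.vg),
        icc1_ci=ci1,
        icc2=icc2(fit.vg, fit.n_groups),
        icc2_ci=ci2,
        rankability=rho,
        rankability_class=classify_rankability(rho),
        median_s2=float(np.median(ses.dropna() ** 2)),
        k=fit.n_groups,
        n_nonestimable=int((~fe_effects["estimable"].fillna(False)).sum()),
    )
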