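import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from nhqi.glmm import (
    DegenerateDataError,
    ModelSpec,
    brute_force_loglik,
    build_design,
    empirical_bayes_effects,
    facility_effects,
    fit_fixed_effects_logistic,
    fit_random_intercept_logistic,
    marginal_loglik,
)
from nhqi.simulate import SimulationConfig, simulate_outcomes

from conftest import make_records

SPEC_CPS = ModelSpec("test", adjusters=("cps",))


@pytest.fixture(scope="module")
def design_5x20(outcome_frame_5x20):
    X, y, codes, labels, names = build_design(outcome_frame_5x20, SPEC_CPS)
    return X, y, codes


@pytest.mark.parametrize(
    "beta,sd",
    [
        ((-1.0, 0.2), 0.8),
        ((0.5, -0.1), 0.3),
        ((0.0, 0.0), 1.5),
        ((-2.0, 0.4), 2.5),
    ],
)
def test_quadrature_matches_brute_force_integration(design_5x20, beta, sd):
    """Adaptive GH likelihood vs dense trapezoid over ±8 SD, within 1e-6."""
    X, y, codes = design_5x20
    agq = marginal_loglik(X, y, codes, np.array(beta), sd, quad_order=15)
    brute = brute_force_loglik(X, y, codes, np.array(beta), sd)
    assert agq == pytest.approx(brute, abs=1e-6)


def test_quadrature_order_converged(design_5x20):
    X, y, codes = design_5x20
    beta = np.array([-1.0, 0.2])
    a15 = marginal_loglik(X, y, codes, beta, 0.8, quad_order=15)
    a31 = marginal_loglik(X, y, codes, beta, 0.8, quad_order=31)
    assert abs(a15 - a31) < 1e-6


def test_zero_variance_reduces_to_plain_logistic(design_5x20):
    """At VG=0 the mixed model nests ordinary logistic regression."""
    import statsmodels.api as sm

    X, y, codes = design_5x20
    beta = np.array([-0.8, 0.15])
    mixed = marginal_loglik(X, y, codes, beta, 0.0)
    plain = sm.Logit(y, X).loglike(beta)
    assert mixed == pytest.approx(plain, abs=1e-10)


def test_fit_agrees_with_lme4(tmp_path, outcome_frame_5x20):
    """Cross-check the ML fit against glmer (adaptive GH, nAGQ=15) in R."""
    df = outcome_frame_5x20[["facility_id", "cps", "outcome"]].copy()
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    fit = fit_random_intercept_logistic(outcome_frame_5x20, SPEC_CPS)
    script = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(outcome ~ cps + (1 | facility_id), data = d,
                   family = binomial, nAGQ = 15)
        cat(sprintf("%.8f %.8f %.8f %.8f\\n", as.numeric(logLik(m)),
            unlist(VarCorr(m))[1], fixef(m)[1], fixef(m)[2]))
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    ll, vg, b0, b1 = map(float, out.stdout.split())
    assert fit.loglik == pytest.approx(ll, abs=1e-4)
    assert fit.vg == pytest.approx(vg, abs=1e-3)
    assert fit.beta["intercept"] == pytest.approx(b0, abs=1e-3)
    assert fit.beta["cps"] == pytest.approx(b1, abs=1e-3)


def test_location_invariance_of_variance_and_slopes():
    """Shifting a continuous covariate moves only the intercept."""
    cfg = SimulationConfig(
        n_facilities=30,
        residents_per_facility=40,
        group_sd=0.7,
        intercept=-1.0,
        fixed_effects={"age": 0.3},
        seed=23,
    )
    df = simulate_outcomes(cfg, ["age"])
    spec = ModelSpec("test", adjusters=("age",))
    fit = fit_random_intercept_logistic(df, spec)

    shifted = df.copy()
    shifted["age"] = shifted["age"] + 10.0  # +1 on the decade scale
    fit_s = fit_random_intercept_logistic(shifted, spec)

    assert fit_s.loglik == pytest.approx(fit.loglik, abs=1e-6)
    assert fit_s.vg == pytest.approx(fit.vg, abs=1e-4)
    assert fit_s.beta["age"] == pytest.approx(fit.beta["age"], abs=1e-4)
    expected_intercept = fit.beta["intercept"] - fit.beta["age"]
    assert fit_s.beta["intercept"] == pytest.approx(expected_intercept, abs=1e-4)


def test_degenerate_outcome_raises():
    records = make_records(*({"facility_id": f"F{i}"} for i in range(4)))
    records["outcome"] = 0
    with pytest.raises(DegenerateDataError):
        fit_random_intercept_logistic(records, ModelSpec("test", adjusters=()))


def test_quad_order_floor():
    records = make_records({}, {"facility_id": "F2"})
    records["outcome"] = [0, 1]
    with pytest.raises(ValueError, match="quad_order"):
        fit_random_intercept_logistic(
            records, ModelSpec("test", adjusters=()), quad_order=3
        )


@pytest.fixture(scope="module")
def sim_fit():
    cfg = SimulationConfig(
        n_facilities=40,
        residents_per_facility=80,
        group_sd=0.8,
        intercept=-1.2,
        fixed_effects={"cps": 0.2},
        seed=31,
    )
    df = simulate_outcomes(cfg, ["cps"])
    fit = fit_random_intercept_logistic(df, SPEC_CPS)
    return df, fit


class TestEmpiricalBayes:
    def test_balanced_null_facilities_have_zero_effect(self):
        # two facilities with identical covariates and identical event rates:
        # neither deviates from its predicted rate, so both EB effects are ~0
        rows = []
        for fac in ("F001", "F002"):
            for i in range(40):
                rows.append({"facility_id": fac, "outcome": int(i < 20)})
        df = pd.DataFrame(rows)
        df["resident_id"] = [f"r{i}" for i in range(len(df))]
        for col, val in (("care_level", 5), ("cps", 2), ("drs", 1), ("sex", "female")):
            df[col] = val
        fit = fit_random_intercept_logistic(df, ModelSpec("test", adjusters=()))
        eb = empirical_bayes_effects(fit)
        assert np.allclose(eb["eb_estimate"], 0.0, atol=1e-6)

    def test_shrinkage_toward_zero(self, sim_fit):
        """EB estimates track the fixed-model effects but are shrunk."""
        df, fit = sim_fit
        eff = facility_effects(fit, df, SPEC_CPS)
        ok = eff["estimable"].fillna(False)
        eb = eff.loc[ok, "eb_estimate"]
        fe = eff.loc[ok, "fe_estimate"]
        r = np.corrcoef(eb, fe)[0, 1]
        slope = np.polyfit(fe, eb, 1)[0]
        assert r > 0.95
        assert slope < 1.0
        # global shrinkage: the EB distribution is strictly tighter
        assert eb.var() < fe.var()

    def test_vanishing_variance_shrinks_everything_to_zero(self, sim_fit):
        import dataclasses

        df, fit = sim_fit
        tiny = dataclasses.replace(fit, vg=1e-14)
        eb = empirical_bayes_effects(tiny)
        assert np.allclose(eb["eb_estimate"], 0.0)


class TestFixedEffectsModel:
    def test_symmetric_facilities_have_zero_effects(self):
        rows = []
        for fac in ("F001", "F002"):
            for i in range(20):
                rows.append({"facility_id": fac, "outcome": int(i < 10)})
        df = pd.DataFrame(rows)
        for col, val in (("care_level", 5), ("cps", 2), ("drs", 1), ("sex", "female")):
            df[col] = val
        df["resident_id"] = [f"r{i}" for i in range(len(df))]
        fe = fit_fixed_effects_logistic(df, ModelSpec("test", adjusters=()))
        assert np.allclose(fe["fe_estimate"], 0.0, atol=1e-8)

    def test_matches_independent_ml_solver(self, outcome_frame_5x20):
        """Sum-to-zero facility effects vs a generic optimizer on the
        dummy-expanded design."""
        from scipy.optimize import minimize
        from scipy.special import log_expit

        fe = fit_fixed_effects_logistic(outcome_frame_5x20, SPEC_CPS)
        X, y, codes, labels, _ = build_design(outcome_frame_5x20, SPEC_CPS)
        k = len(labels)
        C = np.zeros((k, k - 1))
        C[: k - 1] = np.eye(k - 1)
        C[k - 1] = -1.0
        Xs = np.column_stack([X, C[codes]])

        def negll(b):
            eta = Xs @ b
            return -np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta))

        def grad(b):
            from scipy.special import expit

            return -Xs.T @ (y - expit(Xs @ b))

        res = minimize(negll, np.zeros(Xs.shape[1]), jac=grad, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 1000})
        alpha = C @ res.x[X.shape[1]:]
        assert np.allclose(fe["fe_estimate"], alpha, atol=1e-6)

    def test_se_scales_with_inverse_root_n(self):
        def median_se(rpf, seed):
            cfg = SimulationConfig(
                n_facilities=30,
                residents_per_facility=rpf,
                group_sd=0.5,
                intercept=-1.0,
                seed=seed,
            )
            df = simulate_outcomes(cfg)
            fe = fit_fixed_effects_logistic(df, ModelSpec("test", adjusters=()))
            return fe.loc[fe["estimable"], "fe_se"].median()

        ratio = median_se(50, 41) / median_se(200, 41)
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_degenerate_facilities_flagged_not_fatal(self):
        rows = []
        for fac, rate in (("F001", 0.5), ("F002", 0.0), ("F003", 0.4)):
            for i in range(20):
                rows.append({"facility_id": fac, "outcome": int(i < rate * 20)})
        df = pd.DataFrame(rows)
        for col, val in (("care_level", 5), ("cps", 2), ("drs", 1), ("sex", "female")):
            df[col] = val
        df["resident_id"] = [f"r{i}" for i in range(len(df))]
        fe = fit_fixed_effects_logistic(df, ModelSpec("test", adjusters=()))
        assert not fe.set_index("facility_id").loc["F002", "estimable"]
        assert np.isnan(fe.set_index("facility_id").loc["F002", "fe_se"])
        assert fe["estimable"].sum() == 2
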