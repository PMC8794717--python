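"""Design matrices, OLS/AICc conventions, ranking, F tests, envelopes."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from isoniche import (
    DriverSelection,
    ModelFit,
    aicc,
    all_subsets,
    build_design_matrix,
    compare_to_null,
    envelope_normality_check,
    fit_ols,
    rank_models,
    transform_response,
)
from isoniche.exceptions import (
    CollinearityError,
    DomainError,
    InsufficientDataError,
    MarginalityError,
    NestingError,
)


@pytest.fixture()
def covariates(rng):
    n = 40
    return pd.DataFrame({
        "individual_id": [f"i{j}" for j in range(n)],
        "mass": rng.normal(8.0, 1.5, n),
        "sex": rng.choice(["F", "M"], n),
        "competition": rng.choice(["lowered", "normal"], n),
    })


class TestDesignMatrix:
    def test_intercept_only(self, covariates):
        X = build_design_matrix(covariates, ())
        assert list(X.columns) == ["Intercept"]
        assert (X["Intercept"] == 1.0).all()

    def test_binary_factor_indicator(self):
        df = pd.DataFrame({"sex": ["M", "F", "F", "M"]})
        X = build_design_matrix(df, ("sex",))
        # reference = first level alphabetically (F)
        assert list(X.columns) == ["Intercept", "sex[M]"]
        assert X["sex[M]"].tolist() == [1.0, 0.0, 0.0, 1.0]

    def test_interaction_columns_and_marginality(self, covariates):
        X = build_design_matrix(covariates, ("mass", "competition"),
                                (("mass", "competition"),))
        assert X.shape[1] == 4
        inter = [c for c in X.columns if ":" in c][0]
        parents = inter.split(":")
        np.testing.assert_allclose(
            X[inter], X[parents[0]] * X[parents[1]])
        with pytest.raises(MarginalityError):
            build_design_matrix(covariates, ("mass",),
                                (("mass", "competition"),))

    def test_aliased_columns_named(self, covariates):
        df = covariates.assign(mass2=covariates["mass"] * 2.0)
        with pytest.raises(CollinearityError, match="mass"):
            build_design_matrix(df, ("mass", "mass2"))


class TestFitOLS:
    def test_exact_fit(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        X = build_design_matrix(df, ("x",))
        fit = fit_ols(X, 2.0 + 3.0 * df["x"])
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_intercept_only_hand_arithmetic(self):
        X = pd.DataFrame({"Intercept": [1.0, 1.0, 1.0]})
        fit = fit_ols(X, [1.0, 2.0, 3.0])
        assert fit.params["Intercept"] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(2.0)
        assert fit.k == 2  # mean + variance

    def test_matches_normal_equations_and_statsmodels(self, rng):
        import statsmodels.api as sm

        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(30, 3)),
                             columns=["a", "b", "c"])
            X.insert(0, "Intercept", 1.0)
            y = rng.normal(size=30)
            fit = fit_ols(X, y)
            # independent solver: normal equations
            arr = X.to_numpy()
            beta = np.linalg.solve(arr.T @ arr, arr.T @ y)
            np.testing.assert_allclose(fit.params.to_numpy(), beta,
                                       atol=1e-9)
            # ML log-likelihood convention matches statsmodels OLS
            sm_fit = sm.OLS(y, arr).fit()
            assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-8)

    def test_underdetermined(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(InsufficientDataError):
            fit_ols(X, [1.0, 2.0, 3.0])


class TestAICc:
    def test_published_convention_values(self):
        # df/logLik rows of a ranked NSI table: recomputing AICc from the
        # printed logLik and df reproduces the printed deltas
        a1 = aicc(22.234, 4, 70)
        a2 = aicc(23.141, 5, 70)
        a3 = aicc(22.623, 5, 70)
        assert a1 == pytest.approx(-35.8526, abs=1e-3)
        assert a2 - a1 == pytest.approx(0.51, abs=0.01)
        assert a3 - a1 == pytest.approx(1.55, abs=0.01)

    def test_linearity_in_loglik(self):
        assert aicc(10.5, 4, 70) - aicc(10.0, 4, 70) == pytest.approx(-1.0)

    def test_small_sample_correction_vanishes(self):
        k, ll = 5, -10.0
        aic = -2 * ll + 2 * k
        assert aicc(ll, k, 40) > aic
        assert aicc(ll, k, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_domain(self):
        with pytest.raises(DomainError):
            aicc(0.0, 5, 6)


class TestAllSubsets:
    def test_counts(self):
        mains = ("age", "sex", "mass", "competition", "site")
        assert len(all_subsets(mains)) == 32
        assert len(all_subsets(mains, (("mass", "competition"),))) == 40
        assert all_subsets(()) == [((), ())]

    def test_deterministic_order(self):
        a = all_subsets(("b", "a"))
        assert a == [((), ()), (("a",), ()), (("b",), ()),
                     (("a", "b"), ())]


def _fit_with_aicc(label, value, n=70):
    return ModelFit(response="NSI", terms=(label,), interactions=(),
                    params=pd.Series({"Intercept": 0.0, label: 0.0}),
                    n=n, k=3, rss=1.0, loglik=0.0, aicc=value, r2=0.0,
                    residuals=np.zeros(n), fitted=np.zeros(n))


class TestRanking:
    def test_published_support_weights(self):
        # deltas 0.00/0.51/1.55 renormalized over the supported set give
        # weights 0.447/0.347/0.206
        fits = [_fit_with_aicc("m1", -35.85), _fit_with_aicc("m2", -35.34),
                _fit_with_aicc("m3", -34.30), _fit_with_aicc("m4", -30.0)]
        fits[1].aicc = fits[0].aicc + 0.51
        fits[2].aicc = fits[0].aicc + 1.55
        table = rank_models(fits)
        w = table.frame["weight_supported"].to_numpy()[:3]
        np.testing.assert_allclose(w, [0.447, 0.347, 0.206], atol=1e-3)
        assert table.frame["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table.frame["support"].tolist() == [True, True, True, False]

    def test_single_and_tied_models(self):
        t = rank_models([_fit_with_aicc("only", -10.0)])
        assert t.frame["weight"].tolist() == [1.0]
        tied = rank_models([_fit_with_aicc("a", -10.0),
                            _fit_with_aicc("b", -10.0)])
        np.testing.assert_allclose(tied.frame["weight"], [0.5, 0.5])

    def test_shift_invariance(self):
        fits_a = [_fit_with_aicc("a", -10.0), _fit_with_aicc("b", -8.0)]
        fits_b = [_fit_with_aicc("a", 90.0), _fit_with_aicc("b", 92.0)]
        wa = rank_models(fits_a).frame["weight"].to_numpy()
        wb = rank_models(fits_b).frame["weight"].to_numpy()
        np.testing.assert_allclose(wa, wb, atol=1e-12)

    def test_mixed_responses_rejected(self):
        other = _fit_with_aicc("x", -9.0)
        other.response = "CSI"
        with pytest.raises(NestingError):
            rank_models([_fit_with_aicc("a", -10.0), other])


class TestCompareToNull:
    def _pair(self, rng, beta=1.0, sigma=0.1, n=70):
        x = rng.normal(size=n)
        y = beta * x + rng.normal(0.0, sigma, n)
        df = pd.DataFrame({"x": x})
        top = fit_ols(build_design_matrix(df, ("x",)), y, terms=("x",))
        null = fit_ols(build_design_matrix(df, ()), y)
        return top, null

    def test_self_comparison(self, rng):
        top, null = self._pair(rng)
        assert compare_to_null(top, top) == (0.0, 1.0)

    def test_strong_effect_significant(self):
        rng = np.random.default_rng(20)
        top, null = self._pair(rng, beta=1.0, sigma=0.1)
        f, p = compare_to_null(top, null)
        assert p < 1e-6

    def test_f_equals_r2_identity(self, rng):
        top, null = self._pair(rng, beta=0.3, sigma=1.0)
        f, _ = compare_to_null(top, null)
        n, p = top.n, top.k_mean
        expect = (top.r2 / (1.0 - top.r2)) * ((n - p) / (p - 1))
        assert f == pytest.approx(expect, abs=1e-9)

    def test_non_nested_rejected(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20),
                           "z": rng.normal(size=20)})
        y = rng.normal(size=20)
        fx = fit_ols(build_design_matrix(df, ("x",)), y, terms=("x",))
        fz = fit_ols(build_design_matrix(df, ("z",)), y, terms=("z",))
        with pytest.raises(NestingError):
            compare_to_null(fx, fz)


class TestEnvelope:
    def test_outlier_fails(self, rng):
        res = rng.standard_normal(50)
        res[0] = 10.0 * res.std()
        out = envelope_normality_check(res, n_sim=300, seed=5)
        assert not out.passed
        assert out.fraction_inside < 1.0

    def test_tiny_sample_runs(self):
        out = envelope_normality_check([0.1, -0.2, 0.05], n_sim=200, seed=1)
        assert out.fraction_inside >= 0.0

    def test_small_nsim_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="isoniche.drivers"):
            envelope_normality_check([0.1, -0.2, 0.05, 0.3], n_sim=50,
                                     seed=1)
        assert any("n_sim" in r.message for r in caplog.records)

    def test_insufficient_residuals(self):
        with pytest.raises(InsufficientDataError):
            envelope_normality_check([0.1, 0.2])


class TestTransform:
    def test_identity_and_log(self):
        np.testing.assert_allclose(
            transform_response([1.0, math.e], "log"), [0.0, 1.0])
        np.testing.assert_allclose(
            transform_response([1.0, 2.0], "identity"), [1.0, 2.0])

    def test_zero_under_log_names_offender(self):
        with pytest.raises(DomainError, match="dev7"):
            transform_response([0.5, 0.0], "log", ids=["dev6", "dev7"])


class TestDriverSelection:
    def test_listwise_deletion_and_recovery(self, default_population):
        import isoniche as iso

        est = iso.estimate_si(default_population)
        sel = DriverSelection.from_dataframe(est, response="NSI")
        res = sel.fit(check_normality=False)
        assert sel.n_dropped == 1  # one individual lacks a mass record
        assert res.top.n == 70
        # aliased site+competition candidates leave the ranked set
        assert len(sel.aliased_candidates) == 12
        assert len(res.table.fits) == 28
        assert res.frame["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        sup = res.supported_frame()
        assert (sup["p_vs_null"].dropna() <= 1.0).all()

    def test_auto_log_refits_on_skewed_response(self, rng):
        n = 120
        df = pd.DataFrame({
            "individual_id": [f"i{j}" for j in range(n)],
            "mass": rng.normal(8.0, 1.5, n),
            "y": np.exp(rng.normal(0.0, 1.2, n)),  # strongly right-skewed
        })
        sel = DriverSelection.from_dataframe(
            df, response="y", terms=("mass",), interactions=())
        res = sel.fit(auto_log=True, n_sim=300, seed=11)
        assert res.top.response == "log(y)"
        assert res.envelope is not None
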