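import numpy as np
import pytest
from scipy import integrate, stats

from dairygap.frontier import (
    DistanceFunctionSpec,
    FrontierDesign,
    band_for_z,
    build_design,
    fit_frontier,
    gap_from_efficiency,
    inefficiency_z_test,
    mean_te,
    neg_log_likelihood,
    technical_efficiency_scores,
)
from dairygap.survey import FarmRecord, SurveyTable
from dairygap.synthetic import FrontierTruth, gen_frontier_population

SPEC_2X2 = DistanceFunctionSpec(("milk", "y2"), ("x1", "x2"), "milk")


def composed_density_quadrature(eps, sigma_v, sigma_u):
    """Numeric convolution of normal noise and half-normal inefficiency."""

    def integrand(u):
        return stats.norm.pdf(eps - u, scale=sigma_v) * 2 * stats.norm.pdf(u, scale=sigma_u)

    val, _ = integrate.quad(integrand, 0, np.inf)
    return val


def te_conditional_quadrature(eps, sigma_v, sigma_u):
    """E[exp(-u) | eps] by numeric integration over u >= 0."""

    def num(u):
        return np.exp(-u) * stats.norm.pdf(eps - u, scale=sigma_v) * stats.norm.pdf(u, scale=sigma_u)

    def den(u):
        return stats.norm.pdf(eps - u, scale=sigma_v) * stats.norm.pdf(u, scale=sigma_u)

    a, _ = integrate.quad(num, 0, np.inf)
    b, _ = integrate.quad(den, 0, np.inf)
    return a / b


def _design_from_eps(eps):
    eps = np.asarray(eps, dtype=float)
    X = np.zeros((eps.size, 1))
    return FrontierDesign(r=eps, X=X, farm_ids=[f"f{i}" for i in range(eps.size)],
                          spec=DistanceFunctionSpec(("milk",), ("x1",), "milk"))


class TestBuildDesign:
    def test_single_output_reduction(self):
        recs = [
            FarmRecord(f"f{i}", "Z", y, {"milk": y}, {"land": l, "herd": h})
            for i, (y, l, h) in enumerate([(2.0, 1.0, 3.0)] * 6)
        ]
        table = SurveyTable(recs, ["milk"], ["land", "herd"])
        spec = DistanceFunctionSpec(("milk",), ("land", "herd"), "milk")
        d = build_design(table, spec)
        assert d.X.shape == (6, 3)
        assert d.r == pytest.approx([-np.log(2.0)] * 6)

    def test_zero_output_dropped(self):
        recs = [
            FarmRecord(f"f{i}", "Z", 2.0, {"milk": 2.0}, {"land": 1.0}) for i in range(6)
        ]
        recs.append(FarmRecord("z", "Z", 0.0, {"milk": 0.0}, {"land": 1.0}))
        table = SurveyTable(recs, ["milk"], ["land"])
        d = build_design(table, DistanceFunctionSpec(("milk",), ("land",), "milk"))
        assert d.n == 6
        assert d.dropped == 1

    def test_hand_computed_row(self):
        recs = [
            FarmRecord(f"f{i}", "Z", 3.0, {"y1": 3.0, "y2": 6.0}, {"x1": 2.0, "x2": 4.0})
            for i in range(6)
        ]
        table = SurveyTable(recs, ["y1", "y2"], ["x1", "x2"])
        d = build_design(table, DistanceFunctionSpec(("y1", "y2"), ("x1", "x2"), "y2"))
        assert d.r[0] == pytest.approx(-np.log(6.0))
        assert d.X[0] == pytest.approx([1.0, np.log(2.0), np.log(4.0), np.log(3.0 / 6.0)])


class TestNegLogLikelihood:
    def test_gamma_zero_is_gaussian(self):
        rng = np.random.default_rng(1)
        eps = rng.normal(0, 0.7, size=20)
        d = _design_from_eps(eps)
        nll = neg_log_likelihood(np.array([0.0, 0.49, 0.0]), d)
        gauss = -stats.norm.logpdf(eps, scale=0.7).sum()
        assert nll == pytest.approx(gauss, abs=1e-10)

    @pytest.mark.parametrize("eps", [-1.2, -0.1, 0.4, 2.5])
    @pytest.mark.parametrize("sigma_u,sigma_v", [(0.5, 0.3), (1.0, 0.2), (0.4, 0.8)])
    def test_matches_quadrature_oracle(self, eps, sigma_u, sigma_v):
        s2 = sigma_v**2 + sigma_u**2
        gamma = sigma_u**2 / s2
        d = _design_from_eps([eps])
        nll = neg_log_likelihood(np.array([0.0, s2, gamma]), d)
        oracle = -np.log(composed_density_quadrature(eps, sigma_v, sigma_u))
        assert nll == pytest.approx(oracle, abs=1e-6)

    def test_scaling_identity(self):
        rng = np.random.default_rng(2)
        eps = rng.normal(0.3, 0.5, size=15)
        d1, c = _design_from_eps(eps), 3.0
        d2 = _design_from_eps(c * eps)
        for gamma in (0.0, 0.5, 0.9):
            n1 = neg_log_likelihood(np.array([0.0, 0.25, gamma]), d1)
            n2 = neg_log_likelihood(np.array([0.0, 0.25 * c**2, gamma]), d2)
            assert n2 - n1 == pytest.approx(eps.size * np.log(c), abs=1e-9)

    def test_invalid_params_rejected(self):
        d = _design_from_eps([0.1])
        with pytest.raises(ValueError):
            neg_log_likelihood(np.array([0.0, -1.0, 0.5]), d)
        with pytest.raises(ValueError):
            neg_log_likelihood(np.array([0.0, 1.0, 1.0]), d)


class TestFitFrontier:
    def test_null_model_matches_least_squares(self):
        # data generated with no inefficiency: gamma-hat small, loglik ~ OLS
        truth = FrontierTruth(1.0, (0.4, 0.3), (0.2,), sigma_v_sq=0.3, sigma_u_sq=0.0)
        table, _ = gen_frontier_population(400, truth, seed=11)
        fit = fit_frontier(table, SPEC_2X2)
        assert fit.gamma < 0.15
        d = fit.design
        b, res, *_ = np.linalg.lstsq(d.X, d.r, rcond=None)
        s2 = float(res[0]) / d.n
        ols_ll = float(np.sum(stats.norm.logpdf(d.r - d.X @ b, scale=np.sqrt(s2))))
        assert fit.loglik >= ols_ll - 0.5

    def test_duplicating_farms_doubles_loglik(self):
        truth = FrontierTruth(1.0, (0.4,), (), sigma_v_sq=0.1, sigma_u_sq=0.4)
        spec = DistanceFunctionSpec(("milk",), ("x1",), "milk")
        table, _ = gen_frontier_population(100, truth, seed=5)
        fit = fit_frontier(table, spec)
        doubled = SurveyTable(table.records + table.records, table.output_names, table.input_names)
        d2 = build_design(doubled, spec)
        params = np.concatenate([fit.coefs, [fit.sigma_sq, fit.gamma]])
        assert neg_log_likelihood(params, d2) == pytest.approx(-2 * fit.loglik, rel=1e-12)

    def test_mean_te_decreases_with_inefficiency_variance(self):
        # 3-point sweep in sigma_u^2: more inefficiency -> lower mean TE
        means = []
        for s_u2 in (0.05, 0.3, 0.8):
            truth = FrontierTruth(1.0, (0.4,), (), sigma_v_sq=0.1, sigma_u_sq=s_u2)
            table, _ = gen_frontier_population(400, truth, seed=23)
            fit = fit_frontier(table, DistanceFunctionSpec(("milk",), ("x1",), "milk"))
            means.append(mean_te(technical_efficiency_scores(fit)))
        assert means[0] > means[1] > means[2]
        assert all(0 < m <= 1 for m in means)


class TestEfficiencyScores:
    def test_gamma_zero_gives_unit_efficiency(self):
        truth = FrontierTruth(1.0, (0.4,), (), sigma_v_sq=0.2, sigma_u_sq=0.0)
        table, _ = gen_frontier_population(100, truth, seed=3)
        fit = fit_frontier(table, DistanceFunctionSpec(("milk",), ("x1",), "milk"))
        fit.gamma = 0.0  # exact null for the score formula
        scores = technical_efficiency_scores(fit)
        assert all(s.te == 1.0 for s in scores)

    @pytest.mark.parametrize("eps", [-0.8, 0.0, 0.9])
    def test_matches_conditional_expectation_quadrature(self, eps):
        sigma_v, sigma_u = 0.4, 0.6
        s2 = sigma_v**2 + sigma_u**2
        gamma = sigma_u**2 / s2
        d = _design_from_eps([eps])
        fit = _fit_stub(d, s2, gamma)
        te = technical_efficiency_scores(fit, d)[0].te
        assert te == pytest.approx(te_conditional_quadrature(eps, sigma_v, sigma_u), abs=1e-8)

    def test_te_strictly_decreasing_in_residual(self):
        d = _design_from_eps(np.linspace(-2, 2, 21))
        fit = _fit_stub(d, 0.5, 0.7)
        tes = [s.te for s in technical_efficiency_scores(fit, d)]
        assert all(a > b for a, b in zip(tes, tes[1:]))
        assert all(0 < t <= 1 for t in tes)

    def test_jlms_variant_close_but_distinct(self):
        d = _design_from_eps([0.5])
        fit = _fit_stub(d, 0.5, 0.7)
        bc = technical_efficiency_scores(fit, d, estimator="bc")[0].te
        jlms = technical_efficiency_scores(fit, d, estimator="jlms")[0].te
        assert bc != jlms
        assert abs(bc - jlms) < 0.05


def _fit_stub(design, sigma_sq, gamma):
    from dairygap.frontier import FrontierFit

    return FrontierFit(
        alpha0=0.0, beta=np.zeros(0), gamma_out=np.zeros(0), sigma_sq=sigma_sq,
        gamma=gamma, loglik=0.0, std_errors={}, converged=True, n=design.n, design=design,
    )


class TestInefficiencyTest:
    def test_zero_gamma_null(self):
        d = _design_from_eps([0.1, 0.2, -0.1])
        fit = _fit_stub(d, 0.5, 0.0)
        fit.std_errors = {"gamma": 0.2}
        t = inefficiency_z_test(fit)
        assert t.z_value == 0.0
        assert t.p_value == pytest.approx(0.5)
        assert t.significant_at is None

    @pytest.mark.parametrize(
        "z,band", [(2.28, 0.05), (3.65, 0.001), (2.27, 0.05), (3.54, 0.001), (1.30, 0.1)]
    )
    def test_band_mapping(self, z, band):
        assert band_for_z(z) == band

    def test_haryana_z_below_ten_percent_band(self):
        # one-sided p for z = 1.13 is ~0.129: no band under this mapping
        assert band_for_z(1.13) is None

    def test_degenerate_se_raises(self):
        d = _design_from_eps([0.1, 0.2, -0.1])
        fit = _fit_stub(d, 0.5, 0.5)
        fit.std_errors = {"gamma": 0.0}
        with pytest.raises(ZeroDivisionError):
            inefficiency_z_test(fit)


class TestGapFromEfficiency:
    @pytest.mark.parametrize("te,pct", [(1.0, 0), (0.69, 45), (0.5, 100)])
    def test_known_values(self, te, pct):
        assert round(gap_from_efficiency(te)) == pct

    def test_domain(self):
        with pytest.raises(ValueError):
            gap_from_efficiency(0.0)
        with pytest.raises(ValueError):
            gap_from_efficiency(1.2)
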