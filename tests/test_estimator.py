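import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import quad
from scipy.special import gammaln

from phasekit import (
    CouplingTerm,
    OscillatorSpec,
    PhaseModel,
    PhaseSeries,
    PriorSpec,
    SimConfig,
    build_problem,
    coupling_power,
    estimate_model,
    fit_posterior,
    log_evidence,
    select_orders,
    simulate,
)
from phasekit.estimator import RegressionProblem


def _toy_problem(n=5, k=2, seed=42, noise=0.3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(k - 1)])
    w_true = np.arange(1, k + 1) * 0.5
    y = X @ w_true + noise * rng.standard_normal(n)
    labels = ["omega_hat"] + [f"f{i}" for i in range(1, k)]
    return RegressionProblem(y=y, X=X, dt=0.01, labels=labels)


class TestBuildProblem:
    @staticmethod
    def _phases(n=500, dt=0.01):
        rng = np.random.default_rng(1)
        return [
            PhaseSeries(np.cumsum(rng.uniform(0.005, 0.03, n)), dt, label=f"p{i}")
            for i in range(3)
        ]

    def test_no_edges_gives_lone_intercept(self):
        prob = build_problem(self._phases(), 0, [])
        assert prob.X.shape[1] == 1
        assert prob.labels == ["omega_hat"]

    def test_column_count_is_one_plus_two_m(self):
        prob = build_problem(self._phases(), 0, [(1, 1, 1, 1)])
        assert prob.X.shape[1] == 3

    def test_fast_oscillator_design_of_benchmark(self):
        # target driven by two edges with M = 1 and M = 2: 1 + 2 + 4 columns
        prob = build_problem(self._phases(), 1, [(0, 2, 1, 1), (2, 2, 1, 2)])
        assert prob.X.shape[1] == 7

    def test_misaligned_series_rejected(self):
        phases = self._phases()
        phases[1] = PhaseSeries(phases[1].phi[:-1], phases[1].dt)
        with pytest.raises(ValueError, match="aligned"):
            build_problem(phases, 0, [(1, 1, 1, 1)])


class TestFitPosterior:
    def test_no_data_returns_prior(self):
        prob = RegressionProblem(
            y=np.empty(0), X=np.empty((0, 2)), dt=0.01, labels=["omega_hat", "f"]
        )
        prior = PriorSpec().state(2)
        post = fit_posterior(prob, prior)
        assert np.allclose(post.chi, prior.chi)
        assert np.allclose(post.Sigma, prior.Sigma)
        assert post.alpha == prior.alpha
        assert post.beta == prior.beta

    def test_flat_prior_matches_ols_oracle(self):
        prob = _toy_problem()
        post = fit_posterior(prob, PriorSpec(scale=1e6).state(2))
        ols = np.linalg.lstsq(prob.X, prob.y, rcond=None)[0]
        assert np.allclose(post.chi, ols, rtol=1e-4)

    def test_collinear_columns_named_in_error(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(6)
        X = np.column_stack([np.ones(6), x, x])
        prob = RegressionProblem(
            y=rng.standard_normal(6), X=X, dt=0.01,
            labels=["omega_hat", "dup1", "dup2"],
        )
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_posterior(prob, PriorSpec(scale=1e14).state(3))

    def test_recovers_sine_coupling_on_benchmark(self, three_osc):
        phases, truth = three_osc
        prob = build_problem(phases, 0, [(2, 1, 1, 1)])
        post = fit_posterior(prob)
        sd = post.coef_sd()
        assert abs(post.chi[0] - 0.9) < 3 * sd[0]
        assert abs(post.chi[2] - 0.1) < 3 * sd[2]  # sin coefficient of edge 3->1
        # noise strength back-converted to sqrt(2D) = 0.1
        D = post.noise_strength(prob.dt)
        assert np.sqrt(2 * D) == pytest.approx(0.1, rel=0.05)


class TestLogEvidence:
    def test_independent_of_evaluation_point(self):
        prob = _toy_problem()
        prior = PriorSpec(scale=4.0, alpha=2.0, beta=1.0).state(2)
        post = fit_posterior(prob, prior)
        ref = log_evidence(prob, prior, post)
        rng = np.random.default_rng(0)
        for _ in range(3):
            at = (rng.standard_normal(2), float(rng.uniform(0.05, 2.0)))
            assert log_evidence(prob, prior, post, at=at) == pytest.approx(
                ref, abs=1e-8
            )

    def test_inconsistent_triple_rejected(self):
        prob = _toy_problem()
        prior = PriorSpec().state(2)
        post = fit_posterior(prob, prior)
        post.alpha += 1.0
        with pytest.raises(ValueError, match="inconsistent"):
            log_evidence(prob, prior, post)

    def test_matches_numerical_marginalization(self):
        # 6-row, 2-coefficient toy: evidence vs 2-D Gauss-Hermite over the
        # coefficients plus 1-D quadrature over the noise variance
        prob = _toy_problem(n=6)
        spec = PriorSpec(mean=0.0, scale=4.0, alpha=2.0, beta=1.0)
        prior = spec.state(2)
        post = fit_posterior(prob, prior)
        ref = log_evidence(prob, prior, post)

        nodes, weights = hermegauss(160)
        W0, W1 = np.meshgrid(nodes, nodes)
        WW = np.outer(weights, weights)
        y, X, n = prob.y, prob.X, prob.n_rows

        def marginal_over_coeffs(sigma2):
            sd = np.sqrt(sigma2 * spec.scale)
            w0 = spec.mean + sd * W0
            w1 = spec.mean + sd * W1
            r = (
                y[:, None, None]
                - X[:, 0, None, None] * w0[None]
                - X[:, 1, None, None] * w1[None]
            )
            lik = np.exp(-0.5 * np.sum(r**2, axis=0) / sigma2)
            lik /= (2 * np.pi * sigma2) ** (n / 2)
            return np.sum(WW * lik) / (2 * np.pi)

        def integrand(log_s2):
            s2 = np.exp(log_s2)
            log_ig = (
                spec.alpha * np.log(spec.beta)
                - gammaln(spec.alpha)
                - (spec.alpha + 1) * log_s2
                - spec.beta / s2
            )
            return marginal_over_coeffs(s2) * np.exp(log_ig) * s2

        val, _ = quad(integrand, np.log(1e-5), np.log(200), limit=300)
        assert ref == pytest.approx(np.log(val), abs=1e-3)

    def test_occam_prefers_simpler_model_on_noise(self):
        # coupling-free noise data: the M=0 model should win over M=3
        rng = np.random.default_rng(123)
        wins = 0
        n = 200
        for _ in range(100):
            dt = 0.01
            phi_t = np.cumsum(1.0 * dt + 0.1 * np.sqrt(dt) * rng.standard_normal(n))
            phi_s = np.cumsum(1.3 * dt + 0.1 * np.sqrt(dt) * rng.standard_normal(n))
            phases = [PhaseSeries(phi_t, dt), PhaseSeries(phi_s, dt)]
            result = select_orders(phases, 0, [(1, 1, 1)], m_max=3)
            ev = dict(zip(result.candidates, result.log_evidences))
            if ev[(0,)] >= ev[(3,)]:
                wins += 1
        assert wins >= 95


class TestSelectOrders:
    def test_pure_noise_selects_zero(self):
        rng = np.random.default_rng(9)
        dt = 0.01
        phases = [
            PhaseSeries(np.cumsum(w * dt + 0.05 * rng.standard_normal(3000)), dt)
            for w in (1.0, 1.4)
        ]
        result = select_orders(phases, 0, [(1, 1, 1)], m_max=3)
        assert result.selected == (0,)

    def test_single_sine_coupling_selects_m_equal_one(self):
        # one sine term of amplitude 0.1 against D = 0.005, long records
        model = PhaseModel(
            [
                OscillatorSpec(1.0, 0.005, [CouplingTerm(0, 1, 1, 1, (0.0,), (0.1,))]),
                OscillatorSpec(1.25, 0.005, []),
            ]
        )
        hits = 0
        for seed in range(20):
            cfg = SimConfig(dt=0.01, n_steps=100_000, seed=seed, burn_in=0)
            phases = simulate(model, cfg)
            result = select_orders(phases, 0, [(1, 1, 1)], m_max=3)
            hits += result.selected == (1,)
        assert hits >= 19

    def test_coordinate_ascent_used_beyond_two_edges(self, three_osc):
        phases, _ = three_osc
        result = select_orders(
            phases, 1, [(0, 2, 1), (2, 2, 1), (0, 1, 2)], m_max=2
        )
        assert not result.exhaustive
        assert result.selected[:2] == (1, 2)

    def test_evidence_invariant_to_edge_listing_order(self, three_osc):
        phases, _ = three_osc
        r12 = select_orders(phases, 1, [(0, 2, 1), (2, 2, 1)], m_max=2)
        r21 = select_orders(phases, 1, [(2, 2, 1), (0, 2, 1)], m_max=2)
        ev12 = dict(zip(r12.candidates, r12.log_evidences))
        ev21 = dict(zip(r21.candidates, r21.log_evidences))
        for (m1, m2), v in ev12.items():
            assert ev21[(m2, m1)] == pytest.approx(v, abs=1e-8)


class TestEstimateModel:
    def test_independent_oscillators_yield_empty_couplings(self):
        rng = np.random.default_rng(21)
        dt = 0.01
        phases = [
            PhaseSeries(
                np.cumsum(w * dt + 0.1 * np.sqrt(dt) * rng.standard_normal(20_000)),
                dt,
            )
            for w in (1.0, 1.37)
        ]
        model, _ = estimate_model(
            phases, [(0, 1, 1, 1), (1, 0, 1, 1)], m_max=3
        )
        for osc in model.oscillators:
            assert all(coupling_power(t) == 0.0 for t in osc.couplings)

    def test_full_recovery_on_benchmark(self, three_osc):
        phases, truth = three_osc
        edges = [
            (0, 2, 1, 1), (2, 0, 1, 1), (1, 0, 2, 1),
            (1, 2, 2, 1), (0, 1, 1, 2), (2, 1, 1, 2),
        ]
        est, details = estimate_model(phases, edges, m_max=3)
        # every generating coefficient within 3 posterior sd
        for i, osc in enumerate(truth.oscillators):
            post = details[i]["posterior"]
            sd = post.coef_sd()
            labels = details[i]["labels"]
            est_terms = {t.source: t for t in est.oscillators[i].couplings}
            assert abs(est.oscillators[i].omega_hat - osc.omega_hat) < 3 * sd[0]
            for t in osc.couplings:
                got = est_terms[t.source]
                assert got.order >= t.order
                for m in range(1, t.order + 1):
                    for kind, tv in (("cos", t.a[m - 1]), ("sin", t.b[m - 1])):
                        col = labels.index(
                            f"src{t.source}[{t.p_i}:{t.p_j}] {kind}{m}"
                        )
                        gv = got.a[m - 1] if kind == "cos" else got.b[m - 1]
                        assert abs(gv - tv) < 3 * sd[col]
        # absent couplings carry <10% of the weakest true coupling's power
        weakest = np.pi * 0.05**2
        truth_edges = {
            (t.target, t.source) for o in truth.oscillators for t in o.couplings
        }
        for i, osc in enumerate(est.oscillators):
            for t in osc.couplings:
                if (i, t.source) not in truth_edges:
                    assert coupling_power(t) < 0.1 * weakest
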