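import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from pfbt import (
    BetaInfeasibleError,
    FitOptions,
    ModelParams,
    ModelSpec,
    ResponseSet,
    beta_shapes_from_mode_variance,
    fit_map,
    laplace_log_evidence,
    log_model_evidence,
    response_loglik,
    simulate_responses,
    simulate_trajectory,
)
from pfbt.inference import TRANSFORMS, beta_mode_loglik
from pfbt.task_design import TaskSequence


class TestTransforms:
    @settings(derandomize=True, max_examples=10)
    @given(seed=st.integers(0, 1000))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        for tr in TRANSFORMS.values():
            x = rng.normal(0, 2, size=10)
            assert np.allclose(tr.inverse(tr.forward(x)), x, atol=1e-10)
            y = tr.forward(x)
            assert np.all((y > tr.lo) & (y < tr.hi))

    def test_forward_is_monotone(self):
        x = np.linspace(-6, 6, 200)
        for tr in TRANSFORMS.values():
            assert np.all(np.diff(tr.forward(x)) > 0)

    def test_zero_maps_to_centres(self):
        assert TRANSFORMS["alpha"].forward(0.0) == pytest.approx(0.5)
        assert TRANSFORMS["tau"].forward(0.0) == pytest.approx((0.001 + 0.08) / 2)
        assert TRANSFORMS["lambda_self"].forward(0.0) == pytest.approx(0.0)


class TestBetaShapes:
    def test_symmetric_closed_form(self):
        # for mode 0.5, a = b and variance = 1 / (4 (2a + 1))
        a, b = beta_shapes_from_mode_variance(0.5, 0.04)
        assert a == pytest.approx(2.625, abs=1e-8)
        assert b == pytest.approx(2.625, abs=1e-8)
        a, b = beta_shapes_from_mode_variance(0.5, 0.08)
        assert a == pytest.approx(1.0625, abs=1e-8)

    def test_constraints_satisfied_on_grid(self):
        modes = np.linspace(0.001, 0.999, 41)
        for v in (0.001, 0.005, 0.02, 0.05, 0.08):
            a, b = beta_shapes_from_mode_variance(modes, v)
            assert np.all(a >= 1.0 - 1e-12) and np.all(b >= 1.0 - 1e-12)
            got_mode = (a - 1) / (a + b - 2)
            got_var = a * b / ((a + b) ** 2 * (a + b + 1))
            assert np.allclose(got_mode, modes, atol=1e-8)
            assert np.allclose(got_var, v, atol=1e-8)

    def test_density_maximum_matches_requested_mode(self):
        # grid-search oracle: numerically maximise the density
        a, b = beta_shapes_from_mode_variance(0.7, 0.02)
        x = np.linspace(1e-6, 1 - 1e-6, 2_000_001)
        logpdf = (a - 1) * np.log(x) + (b - 1) * np.log1p(-x)
        assert x[np.argmax(logpdf)] == pytest.approx(0.7, abs=1e-4)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(BetaInfeasibleError):
            beta_shapes_from_mode_variance(0.5, 1 / 12 + 1e-6)
        with pytest.raises(BetaInfeasibleError):
            beta_shapes_from_mode_variance(0.5, 0.0)


class TestResponseLoglik:
    def test_response_at_mode_is_density_argmax(self):
        mode, tau = 0.6, 0.02
        ll_at_mode = beta_mode_loglik(np.array([mode]), np.array([mode]), tau)
        for x in np.linspace(0.01, 0.99, 50):
            assert beta_mode_loglik(np.array([x]), np.array([mode]), tau) <= ll_at_mode + 1e-12

    def test_near_uniform_at_max_noise(self):
        # tau at its upper bound: log density close to the uniform's 0
        x = np.linspace(0.05, 0.95, 19)
        ll = beta_mode_loglik(x, np.full_like(x, 0.5), 0.08)
        assert abs(ll) / len(x) < 0.05

    def test_matches_quadrature_normalised_density(self):
        # independent oracle: normalise the unnormalised density numerically
        beliefs = np.array([0.3, 0.55, 0.8])
        responses = np.array([0.25, 0.6, 0.7])
        tau = 0.04
        total = 0.0
        for r, m in zip(responses, beliefs):
            a, b = beta_shapes_from_mode_variance(m, tau)
            a, b = float(a[0]), float(b[0])
            Z, _ = integrate.quad(lambda x: x ** (a - 1) * (1 - x) ** (b - 1), 0, 1)
            total += (a - 1) * np.log(r) + (b - 1) * np.log(1 - r) - np.log(Z)
        assert beta_mode_loglik(responses, beliefs, tau) == pytest.approx(total, abs=1e-8)

    def test_invariant_to_probe_permutation(self, low_noise_participant):
        seq, params, traj, responses = low_noise_participant
        ll = response_loglik(responses, traj, params, seq)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(responses))
        # permute responses together with the probe modes they belong to
        modes = traj.beliefs_at_probes(seq)
        ll_perm = beta_mode_loglik(responses.response[perm], modes[perm], params.tau)
        assert ll_perm == pytest.approx(ll, abs=1e-10)

    def test_misaligned_lengths_rejected(self, low_noise_participant):
        seq, params, traj, responses = low_noise_participant
        short = ResponseSet(
            responses.probe_index[:-1], responses.probe_agent[:-1], responses.response[:-1]
        )
        with pytest.raises(ValueError):
            response_loglik(short, traj, params, seq)


class TestFitMap:
    def test_no_data_returns_prior_mean(self, short_sequence):
        empty_seq = TaskSequence(short_sequence.sampling_trials, (), short_sequence.config)
        empty = ResponseSet(np.array([]), np.array([]), np.array([]))
        fit = fit_map(empty_seq, empty, ModelSpec(), opts=FitOptions(n_restarts=2, seed=0))
        assert np.allclose(fit.map_unconstrained, 0.0, atol=1e-4)
        assert fit.map_params.alpha == pytest.approx(0.5, abs=1e-3)
        assert fit.map_params.lambda_self == pytest.approx(0.0, abs=1e-3)

    def test_zero_leakage_spec_fixes_lambdas(self, low_noise_participant):
        seq, _, _, responses = low_noise_participant
        fit = fit_map(seq, responses, ModelSpec("zero", "shared"),
                      opts=FitOptions(n_restarts=2, seed=0))
        assert fit.map_params.lambda_self == 0.0
        assert fit.map_params.lambda_other == 0.0
        assert fit.n_free_params == 3

    def test_recovers_leakage_at_low_noise(self, default_sequence):
        gen = ModelParams(0.1, 0.02, 0.002, 0.5, 0.0)
        traj = simulate_trajectory(default_sequence, gen)
        responses = simulate_responses(traj, default_sequence, gen, seed=3)
        fit = fit_map(default_sequence, responses, ModelSpec(),
                      opts=FitOptions(n_restarts=4, seed=0))
        assert fit.map_params.lambda_self == pytest.approx(0.5, abs=0.15)
        assert fit.converged

    def test_deterministic_given_seed(self, low_noise_participant):
        seq, _, _, responses = low_noise_participant
        opts = FitOptions(n_restarts=3, seed=5)
        f1 = fit_map(seq, responses, ModelSpec(), opts=opts)
        f2 = fit_map(seq, responses, ModelSpec(), opts=opts)
        assert np.array_equal(f1.map_unconstrained, f2.map_unconstrained)


class TestModelEvidence:
    def test_laplace_exact_for_gaussian_toy(self):
        # prior N(0, 1), likelihood N(y | x, s2): the marginal is N(y; 0, 1 + s2)
        y, s2 = 0.7, 0.3
        post_prec = 1.0 + 1.0 / s2
        x_map = (y / s2) / post_prec
        log_post = (
            -0.5 * x_map**2 - 0.5 * np.log(2 * np.pi)
            - 0.5 * (y - x_map) ** 2 / s2 - 0.5 * np.log(2 * np.pi * s2)
        )
        log_ev = laplace_log_evidence(log_post, np.array([[post_prec]]))
        closed_form = -0.5 * y**2 / (1 + s2) - 0.5 * np.log(2 * np.pi * (1 + s2))
        assert log_ev == pytest.approx(closed_form, abs=1e-6)

    def test_extra_parameter_is_penalised(self, default_sequence):
        # data from the agent-specific model: the richer variant cannot win
        gen = ModelParams(0.15, 0.03, 0.01, 0.0, 0.0)
        traj = simulate_trajectory(default_sequence, gen)
        responses = simulate_responses(traj, default_sequence, gen, seed=21)
        opts = FitOptions(n_restarts=3, seed=0)
        simple = fit_map(default_sequence, responses, ModelSpec("zero", "shared"), opts=opts)
        rich = fit_map(default_sequence, responses, ModelSpec("unrestricted", "shared"), opts=opts)
        assert rich.log_evidence <= simple.log_evidence + 1e-6

    def test_contradicted_datum_lowers_evidence(self, low_noise_participant):
        seq, _, _, responses = low_noise_participant
        opts = FitOptions(n_restarts=3, seed=0)
        base = fit_map(seq, responses, ModelSpec(), opts=opts)
        # duplicate the first probe with a contradictory report
        p0 = seq.probe_trials[0]
        dup = type(p0)(index=p0.index, after_sampling_index=p0.after_sampling_index,
                       probe_agent=p0.probe_agent)
        seq2 = TaskSequence(seq.sampling_trials, (dup,) + seq.probe_trials, seq.config)
        contradiction = 1.0 - responses.response[0]
        resp2 = ResponseSet(
            np.concatenate([[p0.index], responses.probe_index]),
            np.concatenate([[p0.probe_agent], responses.probe_agent]),
            np.concatenate([[contradiction], responses.response]),
        )
        worse = fit_map(seq2, resp2, ModelSpec(), opts=opts)
        assert worse.log_evidence < base.log_evidence

    def test_dim_mismatch_rejected(self, low_noise_participant):
        seq, _, _, responses = low_noise_participant
        fit = fit_map(seq, responses, ModelSpec("zero", "shared"),
                      opts=FitOptions(n_restarts=2, seed=0))
        assert log_model_evidence(fit, dim=3) == fit.log_evidence
        with pytest.raises(ValueError):
            log_model_evidence(fit, dim=5)
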