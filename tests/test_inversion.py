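"""Solver tests: regularization schedules, domain projection, the Tikhonov
objective, the analytic Jacobian against finite differences, and the
regularized Gauss-Newton step against an augmented least-squares oracle."""

import numpy as np
import pytest

from petkin.inversion import (
    IRGNMConfig,
    RegularizationSchedule,
    build_weights,
    irgnm_step,
    jacobian,
    project_domain,
    run_irgnm,
    schedule_value,
    tikhonov_objective,
)
from petkin.model import ParameterVector, forward_operator


def _config(**kw):
    base = dict(
        kinetic_schedule=RegularizationSchedule(10.0, 5.0),
        input_schedule=RegularizationSchedule(600.0, 7.0),
        fraction_schedule=RegularizationSchedule(200.0, 7.0),
        tau=9.2,
        epsilon=1e-3,
        max_iter=50,
        mode="full",
    )
    base.update(kw)
    return IRGNMConfig(**base)


def _random_domain_point(rng, x_truth):
    x0 = x_truth.pack() * (1 + 0.2 * rng.standard_normal(23))
    x0[8] = abs(x0[8])
    x0[9], x0[10] = -abs(x0[9]), -abs(x0[10])
    x0[11:] = np.maximum(np.abs(x0[11:]), 1e-3)
    return ParameterVector.unpack(x0, 4, 4)


class TestSchedules:
    def test_printed_values(self):
        s = RegularizationSchedule(10.0, 5.0)
        assert schedule_value(s, 0) == 10.0
        assert schedule_value(s, 5) == pytest.approx(5.0)

    def test_constant_decay_ratio(self):
        s = RegularizationSchedule(600.0, 7.0)
        ratios = [schedule_value(s, i) / schedule_value(s, i + 1) for i in range(20)]
        np.testing.assert_allclose(ratios, 2.0 ** (1.0 / 7.0))
        assert all(r > 1 for r in ratios)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RegularizationSchedule(0.0, 5.0)
        with pytest.raises(ValueError):
            IRGNMConfig(
                kinetic_schedule=RegularizationSchedule(1, 1),
                input_schedule=RegularizationSchedule(1, 1),
                fraction_schedule=RegularizationSchedule(1, 1),
                tau=0.9,
            )


class TestProjection:
    def test_interior_point_unchanged(self, ground_truth):
        x = ground_truth.parameter_vector().pack()
        np.testing.assert_array_equal(project_domain(x, 4, 4, _config()), x)

    def test_kinetic_rates_clipped_to_epsilon(self, ground_truth):
        x = ground_truth.parameter_vector().pack()
        x[12] = -0.5  # frontal k2
        out = project_domain(x, 4, 4, _config())
        assert out[12] == 1e-3

    def test_fraction_block_clipped_to_admissible_signs(self, ground_truth):
        x = ground_truth.parameter_vector().pack()
        x[8], x[9] = -0.1, 0.2  # A and xi1 out of range
        out = project_domain(x, 4, 4, _config())
        assert out[8] == 0.0 and out[9] == 0.0

    def test_optional_mu_bound_and_origin_pin(self, ground_truth):
        cfg = _config(mu_upper_bound=0.01, pin_cp_origin=True)
        x = ground_truth.parameter_vector().pack()
        x[7] = 0.5  # a positive exponent
        out = project_domain(x, 4, 4, cfg)
        assert np.all(out[4:8] <= -0.01)
        assert out[3] == pytest.approx(-np.sum(out[:3]))


class TestObjective:
    def test_zero_at_truth(self, ground_truth, schedule, clean_data):
        data, aux = clean_data
        x = ground_truth.parameter_vector()
        assert tikhonov_objective(
            x, aux["y"], 1.0, x, schedule, data.CWB_samples
        ) == pytest.approx(0.0, abs=1e-20)

    def test_alpha_zero_is_pure_misfit(self, ground_truth, schedule,
                                       clean_data, rng):
        data, aux = clean_data
        x = _random_domain_point(rng, ground_truth.parameter_vector())
        r = forward_operator(x, schedule, data.CWB_samples) - aux["y"]
        assert tikhonov_objective(
            x, aux["y"], 0.0, ground_truth.parameter_vector(), schedule,
            data.CWB_samples
        ) == pytest.approx(r @ r)

    def test_penalty_vanishes_at_prior(self, ground_truth, schedule,
                                       clean_data, rng):
        data, aux = clean_data
        x = _random_domain_point(rng, ground_truth.parameter_vector())
        at_alpha0 = tikhonov_objective(x, aux["y"], 0.0, x, schedule,
                                       data.CWB_samples)
        at_alpha1 = tikhonov_objective(x, aux["y"], 1.0, x, schedule,
                                       data.CWB_samples)
        assert at_alpha1 == pytest.approx(at_alpha0)


class TestJacobian:
    def test_fraction_block_zero_in_tissue_rows(self, ground_truth, schedule,
                                                clean_data):
        data, _ = clean_data
        J = jacobian(ground_truth.parameter_vector(), schedule,
                     data.CWB_samples)
        np.testing.assert_array_equal(J[:100, 8:11], 0.0)

    def test_K1_column_is_homogeneity_ratio(self, ground_truth, schedule,
                                            clean_data):
        data, _ = clean_data
        x = ground_truth.parameter_vector()
        J = jacobian(x, schedule, data.CWB_samples)
        for i, K in enumerate(x.regions):
            rows = slice(25 * i, 25 * (i + 1))
            np.testing.assert_allclose(
                J[rows, 11 + 3 * i], data.CT_matrix[i] / K.K1, rtol=1e-12
            )

    def test_matches_finite_differences(self, ground_truth, schedule,
                                        clean_data, rng):
        data, _ = clean_data
        x_truth = ground_truth.parameter_vector()
        for _ in range(10):
            x = _random_domain_point(rng, x_truth)
            J = jacobian(x, schedule, data.CWB_samples)
            x0 = x.pack()
            Jfd = np.empty_like(J)
            for j in range(23):
                h = 1e-6 * max(1.0, abs(x0[j]))
                xp, xm = x0.copy(), x0.copy()
                xp[j] += h
                xm[j] -= h
                Jfd[:, j] = (
                    forward_operator(ParameterVector.unpack(xp, 4, 4), schedule,
                                     data.CWB_samples)
                    - forward_operator(ParameterVector.unpack(xm, 4, 4),
                                       schedule, data.CWB_samples)
                ) / (2 * h)
            denom = np.maximum(np.abs(Jfd), 1e-6 * np.abs(Jfd).max())
            assert np.max(np.abs(J - Jfd) / denom) < 1e-5


class TestIRGNMStep:
    def test_fixed_point_at_consistent_data(self, ground_truth, schedule,
                                            clean_data):
        data, aux = clean_data
        x = ground_truth.parameter_vector()
        w = np.full(23, 2.0)
        out = irgnm_step(x, x, aux["y"], w, schedule, data.CWB_samples,
                         _config())
        np.testing.assert_allclose(out.pack(), x.pack(), atol=1e-10)

    def test_large_regularization_pulls_to_prior(self, ground_truth, schedule,
                                                 clean_data, rng):
        data, aux = clean_data
        x_truth = ground_truth.parameter_vector()
        x_k = _random_domain_point(rng, x_truth)
        w = np.full(23, 1e12)
        out = irgnm_step(x_k, x_truth, aux["y"], w, schedule,
                         data.CWB_samples, _config())
        np.testing.assert_allclose(out.pack(), x_truth.pack(), rtol=1e-4)

    def test_matches_augmented_least_squares_oracle(self, ground_truth,
                                                    schedule, clean_data, rng):
        data, aux = clean_data
        x_truth = ground_truth.parameter_vector()
        cfg = _config()
        for _ in range(10):
            x_k = _random_domain_point(rng, x_truth)
            x_0 = _random_domain_point(rng, x_truth)
            w = np.exp(rng.uniform(-1, 4, size=23))
            out = irgnm_step(x_k, x_0, aux["y"], w, schedule,
                             data.CWB_samples, cfg)
            # oracle: min ||J d - r||^2 + sum w (d - (x0-xk))^2 via lstsq on
            # the augmented system, then the same projection
            J = jacobian(x_k, schedule, data.CWB_samples)
            r = aux["y"] - forward_operator(x_k, schedule, data.CWB_samples)
            A = np.vstack([J, np.diag(np.sqrt(w))])
            b = np.concatenate([r, np.sqrt(w) * (x_0.pack() - x_k.pack())])
            d = np.linalg.lstsq(A, b, rcond=None)[0]
            expected = project_domain(x_k.pack() + d, 4, 4, cfg)
            np.testing.assert_allclose(
                out.pack(), expected, rtol=1e-8, atol=1e-12
            )

    def test_nonpositive_weights_rejected(self, ground_truth, schedule,
                                          clean_data):
        data, aux = clean_data
        x = ground_truth.parameter_vector()
        with pytest.raises(ValueError):
            irgnm_step(x, x, aux["y"], np.zeros(23), schedule,
                       data.CWB_samples, _config())


class TestRunIRGNM:
    def test_zero_iteration_cap_returns_initialization(self, ground_truth,
                                                       schedule, clean_data,
                                                       rng):
        data, aux = clean_data
        x0 = _random_domain_point(rng, ground_truth.parameter_vector())
        fit = run_irgnm(x0, aux["y"], 0.0, _config(max_iter=0), schedule,
                        data.CWB_samples)
        assert len(fit.iterates) == 1
        np.testing.assert_array_equal(fit.iterates[0], x0.pack())

    def test_discrepancy_guard_contract(self, ground_truth, schedule,
                                        clean_data, rng):
        data, aux = clean_data
        delta_y = 0.05
        y_noisy = aux["y"] + delta_y * rng.standard_normal(125) / np.sqrt(125)
        x0 = _random_domain_point(rng, ground_truth.parameter_vector())
        cfg = _config(max_iter=100, tau=5.0)
        fit = run_irgnm(x0, y_noisy, delta_y, cfg, schedule, data.CWB_samples)
        if fit.stopped_by == "discrepancy":
            assert fit.residual_norms[fit.stop_iteration] <= cfg.tau * delta_y
            assert all(
                rn > cfg.tau * delta_y
                for rn in fit.residual_norms[: fit.stop_iteration]
            )

    def test_iterates_stay_in_domain(self, ground_truth, schedule, clean_data,
                                     rng):
        data, aux = clean_data
        cfg = _config(max_iter=30)
        x0 = _random_domain_point(rng, ground_truth.parameter_vector())
        fit = run_irgnm(x0, aux["y"], 0.0, cfg, schedule, data.CWB_samples)
        for xk in fit.iterates:
            assert np.all(xk[11:] >= cfg.epsilon)
            assert xk[8] >= 0 and xk[9] <= 0 and xk[10] <= 0

    def test_reduced_mode_freezes_fraction(self, ground_truth, schedule,
                                           clean_data, rng):
        data, aux = clean_data
        cfg = _config(max_iter=20, mode="reduced", fraction_schedule=None)
        x0 = _random_domain_point(rng, ground_truth.parameter_vector())
        fit = run_irgnm(x0, aux["y"], 0.0, cfg, schedule, data.CWB_samples)
        for xk in fit.iterates:
            np.testing.assert_array_equal(xk[8:11], x0.pack()[8:11])

    def test_block_weights_layout(self):
        cfg = _config()
        w = build_weights(4, 4, cfg, 0)
        assert np.all(w[:8] == 600.0)
        assert np.all(w[8:11] == 200.0)
        assert np.all(w[11:] == 10.0)
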