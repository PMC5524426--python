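"""Hybrid engine tests: spec construction, advancement, filter, forecast."""

import numpy as np
import pytest

from hybridcast.models import (generate_training_data, hindmarsh_rose_model,
                               integrate, lorenz63_model, lpa_model, lpa_step,
                               random_network, rk4_step)
from hybridcast.takens import (EmbeddingConfig, build_delay_library,
                               local_constant_predict)
from hybridcast.hybrid import (HybridLayout, default_hybrid_config,
                               hybrid_advance, hybrid_advance_points,
                               hybrid_forecast, make_hybrid_spec,
                               run_hybrid_ukf)
from hybridcast.ukf import default_ukf_config, parametric_forecast, run_joint_ukf

EMB = EmbeddingConfig(d=9, tau=1, kappa=20)


class TestSpecConstruction:
    def test_lorenz_replace_y_drops_rho(self, lorenz):
        spec = make_hybrid_spec(lorenz, ["y"], EMB)
        assert spec.mechanistic_vars == ("x", "z")
        assert spec.nonparametric_vars == ("y",)
        assert spec.retained_params == ("sigma", "beta")
        assert spec.dropped_vars == ()

    def test_lorenz_replace_y_and_z_keeps_only_sigma(self, lorenz):
        spec = make_hybrid_spec(lorenz, ["y", "z"], EMB)
        assert spec.mechanistic_vars == ("x",)
        assert spec.retained_params == ("sigma",)

    def test_empty_replacement_is_degenerate_parametric(self, lorenz):
        spec = make_hybrid_spec(lorenz, [], EMB)
        assert spec.nonparametric_vars == ()
        assert set(spec.retained_params) == set(lorenz.free_params)

    def test_neuron_network_drops_hidden_states_of_replaced_neurons(self):
        net = random_network(3, 5, np.random.default_rng(0))
        model = hindmarsh_rose_model(net)
        spec = make_hybrid_spec(model, ["x1", "x2"], EmbeddingConfig(kappa=10))
        assert spec.mechanistic_vars == ("x3", "y3", "z3")
        assert spec.dropped_vars == ("y1", "z1", "y2", "z2")
        assert spec.retained_params == ("a3", "b3", "c3", "beta_31", "beta_32")

    def test_lpa_hybrid_retains_only_larval_mortality(self):
        spec = make_hybrid_spec(lpa_model(), ["L"], EmbeddingConfig(d=2, kappa=5))
        assert spec.mechanistic_vars == ("P", "A")
        assert spec.retained_params == ("mu_l",)

    def test_replacing_unobserved_variable_rejected(self):
        net = random_network(2, 1, np.random.default_rng(0))
        model = hindmarsh_rose_model(net)
        with pytest.raises(ValueError):
            make_hybrid_spec(model, ["y1"], EMB)

    def test_retained_parameter_count_never_grows(self, lorenz):
        full = len(lorenz.free_params)
        for replace in ([], ["y"], ["z"], ["y", "z"]):
            spec = make_hybrid_spec(lorenz, replace, EMB)
            assert len(spec.retained_params) <= full

    def test_layout_dimension_formula(self, lorenz):
        spec = make_hybrid_spec(lorenz, ["y"], EMB)
        layout = HybridLayout(spec=spec, n_params=2)
        assert layout.dim == 2 + (EMB.d * EMB.tau + 1) + 2
        assert layout.block_slice("y") == slice(2, 12)
        np.testing.assert_array_equal(layout.obs_indices, [0, 2, 1])


class TestAdvancement:
    def test_degenerate_spec_reduces_to_integrator_step(self, lorenz):
        spec = make_hybrid_spec(lorenz, [], EMB)
        layout = HybridLayout(spec=spec, n_params=0)
        state = np.array([1.0, 2.0, 3.0])
        out = hybrid_advance_points(state[None, :], spec, {}, layout)[0]
        expect = rk4_step(lorenz.rhs_or_map, 0.0, state, 0.05, lorenz.true_params)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_exact_library_single_neighbor_advances_exactly(self, lorenz):
        # library built from the noise-free trajectory, kappa=1: querying a
        # delay vector that occurs in the library returns the true next value
        clean, _ = generate_training_data(lorenz, 300, 0.0, seed=8)
        emb = EmbeddingConfig(d=9, tau=1, kappa=1)
        spec = make_hybrid_spec(lorenz, ["y"], emb)
        layout = HybridLayout(spec=spec, n_params=2)
        y = clean.column("y")
        lib = build_delay_library(y, emb, max_lead=1)
        t = 120
        state = np.empty(layout.dim)
        state[0] = clean.column("x")[t]
        state[1] = clean.column("z")[t]
        state[layout.block_slice("y")] = y[t - np.arange(10)]
        state[layout.param_slice] = [10.0, 8 / 3]
        out = hybrid_advance(state, spec, {"y": lib}, layout)
        assert out[layout.block_slice("y").start] == pytest.approx(y[t + 1], abs=1e-12)
        # lag entries shifted by one slot
        np.testing.assert_array_equal(out[layout.block_slice("y")][1:],
                                      state[layout.block_slice("y")][:-1])

    def test_lpa_hybrid_advances_pupae_and_adults_mechanistically(self):
        model = lpa_model()
        emb = EmbeddingConfig(d=2, tau=1, kappa=1)
        spec = make_hybrid_spec(model, ["L"], emb)
        layout = HybridLayout(spec=spec, n_params=1)
        clean, _ = generate_training_data(model, 50, 0.0, seed=4)
        L = clean.column("L")
        lib = build_delay_library(L, emb, max_lead=1)
        t = 20
        state = np.empty(layout.dim)
        state[0] = clean.column("P")[t]
        state[1] = clean.column("A")[t]
        state[layout.block_slice("L")] = L[t - np.arange(3)]
        state[layout.param_slice] = [0.2055]
        out = hybrid_advance(state, spec, {"L": lib}, layout)
        nxt = lpa_step(clean.values[t], model.true_params)
        assert out[0] == pytest.approx(nxt[1])  # P' = L (1 - mu_l)
        assert out[1] == pytest.approx(nxt[2])  # A' = P e^{-c_pa A} + A(1 - mu_a)


class TestHybridFilter:
    def test_degenerate_hybrid_equals_parametric_engine(self, lorenz,
                                                        lorenz_realization):
        _, noisy = lorenz_realization
        init = np.array([9.0, 27.0, 2.9])
        ucfg = default_ukf_config(lorenz, lorenz.free_params, init, 4.0, 0.2,
                                  lam=0.0)
        pres = run_joint_ukf(noisy, lorenz, lorenz.free_params, init, ucfg)

        spec = make_hybrid_spec(lorenz, [], EMB)
        layout = HybridLayout(spec=spec, n_params=3)
        hcfg = default_hybrid_config(spec, layout, init, 4.0, 0.2, lam=0.0)
        hcfg.Q, hcfg.P0 = ucfg.Q.copy(), ucfg.P0.copy()
        hres = run_hybrid_ukf(noisy, spec, init, hcfg)
        np.testing.assert_allclose(hres.final_params, pres.final_params, atol=1e-9)
        np.testing.assert_allclose(
            hres.final_belief.mean[:3], pres.final_belief.mean[:3], atol=1e-9)
        # and forecasts coincide with the parametric forward solve
        hfc = hybrid_forecast(hres, 10)
        pfc = parametric_forecast(lorenz, pres, 10)
        np.testing.assert_allclose(hfc, pfc, atol=1e-9)

    def test_hybrid_estimates_two_parameters_not_three(self, lorenz,
                                                       lorenz_realization):
        _, noisy = lorenz_realization
        spec = make_hybrid_spec(lorenz, ["y"], EMB)
        res = run_hybrid_ukf(noisy, spec, np.array([10.0, 8 / 3]),
                             noise_variance=4.0, uncertainty=0.2)
        assert res.param_history.shape[1] == 2
        assert res.estimate_names == ("sigma", "beta")

    def test_filter_recovers_parameters_near_truth(self, lorenz,
                                                   lorenz_realization):
        _, noisy = lorenz_realization
        spec = make_hybrid_spec(lorenz, ["y"], EMB)
        layout = HybridLayout(spec=spec, n_params=2)
        init = np.array([10.0, 8 / 3])
        cfg = default_hybrid_config(spec, layout, init, 4.0, 0.2,
                                    q_state=np.array([1.0, 0.25]),
                                    q_param_rel=1e-4)
        res = run_hybrid_ukf(noisy, spec, init, cfg)
        assert res.final_params[0] == pytest.approx(10.0, rel=0.15)
        assert res.final_params[1] == pytest.approx(8 / 3, rel=0.15)

    def test_state_coupling_mode_runs(self, lorenz, lorenz_realization):
        _, noisy = lorenz_realization
        spec = make_hybrid_spec(lorenz, ["y"], EMB)
        res = run_hybrid_ukf(noisy, spec, np.array([10.0, 8 / 3]),
                             noise_variance=4.0, uncertainty=0.2,
                             coupling="state")
        assert np.all(np.isfinite(res.final_params))

    def test_wrong_init_length_rejected(self, lorenz, lorenz_realization):
        _, noisy = lorenz_realization
        spec = make_hybrid_spec(lorenz, ["y"], EMB)
        with pytest.raises(ValueError):
            run_hybrid_ukf(noisy, spec, np.array([10.0, 28.0, 8 / 3]),
                           noise_variance=4.0, uncertainty=0.2)


class TestHybridForecast:
    def test_first_step_matches_standalone_lead1_prediction(self, lorenz,
                                                            lorenz_realization):
        _, noisy = lorenz_realization
        spec = make_hybrid_spec(lorenz, ["y"], EMB)
        res = run_hybrid_ukf(noisy, spec, np.array([10.0, 8 / 3]),
                             noise_variance=4.0, uncertainty=0.2)
        fc = hybrid_forecast(res, 3)
        layout = res.layout
        ring = res.final_belief.mean[layout.block_slice("y")]
        expect = local_constant_predict(ring[:: EMB.tau], res.libs["y"], EMB, lead=1)
        assert fc[0, lorenz.state_names.index("y")] == pytest.approx(expect)

    def test_forecast_shape_and_finiteness(self, lorenz, lorenz_realization):
        _, noisy = lorenz_realization
        spec = make_hybrid_spec(lorenz, ["y"], EMB)
        res = run_hybrid_ukf(noisy, spec, np.array([10.0, 8 / 3]),
                             noise_variance=4.0, uncertainty=0.2)
        fc = hybrid_forecast(res, 20)
        assert fc.shape == (20, 3)
        assert np.all(np.isfinite(fc))
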