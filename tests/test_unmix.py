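"""Odor models, sensor reliability weights and the constrained solvers."""

import numpy as np
import pytest

from odormix.data import Dataset, OdorSample
from odormix.synthetic import bench_config, generate_bench_datasets
from odormix.unmix import (
    MixtureModel,
    SensorWeights,
    compute_sensor_weights,
    fit_mixture_model,
    fit_pure_model,
    predict_response,
    solve_cls,
    solve_wcls,
)
from oracles import nnls_by_enumeration

PURE_LEVELS = [28.0, 45.0, 57.0, 68.0, 85.0]


def _pure_dataset(universe, slope_matrix, levels=PURE_LEVELS, noise=None, rng=None):
    samples = []
    for j, name in enumerate(universe.names):
        for k, c in enumerate(levels):
            conc = np.zeros(universe.n)
            conc[j] = c
            feats = slope_matrix[:, j] * c
            if noise is not None:
                feats = feats + noise * rng.standard_normal(len(feats))
            samples.append(OdorSample(f"{name}-{k}", feats,
                                      label=universe.subset([name]),
                                      concentrations=conc))
    return Dataset(universe, samples)


class TestPureModel:
    def test_exact_line_through_origin(self, universe):
        alpha = np.full((4, 3), 2.0)
        ds = _pure_dataset(universe, alpha)
        fitted = fit_pure_model(ds)
        np.testing.assert_allclose(fitted.alpha, 2.0, atol=1e-12)

    def test_single_sample_slope(self, universe):
        ds = Dataset(universe, [
            OdorSample(f"{n}-0", np.full(2, 5.0) if n == "M" else np.full(2, 1.0) * c0,
                       label=universe.subset([n]),
                       concentrations=np.eye(3)[j] * (10.0 if n == "M" else c0))
            for j, (n, c0) in enumerate(zip(universe.names, [10.0, 1.0, 1.0]))
        ])
        fitted = fit_pure_model(ds)
        np.testing.assert_allclose(fitted.alpha[:, 0], 0.5, atol=1e-12)

    def test_noisy_slope_matches_normal_equation_oracle(self, universe, rng):
        alpha = rng.uniform(0.1, 1.0, size=(6, 3))
        ds = _pure_dataset(universe, alpha, noise=0.3, rng=rng)
        fitted = fit_pure_model(ds)
        for j in range(3):
            pure = [s for s in ds if s.label.label == universe.names[j]]
            c = np.array([s.concentrations[j] for s in pure])
            for i in range(6):
                r = np.array([s.features[i] for s in pure])
                assert fitted.alpha[i, j] == pytest.approx(
                    float(r @ c) / float(c @ c), abs=1e-10
                )

    def test_missing_pure_component_reported(self, universe):
        alpha = np.ones((3, 3))
        ds = _pure_dataset(universe, alpha)
        ds = ds.subset(lambda s: s.label.label != "E")
        with pytest.raises(ValueError, match="'E'"):
            fit_pure_model(ds)


def _mixture_dataset(universe, alpha, beta, offset, rng, n_mix=30, noise=0.0):
    samples = list(_pure_dataset(universe, alpha).samples)
    # pure responses must follow the full model for exact-recovery checks
    gain = beta * alpha
    out = []
    for idx, s in enumerate(samples):
        feats = offset + gain @ s.concentrations
        out.append(OdorSample(s.sample_id, feats, label=s.label,
                              concentrations=s.concentrations))
    for k in range(n_mix):
        c = rng.uniform(10, 90, size=universe.n)
        feats = offset + gain @ c + noise * rng.standard_normal(alpha.shape[0])
        out.append(OdorSample(f"mix-{k}", feats,
                              label=universe.subset(universe.names),
                              concentrations=c))
    return Dataset(universe, out)


class TestMixtureModel:
    def test_pure_additivity_recovered_exactly(self, universe, rng):
        alpha = rng.uniform(0.1, 1.0, size=(8, 3))
        ds = _mixture_dataset(universe, alpha, np.ones((8, 3)), np.zeros(8), rng)
        model = fit_mixture_model(ds, fit_pure_model(ds))
        np.testing.assert_allclose(model.beta, 1.0, atol=1e-9)
        np.testing.assert_allclose(model.beta_offset, 0.0, atol=1e-7)

    def test_random_coefficients_identified_without_noise(self, universe, rng):
        alpha = rng.uniform(0.1, 1.0, size=(5, 3))
        beta = rng.uniform(0.5, 1.5, size=(5, 3))
        offset = rng.uniform(-1, 1, size=5)
        ds = _mixture_dataset(universe, alpha, beta, offset, rng)
        # fit betas against the *same* alpha used to generate
        from odormix.unmix import PureOdorModel

        model = fit_mixture_model(ds, PureOdorModel(alpha))
        np.testing.assert_allclose(model.beta, beta, atol=1e-9)
        np.testing.assert_allclose(model.beta_offset, offset, atol=1e-7)
        np.testing.assert_allclose(model.effective_gain, beta * alpha, atol=1e-9)

    def test_noisy_fit_matches_normal_equations_oracle(self, universe, rng):
        from odormix.unmix import PureOdorModel

        alpha = rng.uniform(0.1, 1.0, size=(4, 3))
        ds = _mixture_dataset(universe, alpha, np.ones((4, 3)), np.zeros(4), rng,
                              noise=0.5)
        model = fit_mixture_model(ds, PureOdorModel(alpha))
        C = ds.concentration_matrix()
        T = ds.feature_matrix()
        for i in range(4):
            X = np.column_stack([np.ones(len(ds)), C * alpha[i]])
            coef = np.linalg.solve(X.T @ X, X.T @ T[:, i])
            assert model.beta_offset[i] == pytest.approx(coef[0], abs=1e-8)
            np.testing.assert_allclose(model.beta[i], coef[1:], atol=1e-8)

    def test_mixtures_only_fit_excludes_pure_samples(self, universe, rng):
        from odormix.unmix import PureOdorModel

        alpha = rng.uniform(0.1, 1.0, size=(4, 3))
        beta = rng.uniform(0.5, 1.5, size=(4, 3))
        ds = _mixture_dataset(universe, alpha, beta, np.zeros(4), rng)
        # corrupt the pure samples; a mixtures-only fit must be unaffected
        for s in ds:
            if len(s.label) == 1:
                s.features = s.features + 100.0
        model = fit_mixture_model(ds, PureOdorModel(alpha), include_pure=False)
        np.testing.assert_allclose(model.beta, beta, atol=1e-8)

    def test_rank_deficient_design_reported(self, universe):
        from odormix.unmix import PureOdorModel

        alpha = np.ones((2, 3))
        # all samples share one concentration vector -> rank-deficient design
        samples = [
            OdorSample(f"x{k}", np.ones(2), label=universe.subset(universe.names),
                       concentrations=np.array([10.0, 10.0, 10.0]))
            for k in range(6)
        ]
        with pytest.raises(ValueError, match="sensor 1"):
            fit_mixture_model(Dataset(universe, samples), PureOdorModel(alpha))


def test_mixture_model_table_round_trips(tmp_path, rng):
    alpha = rng.uniform(0.1, 1.0, size=(5, 3))
    beta = rng.uniform(0.5, 1.5, size=(5, 3))
    offset = rng.uniform(-1, 1, size=5)
    model = MixtureModel(offset, beta, alpha, beta * alpha)
    path = tmp_path / "model.csv"
    model.save(path)
    back = MixtureModel.load(path)
    np.testing.assert_allclose(back.alpha, model.alpha, atol=1e-12)
    np.testing.assert_allclose(back.beta, model.beta, atol=1e-12)
    np.testing.assert_allclose(back.beta_offset, model.beta_offset, atol=1e-12)
    np.testing.assert_allclose(back.effective_gain, model.effective_gain, atol=1e-12)


class TestPredictResponse:
    def _model(self, rng, m=6, n=3):
        alpha = rng.uniform(0.1, 1.0, size=(m, n))
        beta = rng.uniform(0.5, 1.5, size=(m, n))
        offset = rng.uniform(-1, 1, size=m)
        return MixtureModel(offset, beta, alpha, beta * alpha)

    def test_zero_concentration_gives_offset(self, rng):
        model = self._model(rng)
        np.testing.assert_allclose(predict_response(model, np.zeros(3)),
                                   model.beta_offset, atol=1e-12)

    def test_linearity_about_the_offset(self, rng):
        model = self._model(rng)
        c1, c2 = rng.uniform(0, 50, 3), rng.uniform(0, 50, 3)
        lhs = predict_response(model, c1 + c2) - model.beta_offset
        rhs = (predict_response(model, c1) - model.beta_offset) + (
            predict_response(model, c2) - model.beta_offset
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_matches_hand_evaluated_sum(self, rng):
        model = self._model(rng, m=4)
        c = rng.uniform(0, 80, 3)
        expected = [
            model.beta_offset[i]
            + sum(model.beta[i, j] * model.alpha[i, j] * c[j] for j in range(3))
            for i in range(4)
        ]
        np.testing.assert_allclose(predict_response(model, c), expected, atol=1e-12)


class TestSensorWeights:
    def test_residual_sums_1_4_give_weights_2_half(self, universe):
        # two sensors, residual sums (1, 4): lambda = 2, omega = (2, 0.5)
        alpha = np.ones((2, 3))
        model = MixtureModel(np.zeros(2), np.ones((2, 3)), alpha, alpha)
        c = np.array([1.0, 1.0, 1.0])
        truth = predict_response(model, c)
        ds = Dataset(universe, [
            OdorSample("a", truth + np.array([1.0, 2.0]),
                       label=universe.subset(universe.names), concentrations=c)
        ])
        w = compute_sensor_weights(model, ds)
        np.testing.assert_allclose(w.training_residual_sums, [1.0, 4.0])
        assert w.normalizer == pytest.approx(2.0)
        np.testing.assert_allclose(w.omega, [2.0, 0.5], atol=1e-12)

    def test_equal_residuals_give_unit_weights_and_product_one(self, rng):
        train, _ = generate_bench_datasets(bench_config(seed=5))
        pure = fit_pure_model(train)
        model = fit_mixture_model(train, pure)
        w = compute_sensor_weights(model, train)
        assert np.prod(w.omega) == pytest.approx(1.0, rel=1e-9)
        # symmetric case
        alpha = np.ones((3, 3))
        m2 = MixtureModel(np.zeros(3), np.ones((3, 3)), alpha, alpha)
        universe = train.universe
        c = np.array([1.0, 1.0, 1.0])
        ds = Dataset(universe, [
            OdorSample("a", predict_response(m2, c) + 0.5,
                       label=universe.subset(universe.names), concentrations=c)
        ])
        np.testing.assert_allclose(compute_sensor_weights(m2, ds).omega, 1.0,
                                   atol=1e-12)


def _random_model(rng, m, n):
    alpha = rng.uniform(0.1, 1.0, size=(m, n))
    beta = rng.uniform(0.5, 1.5, size=(m, n))
    offset = rng.uniform(-1, 1, size=m)
    return MixtureModel(offset, beta, alpha, beta * alpha)


class TestSolvers:
    def test_consistent_system_is_recovered(self, rng):
        model = _random_model(rng, 8, 3)
        c_true = np.array([34.0, 0.0, 68.0])
        res = solve_cls(model, predict_response(model, c_true))
        np.testing.assert_allclose(res.concentrations, c_true, atol=1e-8)
        assert res.objective == pytest.approx(0.0, abs=1e-12)

    def test_offset_only_signal_gives_zero(self, rng):
        model = _random_model(rng, 6, 3)
        res = solve_cls(model, model.beta_offset.copy())
        np.testing.assert_allclose(res.concentrations, 0.0, atol=1e-10)

    def test_infeasible_unconstrained_optimum_matches_enumeration(self, rng):
        hit_boundary = 0
        for _ in range(50):
            m, n = int(rng.integers(4, 10)), int(rng.integers(2, 5))
            model = _random_model(rng, m, n)
            t = model.beta_offset + rng.standard_normal(m) * 5.0
            res = solve_cls(model, t)
            oracle = nnls_by_enumeration(model.effective_gain, t - model.beta_offset)
            np.testing.assert_allclose(res.concentrations, oracle, atol=1e-8)
            unconstrained, *_ = np.linalg.lstsq(model.effective_gain,
                                                t - model.beta_offset, rcond=None)
            hit_boundary += np.any(unconstrained < 0)
        assert hit_boundary > 0  # the sweep really exercised active constraints

    def test_kkt_conditions_hold(self, rng):
        model = _random_model(rng, 8, 4)
        t = model.beta_offset + rng.standard_normal(8) * 3.0
        res = solve_cls(model, t)
        G = model.effective_gain
        grad = G.T @ (G @ res.concentrations - (t - model.beta_offset))
        active = res.concentrations > 1e-10
        assert np.all(np.abs(grad[active]) < 1e-7)
        assert np.all(grad[~active] >= -1e-8)

    def test_unit_weights_reduce_wcls_to_cls(self, rng):
        model = _random_model(rng, 8, 3)
        t = model.beta_offset + rng.standard_normal(8) * 4.0
        w = SensorWeights(np.ones(8), 1.0, np.ones(8))
        a, b = solve_wcls(model, t, w), solve_cls(model, t)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)

    def test_weighting_cannot_move_a_zero_residual_optimum(self, rng):
        model = _random_model(rng, 8, 3)
        c_true = np.array([10.0, 51.0, 0.0])
        t = predict_response(model, c_true)
        omega = rng.uniform(0.2, 5.0, size=8)
        omega /= np.prod(omega) ** (1 / 8)
        res = solve_wcls(model, t, SensorWeights(omega, 1.0, np.ones(8)))
        np.testing.assert_allclose(res.concentrations, c_true, atol=1e-8)

    def test_weighted_instances_match_weighted_enumeration(self, rng):
        for _ in range(30):
            m, n = int(rng.integers(4, 9)), int(rng.integers(2, 5))
            model = _random_model(rng, m, n)
            t = model.beta_offset + rng.standard_normal(m) * 5.0
            omega = rng.uniform(0.1, 10.0, size=m)
            res = solve_wcls(model, t, SensorWeights(omega, 1.0, np.ones(m)))
            oracle = nnls_by_enumeration(model.effective_gain,
                                         t - model.beta_offset, omega)
            np.testing.assert_allclose(res.concentrations, oracle, atol=1e-8)

    def test_repeated_solves_are_bit_stable_and_beat_random_feasible_points(self, rng):
        model = _random_model(rng, 8, 3)
        t = model.beta_offset + rng.standard_normal(8) * 5.0
        omega = rng.uniform(0.2, 5.0, 8)
        w = SensorWeights(omega, 1.0, np.ones(8))
        res1 = solve_wcls(model, t, w)
        res2 = solve_wcls(model, t, w)
        assert np.array_equal(res1.concentrations, res2.concentrations)
        G, y = model.effective_gain, t - model.beta_offset
        for _ in range(100):
            c = rng.uniform(0, 100, size=3)
            r = G @ c - y
            assert res1.objective <= 0.5 * float(omega @ (r * r)) + 1e-9

    def test_rejects_bad_inputs(self, rng):
        model = _random_model(rng, 4, 3)
        with pytest.raises(ValueError):
            solve_cls(model, np.array([1.0, np.nan, 0.0, 0.0]))
        with pytest.raises(ValueError):
            solve_wcls(model, np.ones(4),
                       SensorWeights(np.array([1.0, -1.0, 1.0, 1.0]), 1.0, np.ones(4)))


class TestFullPipeline:
    def test_noise_free_additive_data_is_recovered_exactly(self):
        cfg = bench_config(seed=3, noise_sd=0.0)
        train, test = generate_bench_datasets(cfg)
        pure = fit_pure_model(train)
        model = fit_mixture_model(train, pure)
        w = compute_sensor_weights(model, train)
        for s in test:
            res = solve_wcls(model, s.features, w)
            err = res.concentrations - s.concentrations
            assert float(np.sqrt(np.mean(err**2))) < 1e-6
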