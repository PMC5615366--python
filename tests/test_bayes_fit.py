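"""Cost, gradients, evidence updates, and the two-stage fitting protocol."""

import numpy as np
import pytest

from shapebind import (
    AffinityModel,
    DinucCorrection,
    FitConfig,
    IndependentModel,
    RegularizationState,
    ShapeCorrection,
    SimulationSpec,
    cost_gradient,
    curvature,
    data_misfit,
    fit_correction,
    fit_independent,
    fit_motif_sizes,
    passes_retention,
    predict_signal,
    regularized_cost,
    retain_model,
    simulate_training_set,
    update_hyperparameters,
)
from shapebind.bayes_fit import (
    evidence_fixed_point,
    pack_parameters,
    parameter_layout,
    unpack_parameters,
)

from .conftest import consensus_like_w

FAST = FitConfig(max_outer=3, max_gd_steps=400)


def make_model(kind, rng, shape_table, M=5):
    w = rng.normal(size=(M, 4))
    correction = None
    if kind == "dinuc":
        correction = DinucCorrection(d=rng.normal(size=(M - 1, 16)) * 0.3)
    elif kind == "shape":
        correction = ShapeCorrection(
            df=rng.normal(size=(M - 1, shape_table.K)) * 0.3, table=shape_table
        )
    return AffinityModel(
        independent=IndependentModel(w=w, mu=rng.normal() * 0.5),
        correction=correction,
        a=1.0 + rng.normal() * 0.2,
        b=rng.normal() * 0.2,
    )


def make_reg(model, rng):
    M = model.M
    alpha_d = None if model.correction is None else rng.uniform(0.001, 0.1, M - 1)
    return RegularizationState(
        beta=rng.uniform(0.5, 2.0),
        alpha_w=rng.uniform(0.001, 0.1),
        alpha_d=alpha_d,
        alpha_aux=rng.uniform(0.001, 0.1),
    )


class TestDataMisfit:
    def test_perfect_predictions_give_zero(self, tiny_training_set):
        spec, data = tiny_training_set
        noiseless = SimulationSpec(
            M=spec.M, true_w=spec.true_w, seq_length=spec.seq_length,
            n_pos=spec.n_pos, n_neg=spec.n_neg, noise_sd=0.0, seed=spec.seed,
        )
        clean = simulate_training_set(noiseless)
        assert data_misfit(noiseless.true_model(), clean) < 1e-20

    def test_matches_per_sequence_loop_oracle(self, rng, tiny_training_set):
        _, data = tiny_training_set
        model = make_model("indep", rng, None)
        expected = 0.5 * sum(
            (predict_signal(s, model) - t) ** 2
            for s, t in zip(data.sequences, data.targets)
        )
        assert abs(data_misfit(model, data) - expected) < 1e-9


class TestRegularizedCost:
    def test_zero_alpha_unit_beta_equals_misfit(self, rng, tiny_training_set):
        _, data = tiny_training_set
        model = make_model("indep", rng, None)
        reg = RegularizationState(beta=1.0, alpha_w=0.0, alpha_aux=0.0)
        assert abs(regularized_cost(model, data, reg) - data_misfit(model, data)) < 1e-12

    def test_matches_explicit_summation_oracle(self, rng, shape_table, tiny_training_set):
        _, data = tiny_training_set
        model = make_model("shape", rng, shape_table)
        reg = make_reg(model, rng)
        penalty = reg.alpha_w * float(np.sum(model.independent.w ** 2))
        for p in range(model.M - 1):
            penalty += reg.alpha_d[p] * float(np.sum(model.correction.df[p] ** 2))
        penalty += reg.alpha_aux * (
            model.independent.mu ** 2 + model.a ** 2 + model.b ** 2
        )
        expected = reg.beta * data_misfit(model, data) + penalty
        assert abs(regularized_cost(model, data, reg) - expected) < 1e-9

    def test_negative_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            RegularizationState(beta=-1.0)
        with pytest.raises(ValueError):
            RegularizationState(beta=1.0, alpha_w=-0.1)


class TestCostGradient:
    @pytest.mark.parametrize("kind", ["indep", "dinuc", "shape"])
    def test_matches_central_finite_differences(
        self, kind, rng, shape_table, tiny_training_set
    ):
        _, data = tiny_training_set
        eps = 1e-5
        for point in range(5):
            model = make_model(kind, rng, shape_table)
            reg = make_reg(model, rng)
            theta = pack_parameters(model)
            g = cost_gradient(model, data, reg)
            fd = np.empty_like(theta)
            for i in range(len(theta)):
                tp, tm = theta.copy(), theta.copy()
                tp[i] += eps
                tm[i] -= eps
                fd[i] = (
                    regularized_cost(unpack_parameters(tp, model), data, reg)
                    - regularized_cost(unpack_parameters(tm, model), data, reg)
                ) / (2 * eps)
            scale = np.maximum(np.abs(fd), 1e-6)
            assert np.max(np.abs(g - fd) / scale) < 1e-5

    def test_penalty_term_appears_as_two_alpha_w(self, rng, tiny_training_set):
        _, data = tiny_training_set
        model = make_model("indep", rng, None)
        reg0 = RegularizationState(beta=1.0, alpha_w=0.0, alpha_aux=0.0)
        reg1 = RegularizationState(beta=1.0, alpha_w=0.7, alpha_aux=0.0)
        diff = cost_gradient(model, data, reg1) - cost_gradient(model, data, reg0)
        layout = parameter_layout(model)
        sl = layout.slices()
        expected = 2 * 0.7 * model.independent.w.ravel()
        assert np.allclose(diff[sl["w"]], expected, atol=1e-12)
        assert np.allclose(diff[sl["a"]], 0.0)


class TestCurvature:
    def test_positive_semidefinite(self, rng, shape_table, tiny_training_set):
        _, data = tiny_training_set
        for kind in ("indep", "dinuc", "shape"):
            model = make_model(kind, rng, shape_table)
            H = curvature(model, data, make_reg(model, rng))
            assert np.allclose(H, H.T)
            assert np.linalg.eigvalsh(H).min() >= -1e-9

    def test_single_parameter_linear_toy_closed_form(self):
        # pred_i = a * P_i with fixed P: the exact curvature along `a`
        # is beta * sum(P^2) + 2*alpha
        GtG = np.array([[14.0]])  # P = (1, 2, 3)
        res = evidence_fixed_point(
            GtG, np.array([2.0]), LD=0.5, n_data=10, group_ids=np.array([0]),
            beta=2.0, alpha_by_group=np.array([0.3]), max_iter=1,
        )
        H = 2.0 * 14.0 + 2 * 0.3
        assert abs(res.gamma[0] - (1 - 0.3 / H)) < 1e-12


class TestEvidenceFixedPoint:
    def test_first_iteration_from_zero_alpha(self):
        # gamma = 1 - 0 * Hinv = 1, then alpha = 1/W^2, beta = (N-1)/(2 LD)
        res = evidence_fixed_point(
            np.array([[4.0]]), np.array([3.0]), LD=2.0, n_data=50,
            group_ids=np.array([0]), beta=1.0, alpha_by_group=np.array([0.0]),
            max_iter=1,
        )
        assert res.gamma[0] == 1.0
        assert abs(res.alpha_by_group[0] - 1.0 / 9.0) < 1e-12
        assert abs(res.beta - 49.0 / 4.0) < 1e-12

    def test_all_zero_parameters_cap_alpha(self):
        res = evidence_fixed_point(
            np.eye(2), np.zeros(2), LD=1.0, n_data=10,
            group_ids=np.array([0, 0]), beta=1.0, alpha_by_group=np.array([0.1]),
        )
        assert res.alpha_by_group[0] == 1e6

    def test_no_data_curvature_gives_half_gamma(self):
        # H = 2*diag(alpha) exactly, so alpha * Hinv_ii = 1/2
        res = evidence_fixed_point(
            np.zeros((3, 3)), np.array([1.0, 2.0, 3.0]), LD=1.0, n_data=10,
            group_ids=np.array([0, 1, 2]), beta=1.0,
            alpha_by_group=np.array([0.5, 0.5, 0.5]), max_iter=1,
        )
        assert np.allclose(res.gamma, 0.5)

    def test_beta_update_rejected_when_gamma_exceeds_n(self):
        with pytest.raises(ValueError, match="beta update rejected"):
            evidence_fixed_point(
                np.eye(3) * 100, np.ones(3), LD=1.0, n_data=2,
                group_ids=np.arange(3), beta=1.0,
                alpha_by_group=np.full(3, 1e-6),
            )

    def test_three_parameter_quadratic_matches_scalar_oracle(self):
        """The grouped update must reach the same fixed point as a plain
        scalar re-implementation of the printed equations."""
        rng = np.random.default_rng(4)
        G = rng.normal(size=(40, 3))
        GtG = G.T @ G
        theta = np.array([1.5, -0.7, 0.2])
        LD, n_data = 3.0, 40
        groups = np.array([0, 1, 2])

        # independent scalar-iteration oracle
        alpha = np.full(3, 1e-6)
        beta = 1.0
        for _ in range(500):
            H = beta * GtG + 2.0 * np.diag(alpha)
            Hinv = np.linalg.inv(H)
            gamma = np.array([1 - alpha[i] * Hinv[i, i] for i in range(3)])
            alpha_new = np.array([gamma[i] / theta[i] ** 2 for i in range(3)])
            beta_new = (n_data - gamma.sum()) / (2 * LD)
            if max(abs(alpha_new - alpha).max(), abs(beta_new - beta)) < 1e-12:
                break
            alpha, beta = alpha_new, beta_new

        res = evidence_fixed_point(
            GtG, theta, LD=LD, n_data=n_data, group_ids=groups,
            beta=1.0, alpha_by_group=np.full(3, 1e-6), tol=1e-10, max_iter=1000,
        )
        assert res.converged
        assert np.allclose(res.alpha_by_group, alpha, rtol=1e-4)
        assert abs(res.beta - beta) / beta < 1e-4
        assert np.all((res.gamma >= 0) & (res.gamma <= 1))
        assert res.gamma.sum() < n_data


class TestUpdateHyperparameters:
    def test_sanity_on_fitted_model(self, rng, tiny_training_set):
        _, data = tiny_training_set
        model = make_model("indep", rng, None)
        reg = RegularizationState(beta=1.0, alpha_w=1e-6, alpha_aux=1e-6)
        new = update_hyperparameters(model, data, reg, stage="independent")
        assert new.beta > 0
        assert new.alpha_w >= 0 and new.alpha_aux >= 0
        assert np.all((new.gamma >= 0) & (new.gamma <= 1))
        assert new.gamma.sum() < data.n_data

    def test_correction_stage_yields_per_position_alphas(
        self, rng, shape_table, tiny_training_set
    ):
        _, data = tiny_training_set
        model = make_model("shape", rng, shape_table)
        reg = RegularizationState(
            beta=1.0, alpha_w=0.0,
            alpha_d=np.full(model.M - 1, 1e-6), alpha_aux=1e-6,
        )
        new = update_hyperparameters(model, data, reg, stage="correction")
        assert new.alpha_d is not None and len(new.alpha_d) == model.M - 1
        assert np.all(new.alpha_d >= 0)


@pytest.fixture(scope="module")
def fitted_small():
    rng = np.random.default_rng(123)
    w = consensus_like_w(rng, 6)
    spec = SimulationSpec(
        M=6, true_w=w, seq_length=40, n_pos=60, n_neg=60, noise_sd=0.02, seed=21
    )
    data = simulate_training_set(spec)
    res = fit_independent(data, 6, seed=5, config=FAST)
    return spec, data, res


class TestFitIndependent:
    def test_deterministic_given_seed(self, fitted_small):
        spec, data, res = fitted_small
        res2 = fit_independent(data, 6, seed=5, config=FAST)
        assert np.array_equal(res.model.independent.w, res2.model.independent.w)
        assert res.model.a == res2.model.a and res.model.b == res2.model.b

    def test_descent_is_monotone_within_each_phase(self, fitted_small):
        _, _, res = fitted_small
        for entry in res.trace:
            costs = np.array(entry["phase_costs"])
            assert np.all(np.diff(costs) <= 1e-8 * np.maximum(1.0, np.abs(costs[:-1])))

    def test_evidence_sanity_along_the_run(self, fitted_small):
        _, data, res = fitted_small
        assert res.reg.beta > 0
        assert np.all((res.reg.gamma >= 0) & (res.reg.gamma <= 1))
        assert res.reg.gamma.sum() < data.n_data

    def test_small_data_rejected(self, rng):
        spec = SimulationSpec(
            M=4, true_w=np.zeros((4, 4)), seq_length=20, n_pos=3, n_neg=3, seed=0
        )
        data = simulate_training_set(spec)
        with pytest.raises(ValueError, match="at least 10"):
            fit_independent(data, 4)

    def test_pwm_init_requires_energies(self, fitted_small):
        _, data, _ = fitted_small
        with pytest.raises(ValueError, match="pwm"):
            fit_independent(data, 6, init="pwm")


class TestFitCorrection:
    def test_zero_start_reproduces_base_predictions(self, fitted_small, shape_table):
        """With df pinned at 0 the correction model predicts exactly as
        the base independent model."""
        _, data, res = fitted_small
        base = res.model
        frozen = AffinityModel(
            independent=base.independent,
            correction=ShapeCorrection(
                df=np.zeros((base.M - 1, shape_table.K)), table=shape_table
            ),
            a=base.a,
            b=base.b,
            scan_both_strands=base.scan_both_strands,
        )
        for s in data.sequences[:5]:
            assert abs(predict_signal(s, frozen) - predict_signal(s, base)) < 1e-12

    def test_shape_requires_table(self, fitted_small):
        _, data, res = fitted_small
        with pytest.raises(ValueError, match="table"):
            fit_correction(res, data, kind="shape")

    def test_freezes_independent_part(self, fitted_small, shape_table):
        _, data, res = fitted_small
        corr = fit_correction(
            res, data, kind="shape", table=shape_table, config=FAST, seed=1
        )
        assert np.array_equal(
            corr.model.independent.w, res.model.independent.w
        )
        assert corr.model.independent.mu == res.model.independent.mu
        assert isinstance(corr.model.correction, ShapeCorrection)


class TestRetention:
    def test_strict_inequalities_on_borderline_values(self):
        assert not passes_retention(0.4, 0.9)       # r2 exactly at threshold
        assert not passes_retention(0.9, 0.75)      # AUC exactly at threshold
        assert not passes_retention(0.39, 0.74)
        assert passes_retention(0.400001, 0.750001)

    def test_perfect_model_is_retained(self, fitted_small):
        spec, data, res = fitted_small
        assert retain_model(spec.true_model(), data)

    def test_constant_predictor_fails(self, fitted_small):
        _, data, _ = fitted_small
        flat = AffinityModel(
            independent=IndependentModel(w=np.zeros((6, 4))), a=0.0, b=1.0
        )
        assert not retain_model(flat, data)

    def test_one_class_data_rejected(self, fitted_small):
        from shapebind import TrainingSet

        _, data, res = fitted_small
        one_class = TrainingSet(
            sequences=data.sequences[:10], targets=np.ones(10)
        )
        with pytest.raises(ValueError, match="both"):
            retain_model(res, one_class)


class TestFitMotifSizes:
    def test_empty_sizes(self, fitted_small):
        _, data, _ = fitted_small
        assert fit_motif_sizes(data, sizes=(), seed=0) == []

    def test_attaches_retention_flag(self, fitted_small):
        _, data, _ = fitted_small
        results = fit_motif_sizes(data, sizes=(6,), seed=5, config=FAST)
        assert len(results) == 1
        assert results[0].retained is not None
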