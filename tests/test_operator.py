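"""Core operator machinery: the semi-implicit step, losses, training
gradients, sequential contract, forecasting, Jacobian read-out, archives."""

import numpy as np
import pytest

from lapdyn.cohort import Trajectory
from lapdyn.nn import MLP, ScaledMLP, softplus_inv
from lapdyn.operator import (NeuralOperatorModel, PARENTS, RolloutProblem,
                             TrainConfig, _prepare_batch, data_loss,
                             implicit_step, jacobian_analysis, load_models,
                             predict_forward, project_cohort, residual_loss,
                             rollout_coupled, save_models, train_operator,
                             train_sequential)


class _LinearNet:
    """Stand-in operator net G(x) = A x for closed-form checks."""

    def __init__(self, A):
        self.A = np.asarray(A, float)
        self.sizes = [self.A.shape[1], self.A.shape[0]]
        self.theta = np.zeros(0)

    def forward(self, X, theta=None, need_cache=False):
        out = np.atleast_2d(X) @ self.A.T
        out = out[0] if np.ndim(X) == 1 else out
        return (out, None) if need_cache else out

    def jacobian(self, x, theta=None):
        return self.A


def _model(basis, net, alpha, variable="A"):
    return NeuralOperatorModel(variable=variable, parents=PARENTS[variable],
                               basis=basis, net=net,
                               raw_alpha=float(softplus_inv(max(alpha, 1e-12)))
                               if alpha > 0 else -40.0)


class TestImplicitStep:
    def test_zero_reaction_zero_diffusion_is_identity(self, graph10):
        _, basis = graph10
        m = _model(basis, _LinearNet(np.zeros((basis.P, basis.P))), 0.0)
        b = np.arange(basis.P, dtype=float)
        np.testing.assert_array_equal(implicit_step(b, 0.3, m), b)

    def test_implicit_heat_decay_per_mode(self, graph10):
        _, basis = graph10
        m = _model(basis, _LinearNet(np.zeros((basis.P, basis.P))), 1.0)
        b = np.ones(basis.P)
        out = implicit_step(b, 0.5, m)
        np.testing.assert_allclose(out,
                                   1.0 / (1.0 + 0.5 * basis.eigenvalues),
                                   atol=1e-12)

    def test_linear_reaction_matches_ode_closed_form(self, two_node):
        # single mode: beta' = c*beta - alpha*lambda*beta
        _, basis = two_node
        c, alpha = 0.3, 0.2
        m = _model(basis, _LinearNet(c * np.eye(2)), alpha)
        beta = np.array([1.0, 1.0])
        T, K = 1.0, 2000
        for _ in range(K):
            beta = implicit_step(beta, T / K, m)
        rates = c - alpha * basis.eigenvalues
        np.testing.assert_allclose(beta, np.exp(rates * T), atol=2e-4)

    def test_nonpositive_dt_rejected(self, two_node):
        _, basis = two_node
        m = _model(basis, _LinearNet(np.eye(2)), 0.1)
        with pytest.raises(ValueError):
            implicit_step(np.ones(2), 0.0, m)

    def test_unconditional_stability_for_zero_reaction(self, graph10):
        _, basis = graph10
        m = _model(basis, _LinearNet(np.zeros((basis.P, basis.P))), 0.7)
        rng = np.random.default_rng(0)
        for _ in range(20):
            b = rng.normal(size=basis.P)
            out = implicit_step(b, rng.uniform(0.01, 10.0), m)
            assert np.linalg.norm(out) <= np.linalg.norm(b) + 1e-12


class TestLosses:
    def test_data_loss_exact_match_is_zero(self):
        b = np.random.default_rng(0).normal(size=(3, 4))
        assert data_loss(b, b) == 0.0

    def test_data_loss_doubled_single_point(self):
        e1 = np.array([[1.0, 0.0, 0.0]])
        assert np.isclose(data_loss(2 * e1, e1), 1.0)

    def test_data_loss_matches_manual_sum(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=(3, 5))
        bt = rng.normal(size=(3, 5))
        manual = np.mean([np.linalg.norm(bt[i] - b[i]) /
                          np.linalg.norm(b[i]) for i in range(3)])
        assert np.isclose(data_loss(bt, b), manual)

    def test_residual_loss_zero_for_scheme_generated_data(self, graph10):
        _, basis = graph10
        c = 0.2
        m = _model(basis, _LinearNet(c * np.eye(basis.P)), 0.15)
        dts = np.array([0.5, 1.0, 0.75])
        betas = [np.random.default_rng(2).uniform(0.5, 1.0, basis.P)]
        lam = basis.eigenvalues
        for dt in dts:
            prev = betas[-1]
            g = c * prev
            # data satisfying the one-step scheme identity exactly
            betas.append((prev + dt * g) / (1.0 + dt * m.alpha * lam))
        val = residual_loss(np.array(betas), m, dts)
        assert val < 1e-12

    def test_residual_loss_one_for_zero_operator(self, graph10):
        _, basis = graph10
        m = _model(basis, _LinearNet(np.zeros((basis.P, basis.P))), 0.0)
        rng = np.random.default_rng(3)
        betas = rng.normal(size=(4, basis.P))
        assert np.isclose(residual_loss(betas, m, np.ones(3)), 1.0)

    def test_residual_loss_hand_computed_two_modes(self, two_node):
        _, basis = two_node  # eigenvalues 0, 2
        m = _model(basis, _LinearNet(np.array([[0.1, 0.0], [0.0, 0.2]])), 0.5)
        betas = np.array([[1.0, 1.0], [2.0, 0.5]])
        dt = 2.0
        R = (betas[1] - betas[0]) / dt + 0.5 * np.array([0.0, 2.0]) * betas[1]
        G = np.array([0.1 * 1.0, 0.2 * 1.0])
        expected = np.linalg.norm(R - G) / np.linalg.norm(R)
        assert np.isclose(residual_loss(betas, m, np.array([dt])), expected)

    def test_single_visit_rejected(self, two_node):
        _, basis = two_node
        m = _model(basis, _LinearNet(np.eye(2)), 0.1)
        with pytest.raises(ValueError):
            residual_loss(np.ones((1, 2)), m, np.ones(0))


class TestTrainingGradients:
    def test_rollout_gradients_match_finite_differences(self, graph10):
        dom, basis = graph10
        basis4 = type(basis)(eigenvalues=basis.eigenvalues[:4],
                             vectors=basis.vectors[:, :4],
                             mass=None)
        rng = np.random.default_rng(5)
        records = []
        for pid in range(3):
            t = np.array([0.0, 1.0, 2.2])
            records.append({"patient_id": f"P{pid}", "times": t,
                            "beta": {"A": rng.normal(size=(3, 4))},
                            "C": np.zeros(3)})
        cfg = TrainConfig(dt_max=0.5, weight_decay=1e-4, g_norm_weight=1e-3)
        data = _prepare_batch(records, "A", (), cfg.dt_max, cfg.max_substeps)
        net = ScaledMLP(MLP([4, 12, 12, 4], seed=0, final_scale=0.5))
        prob = RolloutProblem(data, net, basis4.eigenvalues, cfg)
        theta, ra, z = net.theta.copy(), 0.2, np.array([0.0, 0.1, -0.1])
        _, _, _, dth, _, _, _ = prob.loss_and_grad(theta, ra, z)
        eps = 1e-6
        for i in rng.choice(theta.size, 6, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fp = prob.loss_and_grad(tp, ra, z, need_theta=False)[0]
            fm = prob.loss_and_grad(tm, ra, z, need_theta=False)[0]
            fd = (fp - fm) / (2 * eps)
            assert abs(dth[i] - fd) < 1e-6 * max(1.0, abs(fd))

    def test_combined_loss_zero_at_true_generator(self, two_node):
        """Data produced by the discrete scheme itself gives (near-)zero
        combined loss at the generating operator."""
        _, basis = two_node
        c = 0.25
        alpha = 0.1
        m = _model(basis, _LinearNet(c * np.eye(2)), alpha)
        lam = basis.eigenvalues
        t = np.array([0.0, 1.0, 2.0, 3.5])
        betas = [np.array([1.0, 0.5])]
        for dt in np.diff(t):
            prev = betas[-1]
            betas.append((prev + dt * (c * prev)) /
                         (1.0 + dt * alpha * lam))
        betas = np.array(betas)
        ld = data_loss(
            _scheme_rollout(m, betas[0], t, substeps_per_interval=1),
            betas)
        lr = residual_loss(betas, m, np.diff(t))
        assert ld < 1e-12
        assert lr < 1e-12


def _scheme_rollout(model, beta0, times, substeps_per_interval=1):
    out = [beta0]
    lam = model.basis.eigenvalues
    for dt_full in np.diff(times):
        b = out[-1]
        dt = dt_full / substeps_per_interval
        for _ in range(substeps_per_interval):
            b = (b + dt * model.net.forward(b)) / (1 + dt * model.alpha * lam)
        out.append(b)
    return np.array(out)


class TestTrainOperator:
    def test_interpolation_capacity_single_trajectory(self, small_cohort):
        dom, basis, cohort = small_cohort
        # an unconstrained (dense) operator can interpolate one noise-free
        # trajectory essentially exactly
        cfg = TrainConfig(iterations=2500, lr=5e-3, seed=0,
                          architecture="dense", input_noise=0.0,
                          per_patient_scale=False, weight_decay=0.0,
                          g_norm_weight=0.0, weight_residual=0.0)
        m = train_operator(cohort[:1], "A", basis, cfg)
        assert m.train_report.data_loss < 1e-3

    def test_seed_determinism(self, small_cohort):
        _, basis, cohort = small_cohort
        cfg = TrainConfig(iterations=60, seed=3)
        m1 = train_operator(cohort, "A", basis, cfg)
        m2 = train_operator(cohort, "A", basis, cfg)
        assert m1.train_report.loss_trace[-1] == m2.train_report.loss_trace[-1]
        np.testing.assert_array_equal(m1.net.theta, m2.net.theta)

    def test_sequential_order_contract(self, small_cohort):
        _, basis, cohort = small_cohort
        with pytest.raises(ValueError, match="order"):
            train_sequential(cohort, basis, TrainConfig(iterations=5),
                             order=("N", "tau", "A"))

    def test_missing_variable_rejected(self, small_cohort):
        _, basis, cohort = small_cohort
        broken = [Trajectory(patient_id=t.patient_id, times=t.times,
                             fields={"A": t.fields["A"]}, C=t.C)
                  for t in cohort]
        with pytest.raises(ValueError, match="tau"):
            train_sequential(broken, basis, TrainConfig(iterations=5))

    def test_divergence_reported(self, small_cohort):
        _, basis, cohort = small_cohort
        cfg = TrainConfig(iterations=500, lr=1e6, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            train_operator(cohort, "A", basis, cfg)


class TestPredictForward:
    def test_target_equal_to_start_returns_initial(self, small_cohort):
        _, basis, cohort = small_cohort
        models = _tiny_models(basis)
        traj = cohort[0]
        fc = predict_forward(models, traj, np.array([traj.times[-1]]))
        for v in ("A", "tau", "N"):
            ref = basis.vectors @ (basis.vectors.T @ traj.fields[v][-1])
            np.testing.assert_allclose(fc.fields[v][0], ref, atol=1e-10)

    def test_target_before_start_rejected(self, small_cohort):
        _, basis, cohort = small_cohort
        models = _tiny_models(basis)
        with pytest.raises(ValueError, match="precede|before|target"):
            predict_forward(models, cohort[0],
                            np.array([cohort[0].times[-1] - 1.0]))

    def test_substep_refinement_first_order(self, small_cohort):
        _, basis, cohort = small_cohort
        models = _tiny_models(basis, c=0.3)
        start = {v: np.random.default_rng(0).uniform(0.5, 1.0, basis.P)
                 for v in ("A", "tau", "N")}
        ends = []
        for dt in (0.2, 0.1, 0.05):
            out = rollout_coupled(models, start, 0.0, [2.0], dt_max=dt)
            ends.append(out["A"][0])
        e1 = np.linalg.norm(ends[0] - ends[1])
        e2 = np.linalg.norm(ends[1] - ends[2])
        assert 0.7 <= np.log2(e1 / e2) <= 1.3


def _tiny_models(basis, c=0.0):
    P = basis.P
    models = {}
    for v in ("A", "tau", "N"):
        npar = len(PARENTS[v])
        A = np.zeros((P, (npar + 1) * P))
        A[:, npar * P:] = c * np.eye(P)
        models[v] = NeuralOperatorModel(variable=v, parents=PARENTS[v],
                                        basis=basis, net=_LinearNet(A),
                                        raw_alpha=-40.0)
    return models


class TestJacobian:
    def test_linear_operator_recovered_exactly(self, graph10):
        _, basis = graph10
        rng = np.random.default_rng(8)
        A = rng.normal(size=(basis.P, 2 * basis.P))
        m = NeuralOperatorModel(variable="tau", parents=("A",), basis=basis,
                                net=_LinearNet(A), raw_alpha=0.0)
        rep = jacobian_analysis(m, rng.normal(size=2 * basis.P))
        np.testing.assert_allclose(rep.spectral, A, atol=1e-12)
        np.testing.assert_allclose(rep.blocks["A"], A[:, :basis.P])
        np.testing.assert_allclose(
            rep.nodal["tau"],
            basis.vectors @ A[:, basis.P:] @ basis.vectors.T, atol=1e-10)

    def test_autodiff_matches_finite_difference(self, graph10):
        _, basis = graph10
        net = ScaledMLP(MLP([basis.P, 20, basis.P], seed=1, final_scale=1.0),
                        mu=np.zeros(basis.P),
                        sigma=np.full(basis.P, 1.3), out_scale=0.8)
        m = NeuralOperatorModel(variable="A", parents=(), basis=basis,
                                net=net, raw_alpha=0.0)
        x = np.random.default_rng(9).normal(size=basis.P)
        J = jacobian_analysis(m, x).spectral
        eps = 1e-5
        for i in range(0, basis.P, 3):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (net.forward(xp) - net.forward(xm)) / (2 * eps)
            np.testing.assert_allclose(J[:, i], fd, rtol=1e-4, atol=1e-6)

    def test_wrong_state_size_rejected(self, graph10):
        _, basis = graph10
        m = _tiny_models(basis)["N"]
        with pytest.raises(ValueError, match="entries"):
            jacobian_analysis(m, np.zeros(basis.P))


class TestModelArchive:
    def test_round_trip_preserves_predictions_bitwise(self, small_cohort,
                                                      tmp_path):
        _, basis, cohort = small_cohort
        cfg = TrainConfig(iterations=40, seed=1)
        models = train_sequential(cohort, basis, cfg)
        save_models(models, str(tmp_path / "archive"))
        again = load_models(str(tmp_path / "archive"))
        traj = cohort[0]
        t = np.array([traj.times[-1] + 1.0, traj.times[-1] + 2.0])
        a = predict_forward(models, traj, t)
        b = predict_forward(again, traj, t)
        for v in ("A", "tau", "N"):
            np.testing.assert_array_equal(a.fields[v], b.fields[v])
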