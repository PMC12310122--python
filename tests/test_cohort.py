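"""Ground-truth simulator: closed forms, conservation, invariant regions,
treated dynamics and cohort generation contracts."""

import numpy as np
import pytest

from lapdyn.cohort import (CohortConfig, DomainOps, IntegrationError,
                           SimulationParams, generate_cohort, simulate,
                           simulate_treated, step_system)
from lapdyn.domain import (assemble_fem, build_graph_domain, compute_basis,
                           unit_square_mesh)


def zero_rates(**overrides):
    base = dict(lam_A=0, lam_tauA=0, lam_tautau=0, lam_Ntau=0, lam_NN=0,
                lam_CN=0, lam_CC=0, alpha_A=0, alpha_tau=0, alpha_N=0)
    base.update(overrides)
    return SimulationParams(**base)


def single_node():
    # one isolated region: pure reaction kinetics
    return build_graph_domain(np.zeros((1, 1)), allow_disconnected=True)


class TestStepSystem:
    def test_no_dynamics_keeps_state(self):
        ops = DomainOps(single_node())
        state = {"A": np.array([0.3]), "tau": np.array([0.2]),
                 "N": np.array([0.1]), "C": 25.0}
        new = step_system(state, zero_rates(), 0.5, ops)
        for v in ("A", "tau", "N"):
            np.testing.assert_array_equal(new[v], state[v])
        assert new["C"] == state["C"]

    def test_logistic_closed_form(self):
        # dA/dt = 0.5 * A * (2 - A), A0 = 0.1, exact at t = 5
        p = zero_rates(lam_A=0.5, K_A=2.0)
        dom = single_node()
        traj = simulate(p, {"A": np.array([0.1]), "tau": np.zeros(1),
                            "N": np.zeros(1)}, np.array([0.0, 5.0]), dom,
                        dt_max=1e-3)
        lamK = 0.5 * 2.0
        exact = 2.0 / (1.0 + (2.0 - 0.1) / 0.1 * np.exp(-lamK * 5.0))
        assert abs(traj.fields["A"][-1, 0] - exact) < 1e-4

    def test_nonpositive_dt_rejected(self):
        ops = DomainOps(single_node())
        state = {"A": np.zeros(1), "tau": np.zeros(1), "N": np.zeros(1),
                 "C": 0.0}
        with pytest.raises(ValueError, match="dt"):
            step_system(state, zero_rates(), 0.0, ops)

    def test_blowup_reported_with_time(self):
        p = zero_rates(lam_A=1e8, K_A=2.0)
        dom = single_node()
        with pytest.raises(IntegrationError, match="t ="):
            simulate(p, {"A": np.array([1.0]), "tau": np.zeros(1),
                         "N": np.zeros(1)}, np.array([0.0, 10.0]), dom,
                     dt_max=1.0)


class TestConservationAndClosedForms:
    def test_two_node_heat_kernel(self):
        w = 1.0
        dom = build_graph_domain(np.array([[0.0, w], [w, 0.0]]))
        p = zero_rates(alpha_A=1.0)
        traj = simulate(p, {"A": np.array([1.0, 0.0]), "tau": np.zeros(2),
                            "N": np.zeros(2)}, np.array([0.0, 1.0]), dom,
                        dt_max=1e-4)
        exact = 0.5 * np.array([1 + np.exp(-2 * w), 1 - np.exp(-2 * w)])
        # implicit Euler at dt=1e-4 on lambda=2: small but nonzero bias
        assert np.abs(traj.fields["A"][-1] - exact).max() < 5e-5

    @pytest.mark.parametrize("domain_kind", ["graph", "mesh"])
    def test_pure_diffusion_mass_conservation(self, domain_kind, graph10):
        if domain_kind == "graph":
            dom, _ = graph10
            ops = DomainOps(dom)
            u0 = np.linspace(0.2, 1.5, dom.n)
        else:
            fem = assemble_fem(unit_square_mesh(6))
            ops = DomainOps(fem)
            u0 = np.linspace(0.2, 1.5, fem.n)
        p = zero_rates(alpha_A=0.2)
        traj = simulate(p, {"A": u0, "tau": np.zeros_like(u0),
                            "N": np.zeros_like(u0)},
                        np.array([0.0, 1.0]), ops, dt_max=0.01)
        m0 = ops.mean(traj.fields["A"][0]) if domain_kind == "mesh" \
            else traj.fields["A"][0].sum()
        m1 = ops.mean(traj.fields["A"][-1]) if domain_kind == "mesh" \
            else traj.fields["A"][-1].sum()
        assert abs(m1 - m0) < 1e-8

    def test_zero_state_is_equilibrium(self):
        p = zero_rates(lam_A=0.7, K_A=2.0)
        dom = single_node()
        traj = simulate(p, {"A": np.zeros(1), "tau": np.zeros(1),
                            "N": np.zeros(1)}, np.array([0.0, 3.0]), dom)
        np.testing.assert_array_equal(traj.fields["A"][-1], 0.0)

    def test_carrying_capacity_is_equilibrium_with_diffusion(self, graph10):
        dom, _ = graph10
        p = zero_rates(lam_A=0.4, K_A=2.0, alpha_A=0.3)
        u0 = np.full(dom.n, 2.0)
        traj = simulate(p, {"A": u0, "tau": np.zeros(dom.n),
                            "N": np.zeros(dom.n)}, np.array([0.0, 2.0]), dom)
        np.testing.assert_allclose(traj.fields["A"][-1], 2.0, atol=1e-10)

    def test_invariant_region_parameter_sweep(self, graph10):
        dom, basis = graph10
        rng = np.random.default_rng(9)
        for _ in range(5):
            p = SimulationParams(
                lam_A=rng.uniform(0, 0.5), lam_tauA=rng.uniform(0, 0.4),
                lam_tautau=rng.uniform(0, 0.5), lam_Ntau=rng.uniform(0, 0.4),
                lam_NN=rng.uniform(0, 0.4), alpha_A=rng.uniform(0, 0.2),
                alpha_tau=rng.uniform(0, 0.2), alpha_N=rng.uniform(0, 0.2))
            init = {v: rng.uniform(0.05, 1.9, dom.n)
                    for v in ("A", "tau", "N")}
            traj = simulate(p, init, np.linspace(0, 10, 6), dom, dt_max=0.01)
            for v in ("A", "tau", "N"):
                assert traj.fields[v].min() >= 0.0
                assert traj.fields[v].max() <= 2.0 * (1 + 1e-3)

    def test_first_order_convergence(self):
        dom = single_node()
        p = zero_rates(lam_A=0.5, K_A=2.0)
        init = {"A": np.array([0.3]), "tau": np.zeros(1), "N": np.zeros(1)}
        ends = []
        for dt in (0.2, 0.1, 0.05):
            traj = simulate(p, init, np.array([0.0, 4.0]), dom, dt_max=dt)
            ends.append(traj.fields["A"][-1, 0])
        order = np.log2(abs(ends[0] - ends[1]) / abs(ends[1] - ends[2]))
        assert 0.8 <= order <= 1.2


class _ConstPolicy:
    def __init__(self, dA=0.0, dtau=0.0):
        self._dA, self._dtau = dA, dtau

    def dose_A(self, t):
        return self._dA

    def dose_tau(self, t):
        return self._dtau


class TestTreatedSimulation:
    def test_zero_dose_bitwise_identical(self, graph10):
        dom, _ = graph10
        p = SimulationParams()
        rng = np.random.default_rng(1)
        init = {v: rng.uniform(0.1, 0.5, dom.n) for v in ("A", "tau", "N")}
        t = np.array([0.0, 1.0, 2.5])
        a = simulate(p, init, t, dom, dt_max=0.05)
        b = simulate_treated(p, _ConstPolicy(0.0, 0.0), init, t, dom,
                             dt_max=0.05)
        for v in ("A", "tau", "N"):
            np.testing.assert_array_equal(a.fields[v], b.fields[v])
        np.testing.assert_array_equal(a.C, b.C)

    def test_large_dose_suppresses_amyloid(self, graph10):
        dom, _ = graph10
        p = SimulationParams()
        init = {v: np.full(dom.n, 0.5) for v in ("A", "tau", "N")}
        t = np.array([0.0, 5.0])
        treated = simulate_treated(p, _ConstPolicy(dA=50.0), init, t, dom,
                                   dt_max=0.01)
        assert treated.fields["A"][-1].max() < init["A"].max()
        assert treated.fields["A"][-1].min() >= 0.0

    def test_dose_comparison_principle_single_node(self):
        dom = single_node()
        p = SimulationParams()
        init = {v: np.array([0.5]) for v in ("A", "tau", "N")}
        t = np.linspace(0.0, 8.0, 9)
        lo = simulate_treated(p, _ConstPolicy(dtau=0.1), init, t, dom,
                              dt_max=0.01)
        hi = simulate_treated(p, _ConstPolicy(dtau=0.5), init, t, dom,
                              dt_max=0.01)
        assert np.all(hi.fields["tau"] <= lo.fields["tau"] + 1e-12)


class TestCohortGeneration:
    def test_seed_determinism(self, graph10):
        dom, basis = graph10
        cfg = CohortConfig(n_patients=5, seed=21)
        c1 = generate_cohort(cfg, dom, basis=basis)
        c2 = generate_cohort(cfg, dom, basis=basis)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.times, b.times)
            for v in ("A", "tau", "N"):
                np.testing.assert_array_equal(a.fields[v], b.fields[v])
            np.testing.assert_array_equal(a.C, b.C)

    def test_zero_noise_matches_truth(self, graph10):
        dom, basis = graph10
        cfg = CohortConfig(n_patients=3, seed=5, noise_sigma=0.0)
        for traj in generate_cohort(cfg, dom, basis=basis):
            for v in ("A", "tau", "N"):
                np.testing.assert_array_equal(traj.fields[v],
                                              traj.truth_fields[v])

    def test_visit_count_schedule(self, graph10):
        dom, basis = graph10
        cfg = CohortConfig(n_patients=40, seed=3)
        counts = [t.n_visits for t in generate_cohort(cfg, dom, basis=basis)]
        assert set(counts) <= {3, 4, 5}
        # the seeded categorical draw is reproducible bookkeeping
        rng = np.random.default_rng(3)
        assert min(counts) >= 3 and max(counts) <= 5

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            CohortConfig(noise_sigma=-0.1)

    def test_time_rescaling_consistency(self, graph10):
        # simulating with gamma and sampling at t equals base dynamics at
        # gamma * t -- the construction used by the transfer experiments
        dom, basis = graph10
        cfg = CohortConfig(n_patients=2, seed=13, noise_sigma=0.0,
                           jitter_sigma=0.0, gamma_range=(2.0, 2.0),
                           visit_counts=3)
        fast = generate_cohort(cfg, dom, basis=basis)[0]
        base = SimulationParams()
        init = {v: fast.fields[v][0] for v in ("A", "tau", "N")}
        s_grid = 2.0 * (fast.times - fast.times[0])
        ref = simulate(fast.params, init, s_grid, dom, dt_max=cfg.dt_max)
        for v in ("A", "tau", "N"):
            np.testing.assert_allclose(fast.truth_fields[v], ref.fields[v],
                                       atol=1e-12)
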