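"""Synthetic ground-truth simulator for A-tau-N-C reaction-diffusion dynamics.

The generator integrates the coupled system

    dA/dt   - a_A Lap A    = l_A * A * (K_A - A)
    dtau/dt - a_t Lap tau  = (l_tA * A + l_tt * tau) * (K_t - tau)
    dN/dt   - a_N Lap N    = (l_Nt * tau + l_NN * N) * (K_N - N)
    dC/dt                  = (l_CN * <N> + l_CC) * (K_C - C)

under no-flux conditions, on either a triangulated 2D domain (P1 FEM) or a
weighted graph (combinatorial Laplacian).  ``<N>`` is the domain integral of
the neurodegeneration field on meshes and the regional mean on graphs.

Cohorts emulate longitudinal PET-derived regional data: each virtual patient
gets jittered kinetic parameters, a personal progression rate gamma (their
biology runs on the rescaled clock s = gamma * t), smooth random nonnegative
initial fields, 3-5 irregularly spaced visits, and multiplicative
observation noise.  The noise-free truth is retained for evaluation.

Default kinetics produce multi-decade sigmoid-like biomarker accumulation
with SUVR-like plateaus near 2 and an MMSE-like cognitive score that starts
near 29 and decays toward a floor of 0 at 1-3 points/year as
neurodegeneration accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domain import FemMatrices, GraphDomain, SpectralBasis, compute_basis

__all__ = [
    "SimulationParams",
    "Trajectory",
    "CohortConfig",
    "DomainOps",
    "step_system",
    "simulate",
    "simulate_treated",
    "generate_cohort",
    "true_reaction",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationParams:
    """Kinetic parameters of the generator; rates in 1/year."""

    alpha_A: float = 0.05
    alpha_tau: float = 0.05
    alpha_N: float = 0.05
    lam_A: float = 0.3
    lam_tauA: float = 0.2
    lam_tautau: float = 0.3
    lam_Ntau: float = 0.25
    lam_NN: float = 0.2
    lam_CN: float = 0.1
    lam_CC: float = 0.02
    K_A: float = 2.0
    K_tau: float = 2.0
    K_N: float = 2.0
    K_C: float = 0.0
    c0: float = 29.0

    def __post_init__(self) -> None:
        for name in ("alpha_A", "alpha_tau", "alpha_N", "lam_A", "lam_tauA",
                     "lam_tautau", "lam_Ntau", "lam_NN", "lam_CN", "lam_CC",
                     "K_A", "K_tau", "K_N", "K_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def alpha(self, variable: str) -> float:
        return {"A": self.alpha_A, "tau": self.alpha_tau, "N": self.alpha_N}[variable]


@dataclass
class Trajectory:
    """One patient's sampled trajectory (observed and, if synthetic, true)."""

    patient_id: str
    times: np.ndarray                    # ages in years, strictly increasing
    fields: dict[str, np.ndarray]        # variable -> (n_times, n_nodes)
    C: np.ndarray                        # (n_times,)
    params: SimulationParams | None = None
    gamma_true: float = 1.0
    truth_fields: dict[str, np.ndarray] | None = None
    truth_C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")

    @property
    def n_visits(self) -> int:
        return self.times.shape[0]


# --------------------------------------------------------------------------
# domain operations shared by simulator and learner
# --------------------------------------------------------------------------

class DomainOps:
    """Uniform interface over mesh (FEM) and graph domains.

    Provides the semi-implicit diffusion solve, the domain average, and
    nodal application of the Laplacian.  Factorizations of
    ``(M + dt*alpha*K)`` / ``(I + dt*alpha*L)`` are cached per (alpha, dt).
    """

    def __init__(self, domain: FemMatrices | GraphDomain):
        self.domain = domain
        self._cache: dict[tuple[float, float], object] = {}
        if isinstance(domain, FemMatrices):
            self.is_mesh = True
            self.n = domain.n
            self._lumped = np.asarray(domain.mass.sum(axis=1)).ravel()
            self.total_measure = float(self._lumped.sum())
        elif isinstance(domain, GraphDomain):
            self.is_mesh = False
            self.n = domain.n
        else:
            raise TypeError(f"unsupported domain {type(domain)!r}")

    def mean(self, u: np.ndarray) -> float:
        """Domain integral on meshes; arithmetic node mean on graphs."""
        if self.is_mesh:
            return float(self._lumped @ u)
        return float(np.mean(u))

    def laplacian_term(self, u: np.ndarray) -> np.ndarray:
        """Nodal diffusion operator (stiffness / graph Laplacian) applied to u."""
        if self.is_mesh:
            return self.domain.stiffness @ u
        return self.domain.L @ u

    def implicit_diffusion(self, u_plus_dtf: np.ndarray, alpha: float,
                           dt: float) -> np.ndarray:
        """Solve the implicit diffusion update for one substep."""
        if alpha == 0.0:
            return u_plus_dtf
        key = (float(alpha), float(dt))
        solver = self._cache.get(key)
        if self.is_mesh:
            if solver is None:
                A = (self.domain.mass + dt * alpha * self.domain.stiffness).tocsc()
                solver = spla.factorized(A)
                self._cache[key] = solver
            return solver(self.domain.mass @ u_plus_dtf)
        if solver is None:
            A = np.eye(self.n) + dt * alpha * self.domain.L
            import scipy.linalg as sla

            solver = sla.lu_factor(A)
            self._cache[key] = solver
        import scipy.linalg as sla

        return sla.lu_solve(solver, u_plus_dtf)


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def true_reaction(state: dict[str, np.ndarray], params: SimulationParams,
                  ops: DomainOps) -> dict[str, np.ndarray]:
    """Nodal reaction terms F1, F2, F3 and the scalar C rate at a state."""
    A, tau, N = state["A"], state["tau"], state["N"]
    C = state.get("C", params.c0)
    f1 = params.lam_A * A * (params.K_A - A)
    f2 = (params.lam_tauA * A + params.lam_tautau * tau) * (params.K_tau - tau)
    f3 = (params.lam_Ntau * tau + params.lam_NN * N) * (params.K_N - N)
    fC = (params.lam_CN * ops.mean(N) + params.lam_CC) * (params.K_C - C)
    return {"A": f1, "tau": f2, "N": f3, "C": fC}


def step_system(state: dict[str, np.ndarray | float], params: SimulationParams,
                dt: float, ops: DomainOps,
                dose_A: float = 0.0, dose_tau: float = 0.0) -> dict:
    """One semi-implicit step: explicit reactions, implicit diffusion.

    ``dose_A``/``dose_tau`` are clearance rates (1/year) of anti-amyloid /
    anti-tau interventions, entering as sink terms ``-d*A`` and ``-d*tau``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = true_reaction(state, params, ops)
    new = {}
    for var, alpha in (("A", params.alpha_A), ("tau", params.alpha_tau),
                       ("N", params.alpha_N)):
        rate = f[var]
        if var == "A" and dose_A:
            rate = rate - dose_A * state["A"]
        elif var == "tau" and dose_tau:
            rate = rate - dose_tau * state["tau"]
        u = state[var] + dt * rate
        new[var] = ops.implicit_diffusion(u, alpha, dt)
    new["C"] = state["C"] + dt * f["C"]
    for var in ("A", "tau", "N"):
        if not np.all(np.isfinite(new[var])):
            raise IntegrationError(f"non-finite {var} after step of size {dt}")
    return new


def _run(params: SimulationParams, initial_fields: dict[str, np.ndarray],
         t_grid: np.ndarray, ops: DomainOps, dt_max: float,
         dose_A=None, dose_tau=None, c0: float | None = None) -> Trajectory:
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    state = {v: np.asarray(initial_fields[v], dtype=float).copy()
             for v in ("A", "tau", "N")}
    for v in ("A", "tau", "N"):
        if np.any(state[v] < 0):
            raise ValueError(f"initial {v} field must be nonnegative")
    state["C"] = params.c0 if c0 is None else float(c0)

    out_fields = {v: [state[v].copy()] for v in ("A", "tau", "N")}
    out_C = [state["C"]]
    t = t_grid[0]
    for t_next in t_grid[1:]:
        span = t_next - t
        n_sub = max(1, int(np.ceil(span / dt_max - 1e-12)))
        dt = span / n_sub
        for k in range(n_sub):
            tk = t + k * dt
            dA = float(dose_A(tk)) if dose_A is not None else 0.0
            dtau = float(dose_tau(tk)) if dose_tau is not None else 0.0
            try:
                state = step_system(state, params, dt, ops,
                                    dose_A=dA, dose_tau=dtau)
            except IntegrationError as exc:
                raise IntegrationError(f"{exc} (t = {tk + dt:.4f})") from exc
        t = t_next
        for v in ("A", "tau", "N"):
            out_fields[v].append(state[v].copy())
        out_C.append(state["C"])
    return Trajectory(
        patient_id="sim",
        times=t_grid,
        fields={v: np.array(out_fields[v]) for v in ("A", "tau", "N")},
        C=np.array(out_C),
        params=params,
    )


def simulate(params: SimulationParams, initial_fields: dict[str, np.ndarray],
             t_grid: np.ndarray, domain: FemMatrices | GraphDomain | DomainOps,
             dt_max: float = 0.01, c0: float | None = None) -> Trajectory:
    """Integrate the untreated system, sampling at ``t_grid``."""
    ops = domain if isinstance(domain, DomainOps) else DomainOps(domain)
    return _run(params, initial_fields, t_grid, ops, dt_max, c0=c0)


def simulate_treated(params: SimulationParams, policy,
                     initial_fields: dict[str, np.ndarray], t_grid: np.ndarray,
                     domain: FemMatrices | GraphDomain | DomainOps,
                     dt_max: float = 0.01, c0: float | None = None) -> Trajectory:
    """Integrate with anti-amyloid / anti-tau clearance terms from ``policy``.

    ``policy`` must expose callables ``dose_A(t)`` and ``dose_tau(t)``
    (see :mod:`lapdyn.treatment`); with both identically zero the result is
    bitwise identical to :func:`simulate`.
    """
    ops = domain if isinstance(domain, DomainOps) else DomainOps(domain)
    return _run(params, initial_fields, t_grid, ops, dt_max,
                dose_A=policy.dose_A, dose_tau=policy.dose_tau, c0=c0)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design knobs for a virtual longitudinal cohort."""

    n_patients: int = 20
    params: SimulationParams = field(default_factory=SimulationParams)
    jitter_sigma: float = 0.05       # lognormal sd of per-patient rate jitter
    progression_sigma: float = 0.2   # lognormal sd of gamma (progression rate)
    gamma_range: tuple[float, float] | None = None  # overrides lognormal draw
    noise_sigma: float = 0.02        # multiplicative observation noise
    seed: int = 0
    visit_counts: dict[int, float] | int = field(
        default_factory=lambda: {3: 0.3, 4: 0.4, 5: 0.3})
    baseline_age_range: tuple[float, float] = (60.0, 75.0)
    visit_gap_range: tuple[float, float] = (0.8, 2.0)
    dt_max: float = 0.01
    init_levels: dict[str, float] = field(
        default_factory=lambda: {"A": 0.4, "tau": 0.25, "N": 0.25})
    init_amplitude: float = 0.15
    init_modes: int = 8

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


_JITTERED = ("lam_A", "lam_tauA", "lam_tautau", "lam_Ntau", "lam_NN",
             "lam_CN", "lam_CC", "alpha_A", "alpha_tau", "alpha_N")


def _smooth_initial_field(rng: np.random.Generator, basis: SpectralBasis,
                          level: float, amplitude: float, n_modes: int) -> np.ndarray:
    """Nonnegative smooth random field: constant plus a few low eigenmodes."""
    n_modes = min(n_modes, basis.P)
    coeffs = rng.normal(size=n_modes - 1) if n_modes > 1 else np.zeros(0)
    u = np.full(basis.n, level)
    if coeffs.size:
        modes = basis.vectors[:, 1:n_modes]
        bump = modes @ coeffs
        scale = amplitude / max(np.abs(bump).max(), 1e-12)
        u = u + scale * bump
    return np.clip(u, 0.05 * level, None)


def generate_cohort(config: CohortConfig,
                    domain: FemMatrices | GraphDomain,
                    basis: SpectralBasis | None = None) -> list[Trajectory]:
    """Draw a reproducible virtual cohort.

    Each patient's fields at age ``t`` equal the base dynamics evaluated at
    the personal disease time ``s = gamma * (t - t_baseline)``, so a fast
    progressor (gamma > 1) traverses the same trajectory sooner.
    """
    rng = np.random.default_rng(config.seed)
    ops = DomainOps(domain)
    if basis is None:
        basis = compute_basis(domain, min(max(config.init_modes, 2), ops.n))
    patients: list[Trajectory] = []
    for p in range(config.n_patients):
        jitter = {name: float(np.exp(config.jitter_sigma * rng.normal()))
                  for name in _JITTERED}
        params = replace(config.params, **{
            name: getattr(config.params, name) * jitter[name]
            for name in _JITTERED})
        if config.gamma_range is not None:
            lo, hi = config.gamma_range
            gamma = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            gamma = float(np.exp(config.progression_sigma * rng.normal()))

        if isinstance(config.visit_counts, int):
            n_visits = config.visit_counts
        else:
            counts = sorted(config.visit_counts)
            probs = np.array([config.visit_counts[c] for c in counts], float)
            n_visits = int(rng.choice(counts, p=probs / probs.sum()))
        t0 = rng.uniform(*config.baseline_age_range)
        gaps = rng.uniform(*config.visit_gap_range, size=n_visits - 1)
        ages = t0 + np.concatenate([[0.0], np.cumsum(gaps)])

        init = {v: _smooth_initial_field(rng, basis, config.init_levels[v],
                                         config.init_amplitude, config.init_modes)
                for v in ("A", "tau", "N")}
        s_grid = gamma * (ages - ages[0])
        # strictly increasing by construction (gamma > 0, gaps > 0)
        traj = _run(params, init, s_grid, ops, config.dt_max)
        truth_fields = {v: traj.fields[v] for v in ("A", "tau", "N")}
        truth_C = traj.C
        obs_fields = {}
        for v in ("A", "tau", "N"):
            eps = rng.normal(size=truth_fields[v].shape)
            obs_fields[v] = truth_fields[v] * (1.0 + config.noise_sigma * eps)
        epsC = rng.normal(size=truth_C.shape)
        obs_C = truth_C * (1.0 + config.noise_sigma * epsC)
        patients.append(Trajectory(
            patient_id=f"P{p:03d}",
            times=ages,
            fields=obs_fields,
            C=obs_C,
            params=params,
            gamma_true=gamma,
            truth_fields=truth_fields,
            truth_C=truth_C,
        ))
    return patients
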