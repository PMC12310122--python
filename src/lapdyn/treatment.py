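"""In-silico treatment policies on the learned patient model.

Anti-amyloid and anti-tau interventions enter the learned dynamics as
clearance (sink) terms ``-d_A(t) * A`` and ``-d_tau(t) * tau``.  Because
the doses are spatially uniform scalars, the sinks are exact in spectral
coordinates (``-d * beta``), with no basis-truncation error.

Dose schedules are small time-networks squashed through a sigmoid and
scaled by a hard cap ``d_max``, so ``0 <= d(t) <= d_max`` holds
structurally for any weights.  Schedules are optimized by monotone
(backtracking) gradient descent on

    J = -C(T) + eta_A * int d_A(t)^2 dt + eta_tau * int d_tau(t)^2 dt,

i.e. maximize the terminal cognitive score under a quadratic treatment
burden; gradients are exact reverse-mode sweeps through the coupled
rollout with all disease/cognition networks frozen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cognition import CognitiveModel
from .nn import MLP, sigmoid
from .operator import NeuralOperatorModel, TRAIN_ORDER

logger = logging.getLogger(__name__)

__all__ = ["TreatmentPolicy", "PolicyOptConfig", "rollout_treated",
           "optimize_policy", "compare_strategies", "SCENARIOS"]

SCENARIOS = ("none", "anti-A", "anti-tau", "combined")


@dataclass
class TreatmentPolicy:
    """Bounded time-varying clearance-rate schedules d_A(t), d_tau(t)."""

    mode: str = "combined"
    t0: float = 0.0
    horizon: float = 10.0
    d_max: float = 1.0
    eta_A: float = 0.1
    eta_tau: float = 0.1
    hidden: int = 32
    seed: int = 0
    net_A: MLP = field(default=None, repr=False)
    net_tau: MLP = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in SCENARIOS:
            raise ValueError(f"unknown treatment mode {self.mode!r}; "
                             f"choose from {SCENARIOS}")
        if self.d_max < 0:
            raise ValueError("d_max must be nonnegative")
        if self.net_A is None:
            self.net_A = MLP([1, self.hidden, 1], seed=self.seed,
                             final_scale=0.3)
        if self.net_tau is None:
            self.net_tau = MLP([1, self.hidden, 1], seed=self.seed + 1,
                               final_scale=0.3)

    @property
    def active_A(self) -> bool:
        return self.mode in ("anti-A", "combined") and self.d_max > 0

    @property
    def active_tau(self) -> bool:
        return self.mode in ("anti-tau", "combined") and self.d_max > 0

    def _tn(self, t):
        return (np.asarray(t, float) - self.t0) / max(self.horizon, 1e-12)

    def dose_A(self, t):
        if not self.active_A:
            return np.zeros_like(np.asarray(t, float)) if np.ndim(t) else 0.0
        y = self.net_A.forward(np.atleast_2d(self._tn(t)).T)[:, 0]
        d = self.d_max * sigmoid(y)
        return d if np.ndim(t) else float(d[0])

    def dose_tau(self, t):
        if not self.active_tau:
            return np.zeros_like(np.asarray(t, float)) if np.ndim(t) else 0.0
        y = self.net_tau.forward(np.atleast_2d(self._tn(t)).T)[:, 0]
        d = self.d_max * sigmoid(y)
        return d if np.ndim(t) else float(d[0])

    # flat parameter vector over the active dose networks
    def get_params(self) -> np.ndarray:
        parts = []
        if self.active_A:
            parts.append(self.net_A.theta)
        if self.active_tau:
            parts.append(self.net_tau.theta)
        return np.concatenate(parts) if parts else np.zeros(0)

    def set_params(self, flat: np.ndarray) -> None:
        pos = 0
        if self.active_A:
            n = self.net_A.theta.size
            self.net_A.theta = flat[pos : pos + n].copy()
            pos += n
        if self.active_tau:
            n = self.net_tau.theta.size
            self.net_tau.theta = flat[pos : pos + n].copy()


@dataclass
class PolicyOptConfig:
    iterations: int = 80
    step0: float = 1.0
    armijo: float = 1e-4
    min_step: float = 1e-8
    dt_max: float = 0.1


def _forward(models, cog, policy, start, c0, t0, horizon, dt_max, gamma,
             need_tape=False):
    K = max(1, int(np.ceil(horizon / dt_max - 1e-12)))
    dt = horizon / K
    lam = {v: models[v].basis.eigenvalues for v in TRAIN_ORDER}
    alph = {v: models[v].alpha for v in TRAIN_ORDER}
    state = {v: np.asarray(start[v], float).copy() for v in TRAIN_ORDER}
    C = float(c0)
    times = t0 + dt * np.arange(K + 1)
    path = {v: [state[v].copy()] for v in TRAIN_ORDER}
    Cs = [C]
    dA_list, dtau_list = [], []
    tape = []
    for k in range(K):
        tk = t0 + k * dt
        dA = policy.dose_A(tk)
        dtau = policy.dose_tau(tk)
        x = {"A": state["A"],
             "tau": np.concatenate([state["A"], state["tau"]]),
             "N": np.concatenate([state["A"], state["tau"], state["N"]])}
        g, caches = {}, {}
        for v in TRAIN_ORDER:
            g[v], caches[v] = models[v].net.forward(x[v], need_cache=True)
        rate_C, cacheC = cog.net.forward(state["N"][None, :], need_cache=True)
        rate_C = float(rate_C[0, 0])
        new = {}
        for v, dose in (("A", dA), ("tau", dtau), ("N", 0.0)):
            den = 1.0 + dt * gamma * alph[v] * lam[v]
            new[v] = (state[v] + dt * (gamma * g[v] - dose * state[v])) / den
        C_new = C + dt * gamma * rate_C
        if need_tape:
            tape.append({"state": state, "g": g, "caches": caches,
                         "cacheC": cacheC, "dA": dA, "dtau": dtau,
                         "tk": tk, "new": new})
        state, C = new, C_new
        for v in TRAIN_ORDER:
            path[v].append(state[v].copy())
        Cs.append(C)
        dA_list.append(dA)
        dtau_list.append(dtau)
    out = {"times": times, "C": np.array(Cs),
           "betas": {v: np.array(path[v]) for v in TRAIN_ORDER},
           "dose_A": np.array(dA_list), "dose_tau": np.array(dtau_list),
           "dt": dt, "K": K}
    if need_tape:
        out["tape"] = tape
    return out


def rollout_treated(models: dict[str, NeuralOperatorModel],
                    cog: CognitiveModel, policy: TreatmentPolicy,
                    start: dict[str, np.ndarray], c0: float, t0: float,
                    horizon: float, dt_max: float = 0.1,
                    gamma: float = 1.0) -> dict:
    """Coupled treated rollout of (A, tau, N, C) from spectral state ``start``.

    With an all-zero policy (mode "none" or ``d_max = 0``) the result is
    bitwise identical to the untreated rollout on the same substep grid.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return _forward(models, cog, policy, start, c0, t0, horizon, dt_max,
                    gamma)


def _objective_and_grad(models, cog, policy, start, c0, t0, horizon,
                        dt_max, gamma):
    roll = _forward(models, cog, policy, start, c0, t0, horizon, dt_max,
                    gamma, need_tape=True)
    dt, K = roll["dt"], roll["K"]
    dA, dtau = roll["dose_A"], roll["dose_tau"]
    J = -roll["C"][-1] + policy.eta_A * float(np.sum(dA**2)) * dt \
        + policy.eta_tau * float(np.sum(dtau**2)) * dt

    lam = {v: models[v].basis.eigenvalues for v in TRAIN_ORDER}
    alph = {v: models[v].alpha for v in TRAIN_ORDER}
    P = models["A"].P
    dstate = {v: np.zeros(P) for v in TRAIN_ORDER}
    dC = -1.0
    gA = np.zeros(policy.net_A.theta.size)
    gTau = np.zeros(policy.net_tau.theta.size)
    for k in range(K - 1, -1, -1):
        rec = roll["tape"][k]
        state, g = rec["state"], rec["g"]
        dd = {"A": 2.0 * policy.eta_A * dt * dA[k],
              "tau": 2.0 * policy.eta_tau * dt * dtau[k]}
        dnew = dstate
        dstate = {v: np.zeros(P) for v in TRAIN_ORDER}
        # C update: C' = C + dt*gamma*rate(beta_N at step start)
        dxN_C, _ = cog.net.vjp(rec["cacheC"], np.array([[dC * dt * gamma]]),
                               need_param_grads=False)
        dstate["N"] += dxN_C[0]
        for v, dose in (("A", rec["dA"]), ("tau", rec["dtau"]), ("N", 0.0)):
            den = 1.0 + dt * gamma * alph[v] * lam[v]
            dg_v = dnew[v] * dt * gamma / den
            dstate[v] += dnew[v] * (1.0 - dt * dose) / den
            if v in dd:
                dd[v] += float(np.sum(dnew[v] * (-dt * state[v] / den)))
            dx, _ = models[v].net.vjp(rec["caches"][v], dg_v,
                                      need_param_grads=False)
            dx = np.atleast_2d(dx)[0]
            if v == "A":
                dstate["A"] += dx
            elif v == "tau":
                dstate["A"] += dx[:P]
                dstate["tau"] += dx[P:]
            else:
                dstate["A"] += dx[:P]
                dstate["tau"] += dx[P : 2 * P]
                dstate["N"] += dx[2 * P :]
        # dose nets: d = d_max * sigmoid(y)
        tn = np.array([[policy._tn(rec["tk"])]])
        if policy.active_A:
            y = policy.net_A.forward(tn, need_cache=True)
            yv, cache = y
            s = sigmoid(yv[0, 0])
            _, gth = policy.net_A.vjp(cache,
                                      np.array([[dd["A"] * policy.d_max *
                                                 s * (1 - s)]]))
            gA += gth
        if policy.active_tau:
            yv, cache = policy.net_tau.forward(tn, need_cache=True)
            s = sigmoid(yv[0, 0])
            _, gth = policy.net_tau.vjp(cache,
                                        np.array([[dd["tau"] * policy.d_max *
                                                   s * (1 - s)]]))
            gTau += gth
    parts = []
    if policy.active_A:
        parts.append(gA)
    if policy.active_tau:
        parts.append(gTau)
    grad = np.concatenate(parts) if parts else np.zeros(0)
    return J, grad, roll


def optimize_policy(models: dict[str, NeuralOperatorModel],
                    cog: CognitiveModel, start: dict[str, np.ndarray],
                    c0: float, t0: float, horizon: float,
                    eta_A: float = 0.1, eta_tau: float = 0.1,
                    mode: str = "combined", d_max: float = 1.0,
                    config: PolicyOptConfig | None = None,
                    seed: int = 0) -> tuple[TreatmentPolicy, np.ndarray]:
    """Optimize dose schedules; returns (policy, objective trace).

    The backtracking line search only accepts decreasing steps, so the
    returned trace is non-increasing.
    """
    if eta_A < 0 or eta_tau < 0:
        raise ValueError("regularization weights must be nonnegative")
    cfg = config or PolicyOptConfig()
    policy = TreatmentPolicy(mode=mode, t0=t0, horizon=horizon, d_max=d_max,
                             eta_A=eta_A, eta_tau=eta_tau, seed=seed)
    if not (policy.active_A or policy.active_tau):
        J, _, _ = _objective_and_grad(models, cog, policy, start, c0, t0,
                                      horizon, cfg.dt_max, 1.0)
        return policy, np.array([J])

    params = policy.get_params()
    J, grad, _ = _objective_and_grad(models, cog, policy, start, c0, t0,
                                     horizon, cfg.dt_max, 1.0)
    if not np.isfinite(J):
        raise RuntimeError("non-finite treatment objective at initialization")
    trace = [J]
    step = cfg.step0
    for _ in range(cfg.iterations):
        gnorm2 = float(grad @ grad)
        if gnorm2 < 1e-18:
            break
        accepted = False
        while step >= cfg.min_step:
            trial = params - step * grad
            policy.set_params(trial)
            J_new, grad_new, _ = _objective_and_grad(
                models, cog, policy, start, c0, t0, horizon, cfg.dt_max, 1.0)
            if np.isfinite(J_new) and J_new <= J - cfg.armijo * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            policy.set_params(params)
            break
        params, J, grad = trial, J_new, grad_new
        trace.append(J)
        step = min(step * 2.0, cfg.step0)
    policy.set_params(params)
    return policy, np.array(trace)


def compare_strategies(models: dict[str, NeuralOperatorModel],
                       cog: CognitiveModel, start: dict[str, np.ndarray],
                       c0: float, t0: float, horizon: float,
                       scenarios: tuple[str, ...] = SCENARIOS,
                       eta_A: float = 0.1, eta_tau: float = 0.1,
                       d_max: float = 1.0,
                       config: PolicyOptConfig | None = None,
                       seed: int = 0) -> dict:
    """Optimize each treatment arm independently and rank final scores."""
    cfg = config or PolicyOptConfig()
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenario label(s) {sorted(unknown)}")
    report: dict[str, dict] = {}
    for sc in scenarios:
        policy, trace = optimize_policy(models, cog, start, c0, t0, horizon,
                                        eta_A=eta_A, eta_tau=eta_tau,
                                        mode=sc, d_max=d_max, config=cfg,
                                        seed=seed)
        roll = rollout_treated(models, cog, policy, start, c0, t0, horizon,
                               dt_max=cfg.dt_max)
        report[sc] = {"policy": policy, "objective_trace": trace,
                      "times": roll["times"], "C": roll["C"],
                      "dose_A": roll["dose_A"], "dose_tau": roll["dose_tau"],
                      "final_C": float(roll["C"][-1])}
    ranking = sorted(report, key=lambda sc: -report[sc]["final_C"])
    report["ranking"] = ranking
    return report
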