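"""Learning and forecasting cognitive-score dynamics.

The scalar score C (MMSE-like) evolves as ``dC/dt = N4(beta_N)`` where
``beta_N`` is the spectral projection of the regional neurodegeneration
profile and ``N4`` is a small trainable network.  Training integrates the
ODE with forward Euler across each inter-visit interval, restarting from
the observed score at the interval start (teacher forcing), with the
neurodegeneration input linearly interpolated in spectral coordinates;
the integrated increments are matched to the observed score changes.

Note the learned form deliberately depends on the neurodegeneration state
only, not on C itself; any self-limiting behavior present in the data is
absorbed implicitly through the co-evolution of N and C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import Trajectory
from .domain import SpectralBasis
from .nn import MLP, Adam, PooledScalarNet, ScaledMLP
from .operator import project_cohort

logger = logging.getLogger(__name__)

__all__ = ["CognitiveModel", "CognitionTrainConfig", "train_cognitive",
           "predict_cognitive", "save_cognitive", "load_cognitive"]


@dataclass
class CognitionTrainConfig:
    lr: float = 3e-3
    iterations: int = 1500
    dt_max: float = 0.1
    hidden: tuple[int, ...] = (64, 64)
    # "pooled": permutation-invariant read-out h(mean_i g(u_i)) of the
    # nodal neurodegeneration reconstruction -- matches the integral
    # structure of the score dynamics and generalizes across spatial
    # patterns; "dense": plain MLP on the spectral coefficients.
    architecture: str = "pooled"
    weight_decay: float = 1e-4
    # Optional per-iteration jitter of the neurodegeneration inputs
    # (fraction of their per-dimension spread, targets clean).  Off by
    # default: the dominant input mode carries the disease-stage signal
    # and jittering it attenuates the fitted rate's stage dependence.
    input_noise: float = 0.0
    seed: int = 0
    lr_decay: bool = True


@dataclass
class CognitiveModel:
    """Trainable map from the neurodegeneration profile to dC/dt."""

    net: ScaledMLP
    basis: SpectralBasis
    c_scale: float = 1.0
    final_loss: float = field(default=float("nan"), repr=False)

    def rate(self, beta_N: np.ndarray) -> float | np.ndarray:
        out = self.net.forward(np.atleast_2d(beta_N))[:, 0]
        return float(out[0]) if np.ndim(beta_N) == 1 else out


def _prepare(records: list[dict], gammas: np.ndarray | None, dt_max: float):
    """Per-patient substep inputs and bookkeeping for Euler integration."""
    prep = []
    for i, r in enumerate(records):
        t, C = r["times"], r["C"]
        bN = r["beta"]["N"]
        good = np.isfinite(C)
        if good.sum() < 2:
            logger.warning("patient %s: fewer than 2 usable C visits; skipped",
                           r["patient_id"])
            continue
        if not good.all():
            logger.warning("patient %s: %d C visits without scores skipped",
                           r["patient_id"], int((~good).sum()))
        t, C, bN = t[good], C[good], bN[good]
        gamma = 1.0 if gammas is None else float(gammas[i])
        xs, dts, interval_idx = [], [], []
        for n in range(1, len(t)):
            gap = t[n] - t[n - 1]
            K = max(1, int(np.ceil(gap / dt_max - 1e-12)))
            dt = gamma * gap / K
            for k in range(K):
                frac = k / K
                xs.append(bN[n - 1] + frac * (bN[n] - bN[n - 1]))
                dts.append(dt)
                interval_idx.append(n - 1)
        prep.append({"X": np.array(xs), "dt": np.array(dts),
                     "iidx": np.array(interval_idx), "C": C,
                     "n_int": len(t) - 1})
    if not prep:
        raise ValueError("no patient has two or more usable C observations")
    return prep


def train_cognitive(cohort: list[Trajectory] | list[dict],
                    basis: SpectralBasis,
                    config: CognitionTrainConfig | None = None,
                    gammas: np.ndarray | None = None) -> CognitiveModel:
    """Fit N4 by matching Euler-integrated scores to observations.

    The loss is the mean over patients of the mean squared mismatch of the
    integrated curve at every post-baseline visit, in units of the cohort
    score scale; duplicated patients therefore do not change the fit.
    """
    cfg = config or CognitionTrainConfig()
    if cohort and isinstance(cohort[0], dict):
        records = cohort
    else:
        records = project_cohort(cohort, basis)
    prep = _prepare(records, gammas, cfg.dt_max)

    allX = np.vstack([p["X"] for p in prep])
    allC = np.concatenate([p["C"] for p in prep])
    c_scale = float(np.std(allC)) or 1.0
    if cfg.architecture == "pooled":
        U = allX @ basis.vectors.T
        u_mu, u_sd = float(U.mean()), float(U.std()) or 1.0
        inner = MLP([1, 16, 8], seed=cfg.seed, final_scale=1.0)
        head = MLP([8, 16, 1], seed=cfg.seed + 1, final_scale=0.1)
        net = PooledScalarNet(inner, head, phi=basis.vectors,
                              mu=u_mu, sigma=u_sd, out_scale=c_scale)
    else:
        mu, sig, _ = ScaledMLP.fit_scaling(allX)
        sizes = [basis.P, *cfg.hidden, 1]
        net = ScaledMLP(MLP(sizes, seed=cfg.seed, final_scale=0.1),
                        mu=mu, sigma=sig, out_scale=c_scale)

    x_jitter_scale = allX.std(axis=0)
    theta = net.theta.copy()
    opt = Adam(theta.size, lr=cfg.lr)
    M = len(prep)
    loss = np.nan
    aug_rng = np.random.default_rng(cfg.seed + 7)
    for it in range(cfg.iterations):
        loss = cfg.weight_decay * float(theta @ theta)
        dtheta = 2.0 * cfg.weight_decay * theta
        for p in prep:
            X_in = p["X"]
            if cfg.input_noise > 0:
                # leave the dominant (domain-mean) mode clean: it carries
                # the disease-stage signal the rate depends on
                jit = aug_rng.normal(size=X_in.shape) * \
                    (cfg.input_noise * x_jitter_scale)
                jit[:, 0] = 0.0
                X_in = X_in + jit
            rates, cache = net.forward(X_in, theta=theta, need_cache=True)
            rates = rates[:, 0]
            # per-interval increments, teacher-forced at the interval start
            steps = rates * p["dt"]
            inc = np.zeros(p["n_int"])
            np.add.at(inc, p["iidx"], steps)
            C_pred = p["C"][:-1] + inc
            diff = (C_pred - p["C"][1:]) / c_scale
            loss += float(np.mean(diff**2)) / M
            e = 2.0 * diff / (c_scale * p["n_int"] * M)
            coeff = (e[p["iidx"]] * p["dt"])[:, None]
            _, g = net.vjp(cache, coeff, theta=theta)
            dtheta += g
        if not np.isfinite(loss):
            raise RuntimeError(f"cognitive training diverged at iteration {it}")
        if cfg.lr_decay:
            opt.lr = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * it / cfg.iterations))
        theta = opt.step(theta, dtheta)
    net.theta = theta
    return CognitiveModel(net=net, basis=basis, c_scale=c_scale,
                          final_loss=float(loss))


def save_cognitive(model: CognitiveModel, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("theta", data=model.net.theta, track_times=False)
        fh.create_dataset("x_mu", data=np.atleast_1d(model.net.mu),
                          track_times=False)
        fh.create_dataset("x_sigma", data=np.atleast_1d(model.net.sigma),
                          track_times=False)
        fh.attrs["out_scale"] = model.net.out_scale
        fh.attrs["c_scale"] = model.c_scale
        if isinstance(model.net, PooledScalarNet):
            fh.attrs["arch"] = "pooled"
            fh.attrs["sizes_inner"] = model.net.inner.sizes
            fh.attrs["sizes_head"] = model.net.head.sizes
        else:
            fh.attrs["arch"] = "dense"
            fh.attrs["sizes"] = model.net.sizes


def load_cognitive(path: str, basis: SpectralBasis) -> CognitiveModel:
    import h5py

    with h5py.File(path, "r") as fh:
        arch = str(fh.attrs.get("arch", "dense"))
        if arch == "pooled":
            inner = MLP([int(s) for s in fh.attrs["sizes_inner"]], seed=0)
            head = MLP([int(s) for s in fh.attrs["sizes_head"]], seed=0)
            net = PooledScalarNet(inner, head, phi=basis.vectors,
                                  mu=float(fh["x_mu"][()][0]),
                                  sigma=float(fh["x_sigma"][()][0]),
                                  out_scale=float(fh.attrs["out_scale"]))
        else:
            net = ScaledMLP(MLP([int(s) for s in fh.attrs["sizes"]], seed=0),
                            mu=fh["x_mu"][()], sigma=fh["x_sigma"][()],
                            out_scale=float(fh.attrs["out_scale"]))
        net.theta = fh["theta"][()]
        c_scale = float(fh.attrs["c_scale"])
    return CognitiveModel(net=net, basis=basis, c_scale=c_scale)


def predict_cognitive(model: CognitiveModel, times_N: np.ndarray,
                      beta_N: np.ndarray, c0: float,
                      target_times: np.ndarray, gamma: float = 1.0,
                      dt_max: float = 0.1) -> np.ndarray:
    """Integrate dC/dt = N4(beta_N(t)) from ``c0`` at ``times_N[0]``.

    ``beta_N`` is (T, P) at ``times_N``; it is linearly interpolated in
    spectral coordinates and held constant beyond its last sample.  With a
    personal clock, model time advances ``gamma`` per patient-year.
    """
    times_N = np.asarray(times_N, float)
    beta_N = np.atleast_2d(beta_N)
    target_times = np.asarray(target_times, float)
    t0 = times_N[0]
    if np.any(target_times < t0 - 1e-12):
        raise ValueError("target times must not precede the first N sample")
    out = []
    C = float(c0)
    t = t0
    for tt in target_times:
        span = tt - t
        if span > 1e-12:
            K = max(1, int(np.ceil(span / dt_max - 1e-12)))
            dt = span / K
            for k in range(K):
                tk = t + k * dt
                bN = np.array([np.interp(tk, times_N, beta_N[:, j])
                               for j in range(beta_N.shape[1])])
                C += gamma * dt * model.rate(bN)
            t = tt
        out.append(C)
    return np.array(out)
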