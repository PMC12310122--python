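"""Neural operators in Laplacian-eigenfunction coordinates.

Each biomarker variable gets a reaction operator ``G`` acting on spectral
coefficients, together with a learnable nonnegative diffusion coefficient
``alpha``.  The discrete dynamics over one substep of size ``dt`` are the
semi-implicit (implicit diffusion, explicit reaction) update

    (beta - beta_prev)/dt + alpha * Lambda * beta = G(x_prev; theta),

solved mode-by-mode in closed form since ``Lambda`` is diagonal.  The input
``x`` concatenates the spectral coefficients of the variable's upstream
drivers with its own: following the amyloid-cascade ordering, the amyloid
operator sees only amyloid, the tau operator sees (amyloid, tau), and the
neurodegeneration operator sees all three; training is strictly sequential
in that order.

Training minimizes the sum of a trajectory-fit term (relative L2 mismatch
between the rolled-out scheme and the observed coefficients at every visit)
and a residual term (mismatch between ``G`` evaluated at one visit and the
discrete time-derivative-plus-diffusion residual over the following
inter-visit interval), optionally with a per-patient temporal scale that
absorbs heterogeneous progression rates.  All gradients are exact
reverse-mode propagations through the rollout, computed by hand on numpy
arrays (see :mod:`lapdyn.nn`).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

from .cohort import Trajectory
from .domain import SpectralBasis
from .nn import (MLP, Adam, NodalReactionNet, ScaledMLP, softplus,
                 softplus_inv, sigmoid)
from .projection import project

logger = logging.getLogger(__name__)

__all__ = [
    "PARENTS",
    "TRAIN_ORDER",
    "TrainConfig",
    "TrainReport",
    "NeuralOperatorModel",
    "implicit_step",
    "data_loss",
    "residual_loss",
    "project_cohort",
    "train_operator",
    "train_sequential",
    "predict_forward",
    "rollout_coupled",
    "jacobian_analysis",
    "JacobianReport",
    "save_models",
    "load_models",
]

PARENTS: dict[str, tuple[str, ...]] = {"A": (), "tau": ("A",), "N": ("A", "tau")}
TRAIN_ORDER: tuple[str, ...] = ("A", "tau", "N")


@dataclass
class TrainConfig:
    """Optimization settings for operator training."""

    lr: float = 3e-3
    iterations: int = 800
    dt_max: float = 0.1              # substep cap (years) for training rollouts
    weight_data: float = 1.0
    weight_residual: float = 1.0
    weight_decay: float = 1e-3
    # Small ridge on the reaction magnitude at observed states, normalized
    # by the squared data-velocity scale.  The split between diffusion and
    # a reaction component proportional to Lambda*beta is not identifiable
    # from trajectories alone (adding c to alpha and c*Lambda*beta to G
    # leaves the dynamics unchanged); this penalty selects the
    # minimal-reaction representative, which pins alpha.
    g_norm_weight: float = 1e-2
    # Operator architecture: "nodal" ties a small reaction network across
    # nodes (local-reaction inductive bias; generalizes across spatial
    # patterns); "dense" is an unconstrained MLP on the stacked spectral
    # coefficients (can represent nonlocal reactions, needs more data).
    architecture: str = "nodal"
    hidden_width: int | None = None  # dense net width; default 2 * P
    n_hidden: int = 2
    final_scale: float = 0.1
    seed: int = 0
    alpha_init: float = 0.05
    lr_decay: bool = True            # cosine decay of lr to 0 over iterations
    # Update alpha by an exact weighted least-squares solve of the interval
    # residual identity each iteration (it enters linearly), rather than by
    # gradient steps; Adam traverses the alpha/G degeneracy far too slowly.
    alpha_solve: bool = True
    # Fraction of iterations spent on a residual-regression warm start
    # (trajectory-fit weight zero).  The residual term is a plain
    # supervised regression with a benign landscape; warm-starting there
    # avoids the bad basins the rollout loss alone can fall into.
    pretrain_fraction: float = 0.3
    # Residual-term evaluation points: "left" matches the secant residual
    # R^n against G at the interval start (the rollout scheme's own
    # evaluation point); "trapezoid" matches it against the average of G at
    # both endpoints.  The trapezoid form is second-order accurate in the
    # interval length (the secant over a long inter-visit gap approximates
    # the mean derivative, not the left derivative) and, importantly,
    # supervises the operator at each patient's most advanced state --
    # exactly where forecasts launch from.
    residual_form: str = "trapezoid"
    # Input-noise augmentation: each iteration the network inputs (initial
    # rollout state, upstream coefficients, residual-regression inputs) are
    # jittered by this fraction of their per-dimension spread, targets left
    # clean.  Smooths the learned operator between the sparse observed
    # states and makes it robust to consuming its own forecasts.
    input_noise: float = 0.1
    # Independent restarts (seed, seed+1, ...); the run with the lowest
    # final combined loss is kept.
    n_restarts: int = 2
    per_patient_scale: bool = True
    early_stop_patience: int = 2000
    early_stop_tol: float = 1e-7
    max_substeps: int = 40


@dataclass
class TrainReport:
    loss_trace: np.ndarray
    data_loss: float
    residual_loss: float
    alpha: float
    xi: np.ndarray
    iterations_run: int


@dataclass
class NeuralOperatorModel:
    """Learned reaction operator + diffusion coefficient for one variable."""

    variable: str
    parents: tuple[str, ...]
    basis: SpectralBasis
    net: MLP
    raw_alpha: float
    train_report: TrainReport | None = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        return float(softplus(self.raw_alpha))

    @property
    def P(self) -> int:
        return self.basis.P

    def G(self, x: np.ndarray) -> np.ndarray:
        """Reaction operator on concatenated (parents..., self) coefficients."""
        return self.net.forward(x)


def implicit_step(beta_prev: np.ndarray, dt: float, model: NeuralOperatorModel,
                  parent_betas: np.ndarray | None = None) -> np.ndarray:
    """One closed-form semi-implicit update of the model's variable."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    beta_prev = np.asarray(beta_prev, dtype=float)
    if parent_betas is None:
        x = beta_prev
    else:
        x = np.concatenate([np.asarray(parent_betas, float).ravel(), beta_prev])
    g = model.G(x)
    lam = model.basis.eigenvalues
    return (beta_prev + dt * g) / (1.0 + dt * model.alpha * lam)


# --------------------------------------------------------------------------
# losses on explicit coefficient sequences
# --------------------------------------------------------------------------

def data_loss(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean relative L2 mismatch over aligned time points (initial excluded
    when sequences include it; here every row pair is a term)."""
    predicted = np.atleast_2d(predicted)
    observed = np.atleast_2d(observed)
    if predicted.shape != observed.shape:
        raise ValueError("prediction/observation shape mismatch")
    terms = []
    for bt, b in zip(predicted, observed):
        nb = np.linalg.norm(b)
        if nb == 0:
            logger.warning("skipping zero-norm observation in data loss")
            continue
        terms.append(np.linalg.norm(bt - b) / nb)
    return float(np.mean(terms)) if terms else 0.0


def residual_loss(betas: np.ndarray, model: NeuralOperatorModel,
                  dts: np.ndarray, parent_betas: np.ndarray | None = None) -> float:
    """Mean relative mismatch between G and the discrete residual.

    ``betas`` is (T, P) observed coefficients of the model's variable;
    ``parent_betas`` is (T, n_parents*P) when the operator has upstream
    inputs; ``dts`` are the T-1 interval lengths (model-time years).
    """
    betas = np.atleast_2d(betas)
    T = betas.shape[0]
    if T < 2:
        raise ValueError("at least two time points are required")
    dts = np.asarray(dts, dtype=float)
    lam = model.basis.eigenvalues
    alpha = model.alpha
    terms = []
    for n in range(1, T):
        R = (betas[n] - betas[n - 1]) / dts[n - 1] + alpha * lam * betas[n]
        nR = np.linalg.norm(R)
        if nR == 0:
            logger.warning("skipping zero-norm residual in residual loss")
            continue
        if parent_betas is None:
            x = betas[n - 1]
        else:
            x = np.concatenate([parent_betas[n - 1], betas[n - 1]])
        terms.append(np.linalg.norm(R - model.G(x)) / nR)
    return float(np.mean(terms)) if terms else 0.0


# --------------------------------------------------------------------------
# cohort preparation
# --------------------------------------------------------------------------

def project_cohort(cohort: list[Trajectory], basis: SpectralBasis,
                   use_truth: bool = False) -> list[dict]:
    """Project every patient's fields onto the basis.

    Returns one record per patient: ``{"times", "beta": {var: (T, P)},
    "C": (T,), "patient_id"}``.
    """
    out = []
    for traj in cohort:
        fields = traj.truth_fields if use_truth and traj.truth_fields is not None \
            else traj.fields
        beta = {}
        for var, arr in fields.items():
            beta[var] = np.stack([project(arr[t], basis).beta
                                  for t in range(arr.shape[0])])
        out.append({"times": traj.times.copy(), "beta": beta,
                    "C": (traj.truth_C if use_truth and traj.truth_C is not None
                          else traj.C).copy(),
                    "patient_id": traj.patient_id})
    return out


def _prepare_batch(records: list[dict], variable: str,
                   parents: tuple[str, ...], dt_max: float,
                   max_substeps: int) -> dict:
    B = len(records)
    P = records[0]["beta"][variable].shape[1]
    T_max = max(r["times"].shape[0] for r in records)
    npar = len(parents)
    beta = np.zeros((B, T_max, P))
    par = np.zeros((B, T_max, npar * P))
    vmask = np.zeros((B, T_max), dtype=bool)
    gaps = np.zeros((B, T_max - 1)) if T_max > 1 else np.zeros((B, 0))
    for b, r in enumerate(records):
        T = r["times"].shape[0]
        if T < 2:
            raise ValueError(f"patient {r['patient_id']} has fewer than 2 visits")
        beta[b, :T] = r["beta"][variable]
        beta[b, T:] = r["beta"][variable][-1]
        if npar:
            pcat = np.concatenate([r["beta"][p] for p in parents], axis=1)
            par[b, :T] = pcat
            par[b, T:] = pcat[-1]
        vmask[b, :T] = True
        gaps[b, : T - 1] = np.diff(r["times"])
    imask = vmask[:, 1:]
    Ksub = []
    for n in range(T_max - 1):
        g = gaps[imask[:, n], n]
        K = int(np.ceil(g.max() / dt_max - 1e-12)) if g.size else 1
        Ksub.append(int(np.clip(K, 1, max_substeps)))
    rows = []
    for b in range(B):
        T_b = int(vmask[b].sum())
        blk = [par[b, :T_b]] if npar else []
        rows.append(np.concatenate(blk + [beta[b, :T_b]], axis=1))
    x_sigma = np.vstack(rows).std(axis=0)
    x_sigma = np.maximum(x_sigma, 0.05 * max(float(x_sigma.mean()), 1e-12))
    return {"B": B, "P": P, "T": T_max, "npar": npar, "beta": beta,
            "par": par, "vmask": vmask, "imask": imask, "gaps": gaps,
            "Ksub": Ksub, "x_sigma": x_sigma}


# --------------------------------------------------------------------------
# batched loss + exact gradients
# --------------------------------------------------------------------------

class RolloutProblem:
    """Combined trajectory-fit + residual loss over a batched cohort, with
    exact reverse-mode gradients w.r.t. network weights, the diffusion
    coefficient and per-patient log temporal scales."""

    def __init__(self, data: dict, net: MLP, lam: np.ndarray, cfg: TrainConfig):
        self.d = data
        self.net = net
        self.lam = lam
        self.cfg = cfg

    def loss_and_grad(self, theta, raw_alpha, z, need_theta=True,
                      need_alpha=True, need_z=True, rng=None):
        d, net, lam, cfg = self.d, self.net, self.lam, self.cfg
        B, P, T = d["B"], d["P"], d["T"]
        alpha = float(softplus(raw_alpha))
        xi = np.exp(z)[:, None]
        wD, wR = cfg.weight_data, cfg.weight_residual
        wG = cfg.g_norm_weight
        n_terms = np.maximum(d["imask"].sum(axis=1), 1)

        # input-noise augmentation (targets stay clean)
        npar_dim = d["npar"] * P
        if rng is not None and cfg.input_noise > 0:
            sig_in = d["x_sigma"]
            beta_jit = d["beta"] + rng.normal(size=d["beta"].shape) * \
                (cfg.input_noise * sig_in[npar_dim:])
            par_jit = d["par"] + rng.normal(size=d["par"].shape) * \
                (cfg.input_noise * sig_in[:npar_dim]) if d["npar"] else d["par"]
        else:
            beta_jit, par_jit = d["beta"], d["par"]

        # ---------------- forward rollout with tape ----------------
        # (skipped entirely in residual-only phases: wD == 0)
        state = beta_jit[:, 0, :].copy()
        tape = []
        visit_state_idx = {}  # visit n -> index of tape entry producing it
        for n in range(1, T if wD != 0 else 0):
            K = d["Ksub"][n - 1]
            gap = d["gaps"][:, n - 1 : n]
            dtp = xi * gap / K
            par0 = par_jit[:, n - 1, :]
            par1 = par_jit[:, n, :]
            for k in range(K):
                frac = k / K
                if d["npar"]:
                    x = np.concatenate([par0 + frac * (par1 - par0), state], axis=1)
                else:
                    x = state
                g, cache = net.forward(x, theta=theta, need_cache=True)
                den = 1.0 + dtp * alpha * lam[None, :]
                new = (state + dtp * g) / den
                tape.append({"cache": cache, "g": g, "den": den, "dtp": dtp,
                             "gap": gap, "K": K, "new": new})
                state = new
            visit_state_idx[n] = len(tape) - 1

        # ---------------- data loss and visit cotangents ----------------
        terms = np.zeros(B)
        dstate_at = {}
        for n in visit_state_idx:
            s = tape[visit_state_idx[n]]["new"]
            obs = d["beta"][:, n, :]
            diff = s - obs
            nd = np.linalg.norm(diff, axis=1)
            nb = np.linalg.norm(obs, axis=1)
            valid = d["imask"][:, n - 1] & (nb > 0)
            terms += np.where(valid, nd / np.maximum(nb, 1e-300), 0.0)
            dcon = np.zeros_like(diff)
            ok = valid & (nd > 1e-300)
            dcon[ok] = diff[ok] / (nd[ok, None] * nb[ok, None])
            dstate_at[n] = dcon
        L_D = float(np.mean(terms / n_terms)) if wD != 0 else 0.0
        wpat = (1.0 / (B * n_terms))[:, None]

        # ---------------- residual loss (single-interval secant) --------
        # R^n = (b_n - b_{n-1})/(xi*gap) + alpha*lam*b_n, target G(x_{n-1})
        res_terms = np.zeros(B)
        res_inputs = []
        aux = {"num": 0.0, "den": 0.0}
        dalpha_res = 0.0
        dz_res = np.zeros(B)
        n_int_total = max(int(d["imask"].sum()), 1)
        g_pen = 0.0
        # data-velocity scale for the reaction ridge (parameters detached)
        v2 = 0.0
        for n in range(1, T):
            gap = d["gaps"][:, n - 1]
            valid = d["imask"][:, n - 1] & (gap > 0)
            dtm = np.maximum(xi[:, 0] * gap, 1e-300)
            sec = (d["beta"][:, n, :] - d["beta"][:, n - 1, :]) / dtm[:, None]
            v2 += float(np.sum((sec[valid]) ** 2))
        v2 = max(v2 / n_int_total, 1e-300)
        for n in range(1, T):
            gap = d["gaps"][:, n - 1]
            valid = d["imask"][:, n - 1] & (gap > 0)
            b0 = d["beta"][:, n - 1, :]
            b1 = d["beta"][:, n, :]
            dt_model = np.maximum(xi[:, 0] * gap, 1e-300)
            R = (b1 - b0) / dt_model[:, None] + alpha * lam[None, :] * b1
            if d["npar"]:
                x = np.concatenate([par_jit[:, n - 1, :],
                                    beta_jit[:, n - 1, :]], axis=1)
                x_r = np.concatenate([par_jit[:, n, :], beta_jit[:, n, :]],
                                     axis=1)
            else:
                x = beta_jit[:, n - 1, :]
                x_r = beta_jit[:, n, :]
            g, cache = net.forward(x, theta=theta, need_cache=True)
            if cfg.residual_form == "trapezoid":
                g_r, cache_r = net.forward(x_r, theta=theta, need_cache=True)
                g_eff = 0.5 * (g + g_r)
            else:
                g_r, cache_r = None, None
                g_eff = g
            r = R - g_eff
            nr = np.linalg.norm(r, axis=1)
            nR = np.linalg.norm(R, axis=1)
            ok = valid & (nR > 1e-300)
            res_terms += np.where(ok, nr / np.maximum(nR, 1e-300), 0.0)
            # Cotangents.  The 1/||R|| normalization is treated as a frozen
            # per-interval weight (no gradient through the denominator):
            # letting the optimizer shrink or inflate ||R|| itself distorts
            # the diffusion coefficient badly when true reactions are small.
            dterm_dr = np.zeros_like(r)
            okn = ok & (nr > 1e-300)
            dterm_dr[okn] = r[okn] / (nr[okn, None] * nR[okn, None])
            dR_total = dterm_dr                       # numerator path only
            dg_total = -dterm_dr                      # d(term)/dg
            # scale by per-patient averaging weight
            dR_total = dR_total * wpat
            dg_total = dg_total * wpat
            # alpha path: dR/dalpha = lam*b1
            dalpha_res += float(np.sum(dR_total * lam[None, :] * b1))
            # xi path: dR/dxi = -(b1-b0)*gap/(xi*gap)^2 = -(b1-b0)/(xi^2*gap)
            dz_res += np.sum(dR_total * (-(b1 - b0) /
                             (np.maximum(xi[:, 0], 1e-300) ** 2 *
                              np.maximum(gap, 1e-300))[:, None]), axis=1) * xi[:, 0]
            # Weighted LS system for the closed-form alpha update:
            # alpha_hat = argmin sum w * ||S + alpha*lam*b1||^2 with S the
            # interval secant -- the minimal-reaction representative of the
            # alpha/G degeneracy (G absorbs whatever the diffusion term
            # cannot explain).  Weights follow the relative residual terms.
            lb1 = lam[None, :] * b1
            wls = np.where(ok, 1.0 / (B * n_terms * np.maximum(nR, 1e-12)), 0.0)
            S = (b1 - b0) / dt_model[:, None]
            aux["num"] += float(np.sum(wls[:, None] * lb1 * (-S)))
            aux["den"] += float(np.sum(wls[:, None] * lb1 * lb1))
            # reaction-magnitude ridge on observed states (see TrainConfig)
            gv = g * valid[:, None]
            g_pen += float(np.sum(gv**2)) / (n_int_total * v2)
            ridge_cot = wG * 2.0 * gv / (n_int_total * v2)
            if cfg.residual_form == "trapezoid":
                res_inputs.append((cache, wR * 0.5 * dg_total + ridge_cot))
                res_inputs.append((cache_r, wR * 0.5 * dg_total))
            else:
                res_inputs.append((cache, wR * dg_total + ridge_cot))
        L_R = float(np.mean(res_terms / n_terms))

        loss = wD * L_D + wR * L_R + wG * g_pen \
            + cfg.weight_decay * float(theta @ theta)

        # ---------------- backward through the rollout ----------------
        dtheta = np.zeros_like(theta)
        dalpha = wR * dalpha_res
        dz = wR * dz_res
        dstate = np.zeros((B, P))
        idx_to_visit = {v: n for n, v in visit_state_idx.items()}
        for idx in range(len(tape) - 1, -1, -1):
            rec = tape[idx]
            if idx in idx_to_visit:
                n = idx_to_visit[idx]
                # each visit term enters L_D as term_b / (B * n_terms_b)
                dstate = dstate + wD * dstate_at[n] * (1.0 / (B * n_terms))[:, None]
            dnew = dstate
            den, dtp, g = rec["den"], rec["dtp"], rec["g"]
            new = rec["new"]
            dg = dnew * dtp / den
            d_dtp = np.sum(dnew * (g / den - new * alpha * lam[None, :] / den),
                           axis=1, keepdims=True)
            dalpha += float(np.sum(dnew * (-new * dtp * lam[None, :] / den)))
            dx, gtheta = self.net.vjp(rec["cache"], dg, theta=theta,
                                      need_param_grads=need_theta)
            if need_theta:
                dtheta += gtheta
            dstate = dnew / den + dx[:, -P:]
            dz += (d_dtp * rec["gap"] / rec["K"])[:, 0] * np.exp(z)

        # residual-loss and reaction-ridge parameter gradients
        for cache, cot in res_inputs:
            _, gtheta = self.net.vjp(cache, cot, theta=theta,
                                     need_param_grads=need_theta)
            if need_theta:
                dtheta += gtheta
        if need_theta:
            dtheta += 2.0 * cfg.weight_decay * theta

        draw_alpha = dalpha * float(sigmoid(raw_alpha))  # softplus chain
        return loss, L_D, L_R, dtheta, draw_alpha, dz, aux



# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def train_operator(cohort: list[Trajectory] | list[dict], variable: str,
                   basis: SpectralBasis, config: TrainConfig | None = None,
                   records: list[dict] | None = None,
                   fixed_xi: np.ndarray | None = None) -> NeuralOperatorModel:
    """Fit the reaction operator and diffusion coefficient for one variable.

    ``cohort`` may be a list of trajectories or pre-projected records from
    :func:`project_cohort`.  Upstream variables required by the cascade
    ordering must be present in the data; they are supplied as observed
    inputs during rollouts.
    """
    cfg = config or TrainConfig()
    parents = PARENTS[variable]
    if records is None:
        if cohort and isinstance(cohort[0], dict):
            records = cohort  # already projected
        else:
            records = project_cohort(cohort, basis)
    for p in parents + (variable,):
        if p not in records[0]["beta"]:
            raise ValueError(f"variable {p!r} missing from cohort data")

    data = _prepare_batch(records, variable, parents, cfg.dt_max,
                          cfg.max_substeps)
    P = data["P"]
    n_vars = len(parents) + 1
    width = cfg.hidden_width or 2 * P
    sizes = [n_vars * P] + [width] * cfg.n_hidden + [P]
    # input standardization / output scaling from the observed data
    Xs, vels = [], []
    for b in range(data["B"]):
        T_b = int(data["vmask"][b].sum())
        blk = [data["par"][b, :T_b]] if data["npar"] else []
        x = np.concatenate(blk + [data["beta"][b, :T_b]], axis=1)
        Xs.append(x)
        gaps = data["gaps"][b, : T_b - 1]
        vels.append((np.diff(data["beta"][b, :T_b], axis=0) /
                     gaps[:, None]).ravel())
    Xall = np.vstack(Xs)
    mu, sig, out_scale = ScaledMLP.fit_scaling(Xall, np.concatenate(vels))
    if cfg.architecture == "nodal":
        phi = basis.vectors
        phi_t_m = basis.apply_mass(phi).T
        # nodal feature statistics and nodal output (velocity) scale
        feats = np.stack([Xall[:, j * P : (j + 1) * P] @ phi.T
                          for j in range(n_vars)], axis=-1)
        mu_nod = feats.reshape(-1, n_vars).mean(axis=0)
        sd_nod = feats.reshape(-1, n_vars).std(axis=0)
        sd_nod = np.maximum(sd_nod, 0.05 * max(float(sd_nod.mean()), 1e-12))
        vel_nod = np.concatenate(vels).reshape(-1, P) @ phi.T
        out_nod = float(np.sqrt(np.mean(vel_nod**2))) or 1.0
    elif cfg.architecture != "dense":
        raise ValueError(f"unknown architecture {cfg.architecture!r}")
    B = data["B"]
    fit_xi = cfg.per_patient_scale and fixed_xi is None and B > 1
    z0 = np.zeros(B) if fixed_xi is None \
        else np.log(np.asarray(fixed_xi, dtype=float))

    n_pre = int(round(cfg.iterations * cfg.pretrain_fraction)) \
        if cfg.weight_data != 0 and cfg.weight_residual != 0 else 0
    from dataclasses import replace as _replace

    phases = ([(n_pre, _replace(cfg, weight_data=0.0))] if n_pre else []) \
        + [(cfg.iterations - n_pre, cfg)]

    best_run = None
    for restart in range(max(cfg.n_restarts, 1)):
        if cfg.architecture == "nodal":
            hidden = cfg.hidden_width or 16
            point = MLP([n_vars] + [hidden] * cfg.n_hidden + [1],
                        seed=cfg.seed + restart,
                        final_scale=cfg.final_scale)
            net = NodalReactionNet(point, phi=phi, phi_t_m=phi_t_m,
                                   n_vars=n_vars, mu=mu_nod, sigma=sd_nod,
                                   out_scale=out_nod)
        else:
            net = ScaledMLP(MLP(sizes, seed=cfg.seed + restart,
                                final_scale=cfg.final_scale),
                            mu=mu, sigma=sig, out_scale=out_scale)
        theta = net.theta.copy()
        raw_alpha = float(softplus_inv(cfg.alpha_init))
        z = z0.copy()
        trace = []
        it_total = 0
        loss = np.inf
        for n_iter, phase_cfg in phases:
            problem = RolloutProblem(data, net, basis.eigenvalues, phase_cfg)
            n_all = theta.size + 1 + (B if fit_xi else 0)
            opt = Adam(n_all, lr=phase_cfg.lr)
            best = np.inf
            stall = 0
            aug_rng = np.random.default_rng(cfg.seed + 1000 * restart)
            for it in range(n_iter):
                loss, L_D, L_R, dtheta, dra, dz, aux = problem.loss_and_grad(
                    theta, raw_alpha, z, rng=aug_rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at iteration {it_total}: "
                        f"loss={loss}, alpha={softplus(raw_alpha):.4g}")
                trace.append(loss)
                it_total += 1
                if phase_cfg.lr_decay:
                    opt.lr = phase_cfg.lr * 0.5 * (1.0 +
                                                   np.cos(np.pi * it / n_iter))
                flat = np.concatenate([theta, [raw_alpha]]
                                      + ([z] if fit_xi else []))
                gflat = np.concatenate([dtheta, [dra]]
                                       + ([dz] if fit_xi else []))
                flat = opt.step(flat, gflat)
                theta = flat[: theta.size]
                if phase_cfg.alpha_solve and aux["den"] > 0:
                    alpha_hat = max(aux["num"] / aux["den"], 1e-8)
                    raw_alpha = float(softplus_inv(alpha_hat))
                else:
                    raw_alpha = float(flat[theta.size])
                if fit_xi:
                    z = flat[theta.size + 1 :]
                    z = z - z.mean()  # remove global time-scale degeneracy
                if loss < best * (1 - cfg.early_stop_tol):
                    best, stall = loss, 0
                else:
                    stall += 1
                    if stall > cfg.early_stop_patience:
                        break
        if best_run is None or loss < best_run[0]:
            best_run = (loss, net, theta, raw_alpha, z, trace, it_total)

    _, net, theta, raw_alpha, z, trace, it_total = best_run
    net.theta = theta
    problem = RolloutProblem(data, net, basis.eigenvalues, cfg)
    loss, L_D, L_R, *_ = problem.loss_and_grad(theta, raw_alpha, z,
                                               need_theta=False)
    model = NeuralOperatorModel(variable=variable, parents=parents,
                                basis=basis, net=net, raw_alpha=raw_alpha)
    model.train_report = TrainReport(
        loss_trace=np.array(trace), data_loss=L_D, residual_loss=L_R,
        alpha=model.alpha, xi=np.exp(z), iterations_run=it_total)
    return model


def train_sequential(cohort: list[Trajectory], basis: SpectralBasis,
                     config: TrainConfig | None = None,
                     order: tuple[str, ...] = TRAIN_ORDER,
                     ) -> dict[str, NeuralOperatorModel]:
    """Train the three operators in the amyloid-cascade order A -> tau -> N.

    The ordering is part of the contract (downstream operators consume
    upstream observations); any other ``order`` is rejected.
    """
    if tuple(order) != TRAIN_ORDER:
        raise ValueError(
            f"training order must be {TRAIN_ORDER} (amyloid cascade); "
            f"got {tuple(order)}")
    records = project_cohort(cohort, basis)
    for v in TRAIN_ORDER:
        if v not in records[0]["beta"]:
            raise ValueError(f"cohort is missing variable {v!r}")
    models: dict[str, NeuralOperatorModel] = {}
    xi = None
    for v in TRAIN_ORDER:
        logger.info("training operator for %s", v)
        models[v] = train_operator(records, v, basis, config, fixed_xi=xi)
        if v == "A" and models[v].train_report is not None:
            # reuse the temporal scales identified on the upstream variable
            xi = models[v].train_report.xi
    return models


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def rollout_coupled(models: dict[str, NeuralOperatorModel],
                    start: dict[str, np.ndarray], t0: float,
                    target_times: np.ndarray, gamma: float = 1.0,
                    dt_max: float = 0.1) -> dict[str, np.ndarray]:
    """Roll all three operators jointly from spectral state ``start`` at t0.

    Model time advances by ``gamma`` per patient-year.  Returns
    ``{var: (len(target_times), P)}`` including the start time if present in
    ``target_times``.
    """
    target_times = np.asarray(target_times, dtype=float)
    if np.any(target_times < t0 - 1e-12):
        raise ValueError("target times must not precede the initial time")
    lam = {v: m.basis.eigenvalues for v, m in models.items()}
    state = {v: np.asarray(start[v], dtype=float).copy() for v in TRAIN_ORDER}
    out = {v: [] for v in TRAIN_ORDER}
    t = t0
    for tt in target_times:
        span = tt - t
        if span > 1e-12:
            K = max(1, int(np.ceil(span / dt_max - 1e-12)))
            dt = gamma * span / K
            for _ in range(K):
                x_in = {
                    "A": state["A"],
                    "tau": np.concatenate([state["A"], state["tau"]]),
                    "N": np.concatenate([state["A"], state["tau"], state["N"]]),
                }
                new = {}
                for v in TRAIN_ORDER:
                    m = models[v]
                    g = m.G(x_in[v])
                    new[v] = (state[v] + dt * g) / (1.0 + dt * m.alpha * lam[v])
                state = new
            t = tt
        for v in TRAIN_ORDER:
            out[v].append(state[v].copy())
    return {v: np.array(out[v]) for v in TRAIN_ORDER}


def predict_forward(models: dict[str, NeuralOperatorModel],
                    initial: Trajectory | dict, target_times: np.ndarray,
                    gamma: float = 1.0, dt_max: float = 0.1) -> Trajectory:
    """Forecast nodal biomarker fields at ``target_times``.

    ``initial`` is either a trajectory (its last visit is the launch state)
    or a dict ``{"t0": float, "beta": {var: (P,)}}``.
    """
    basis = models["A"].basis
    if isinstance(initial, Trajectory):
        t0 = float(initial.times[-1])
        start = {v: project(initial.fields[v][-1], basis).beta
                 for v in TRAIN_ORDER}
    else:
        t0 = float(initial["t0"])
        start = initial["beta"]
    target_times = np.asarray(target_times, dtype=float)
    betas = rollout_coupled(models, start, t0, target_times, gamma=gamma,
                            dt_max=dt_max)
    fields = {v: betas[v] @ basis.vectors.T for v in TRAIN_ORDER}
    return Trajectory(patient_id="forecast", times=target_times,
                      fields=fields, C=np.zeros(len(target_times)))


# --------------------------------------------------------------------------
# mechanistic read-out
# --------------------------------------------------------------------------

@dataclass
class JacobianReport:
    """Jacobian of a learned reaction operator at a representative state."""

    spectral: np.ndarray                 # (P, n_inputs*P)
    blocks: dict[str, np.ndarray]        # input variable -> (P, P)
    nodal: dict[str, np.ndarray]         # input variable -> (n, n) coupling


def jacobian_analysis(model: NeuralOperatorModel,
                      state: np.ndarray) -> JacobianReport:
    """Differentiate G at ``state`` (concatenated parent+self coefficients)
    and conjugate each P x P block back to nodal space,
    ``Phi J Phi^T M``, giving the inter-regional coupling matrix."""
    x = np.asarray(state, dtype=float)
    J = model.net.jacobian(x)
    P = model.P
    names = model.parents + (model.variable,)
    if x.shape[0] != len(names) * P:
        raise ValueError(f"state must have {len(names) * P} entries")
    Phi = model.basis.vectors
    blocks, nodal = {}, {}
    for k, name in enumerate(names):
        blk = J[:, k * P : (k + 1) * P]
        blocks[name] = blk
        PhiT_M = model.basis.apply_mass(Phi).T
        nodal[name] = Phi @ blk @ PhiT_M
    return JacobianReport(spectral=J, blocks=blocks, nodal=nodal)


# --------------------------------------------------------------------------
# model archive
# --------------------------------------------------------------------------

def save_models(models: dict[str, NeuralOperatorModel], path: str,
                extra_meta: dict | None = None) -> None:
    """Write a model archive: JSON metadata + HDF5 weights + basis."""
    os.makedirs(path, exist_ok=True)
    basis = next(iter(models.values())).basis
    meta = {
        "variables": {v: {"parents": list(m.parents),
                          "sizes": m.net.sizes,
                          "alpha": m.alpha}
                      for v, m in models.items()},
        "P": basis.P,
        "domain_hash": basis.domain_hash,
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    with h5py.File(os.path.join(path, "weights.h5"), "w") as fh:
        b = fh.create_group("basis")
        b.create_dataset("eigenvalues", data=basis.eigenvalues, track_times=False)
        b.create_dataset("eigenvectors", data=basis.vectors, track_times=False)
        if basis.mass is not None:
            m = basis.mass.tocoo()
            b.create_dataset("mass_row", data=m.row, track_times=False)
            b.create_dataset("mass_col", data=m.col, track_times=False)
            b.create_dataset("mass_data", data=m.data, track_times=False)
        for v, model in models.items():
            g = fh.create_group(f"model_{v}")
            g.create_dataset("theta", data=model.net.theta, track_times=False)
            g.create_dataset("x_mu", data=model.net.mu, track_times=False)
            g.create_dataset("x_sigma", data=model.net.sigma, track_times=False)
            g.attrs["out_scale"] = model.net.out_scale
            g.attrs["raw_alpha"] = model.raw_alpha
            g.attrs["sizes"] = model.net.sizes
            g.attrs["arch"] = ("nodal" if isinstance(model.net,
                                                     NodalReactionNet)
                               else "dense")


def load_models(path: str) -> dict[str, NeuralOperatorModel]:
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    with h5py.File(os.path.join(path, "weights.h5"), "r") as fh:
        b = fh["basis"]
        mass = None
        vecs = b["eigenvectors"][()]
        if "mass_data" in b:
            n = vecs.shape[0]
            mass = sp.coo_matrix(
                (b["mass_data"][()], (b["mass_row"][()], b["mass_col"][()])),
                shape=(n, n)).tocsr()
        basis = SpectralBasis(eigenvalues=b["eigenvalues"][()], vectors=vecs,
                              mass=mass, domain_hash=meta.get("domain_hash", ""))
        models = {}
        for v, info in meta["variables"].items():
            g = fh[f"model_{v}"]
            arch = str(g.attrs.get("arch", "dense"))
            if arch == "nodal":
                phi = basis.vectors
                net = NodalReactionNet(
                    MLP([int(s) for s in g.attrs["sizes"]], seed=0),
                    phi=phi, phi_t_m=basis.apply_mass(phi).T,
                    n_vars=len(info["parents"]) + 1, mu=g["x_mu"][()],
                    sigma=g["x_sigma"][()],
                    out_scale=float(g.attrs["out_scale"]))
            else:
                net = ScaledMLP(MLP([int(s) for s in g.attrs["sizes"]],
                                    seed=0),
                                mu=g["x_mu"][()], sigma=g["x_sigma"][()],
                                out_scale=float(g.attrs["out_scale"]))
            net.theta = g["theta"][()]
            models[v] = NeuralOperatorModel(
                variable=v, parents=tuple(info["parents"]), basis=basis,
                net=net, raw_alpha=float(g.attrs["raw_alpha"]))
    return models
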