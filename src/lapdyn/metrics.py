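"""Evaluation metrics shared by tests, reports and the pipeline.

Two accuracy scores are used throughout:

* ``Acc2 = 1 - ||u - u_hat|| / ||u||`` (relative L2 accuracy), and
* ``Acc1 = 1 - mean_j |u_j - u_hat_j| / |u_j|`` (mean pointwise relative
  accuracy), with zero-valued locations excluded and counted.

Norms use the FEM mass inner product on meshes and the Euclidean norm on
graphs.  The error suite reports the relative solution error E_L2, the
relative residual error E_Res (how well the learned reaction matches the
discrete time-derivative-plus-diffusion residual of the data), and -- when
the generating reaction is known, i.e. on synthetic data -- the relative
nonlinear-term recovery error E_Nonlinear.  Errors are averaged first and
transformed to accuracies afterwards.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain import SpectralBasis

logger = logging.getLogger(__name__)

__all__ = ["acc2", "acc1", "EvalReport", "error_suite",
           "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    pass


def _norm(u: np.ndarray, basis: SpectralBasis | None = None) -> float:
    if basis is not None and basis.mass is not None:
        return float(np.sqrt(u @ (basis.mass @ u)))
    return float(np.linalg.norm(u))


def acc2(u: np.ndarray, u_hat: np.ndarray,
         basis: SpectralBasis | None = None) -> float:
    """Relative L2 accuracy; 1 for a perfect match, 0 for a zero predictor."""
    u = np.asarray(u, float).ravel()
    u_hat = np.asarray(u_hat, float).ravel()
    nu = _norm(u, basis)
    if nu == 0:
        raise UndefinedMetricError("acc2 is undefined for a zero reference")
    return 1.0 - _norm(u - u_hat, basis) / nu


def acc1(u: np.ndarray, u_hat: np.ndarray) -> float:
    """Mean pointwise relative accuracy; zero-valued locations excluded."""
    u = np.asarray(u, float).ravel()
    u_hat = np.asarray(u_hat, float).ravel()
    ok = u != 0
    n_excl = int((~ok).sum())
    if n_excl:
        logger.warning("acc1: excluded %d zero-valued locations", n_excl)
    if not ok.any():
        raise UndefinedMetricError("acc1 is undefined: all locations zero")
    return 1.0 - float(np.mean(np.abs(u[ok] - u_hat[ok]) / np.abs(u[ok])))


@dataclass
class EvalReport:
    """Per-variable training/prediction accuracies and error suite."""

    train_acc2: dict[str, float] = field(default_factory=dict)
    train_acc1: dict[str, float] = field(default_factory=dict)
    pred_acc2: dict[str, float] = field(default_factory=dict)
    pred_acc1: dict[str, float] = field(default_factory=dict)
    e_l2: dict[str, float] = field(default_factory=dict)
    e_res: dict[str, float] = field(default_factory=dict)
    e_nonlinear: dict[str, float | None] = field(default_factory=dict)
    e_l2_pred: dict[str, float] = field(default_factory=dict)
    n_trajectories: int = 0
    n_timepoints: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.train_acc2:
            rows.append({
                "variable": v,
                "train_acc2": self.train_acc2.get(v),
                "train_acc1": self.train_acc1.get(v),
                "pred_acc2": self.pred_acc2.get(v),
                "pred_acc1": self.pred_acc1.get(v),
            })
        return pd.DataFrame(rows)

    def to_json(self, path: str | None = None) -> str:
        payload = {k: getattr(self, k) for k in (
            "train_acc2", "train_acc1", "pred_acc2", "pred_acc1",
            "e_l2", "e_res", "e_nonlinear", "e_l2_pred")}
        payload["n_trajectories"] = self.n_trajectories
        payload["n_timepoints"] = self.n_timepoints
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def error_suite(truth: dict[str, list[np.ndarray]],
                predicted: dict[str, list[np.ndarray]],
                basis: SpectralBasis | None = None,
                residual_pairs: dict[str, list[tuple]] | None = None,
                nonlinear_pairs: dict[str, list[tuple]] | None = None,
                pred_truth: dict[str, list[np.ndarray]] | None = None,
                pred_predicted: dict[str, list[np.ndarray]] | None = None,
                ) -> EvalReport:
    """Aggregate relative errors over aligned trajectory snapshots.

    ``truth`` / ``predicted`` map a variable to equally long lists of nodal
    snapshots (training phase).  ``residual_pairs[v]`` is a list of
    ``(G_of_prev, R_of_data)`` spectral vectors; ``nonlinear_pairs[v]`` a
    list of ``(learned_reaction, true_reaction)`` nodal vectors (synthetic
    data only -- when absent, E_Nonlinear is reported as None, never 0).
    ``pred_*`` are held-out-phase snapshot lists for E_L2pred.
    """
    rep = EvalReport()
    for v, u_list in truth.items():
        errs = [np.linalg.norm(np.ravel(p) - np.ravel(u)) /
                np.linalg.norm(np.ravel(u))
                for u, p in zip(u_list, predicted[v])]
        rep.e_l2[v] = float(np.mean(errs))
        if residual_pairs and v in residual_pairs:
            terms = [np.linalg.norm(g - r) / np.linalg.norm(r)
                     for g, r in residual_pairs[v]
                     if np.linalg.norm(r) > 0]
            rep.e_res[v] = float(np.mean(terms)) if terms else float("nan")
        if nonlinear_pairs is not None and v in nonlinear_pairs:
            terms = [np.linalg.norm(np.ravel(nl) - np.ravel(fl)) /
                     np.linalg.norm(np.ravel(fl))
                     for nl, fl in nonlinear_pairs[v]
                     if np.linalg.norm(np.ravel(fl)) > 0]
            rep.e_nonlinear[v] = float(np.mean(terms)) if terms else None
        else:
            rep.e_nonlinear[v] = None
        if pred_truth and v in pred_truth:
            errs = [np.linalg.norm(np.ravel(p) - np.ravel(u)) /
                    np.linalg.norm(np.ravel(u))
                    for u, p in zip(pred_truth[v], pred_predicted[v])]
            rep.e_l2_pred[v] = float(np.mean(errs))
    return rep
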