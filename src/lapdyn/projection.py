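"""Projection between nodal fields and spectral coefficients.

A biomarker field ``u`` (one value per mesh node or graph region) is
represented by its coefficients ``beta_i = <u, phi_i>`` in the Laplacian
eigenbasis; reconstruction is ``u = sum_i beta_i phi_i``.  The discrete
residual combines the backward-difference time derivative with the spectral
diffusion term and is the quantity the learned reaction operator must match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domain import SpectralBasis

__all__ = [
    "BiomarkerField",
    "SpectralCoefficients",
    "ResidualVector",
    "project",
    "reconstruct",
    "residual",
]

VARIABLES = ("A", "tau", "N")


@dataclass
class BiomarkerField:
    """A nodal/regional biomarker snapshot (SUVR-like, dimensionless)."""

    variable: str
    values: np.ndarray
    time: float  # age in years

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


@dataclass
class SpectralCoefficients:
    """Length-P coefficient vector of a field in the eigenbasis."""

    variable: str
    beta: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients contain non-finite values")


@dataclass
class ResidualVector:
    """Discrete residual R^n = (beta^n - beta^{n-1})/dt + alpha * Lambda beta^n."""

    values: np.ndarray
    dt: float
    alpha: float


def project(field: BiomarkerField | np.ndarray, basis: SpectralBasis,
            variable: str = "", time: float = 0.0) -> SpectralCoefficients:
    """Project a nodal field onto the eigenbasis.

    For meshes the projection uses the mass inner product
    ``beta_i = phi_i^T M u``; for graphs it is the Euclidean dot product.
    """
    if isinstance(field, BiomarkerField):
        u, variable, time = field.values, field.variable, field.time
    else:
        u = np.asarray(field, dtype=float)
    if u.shape[0] != basis.n:
        raise ValueError(f"field has {u.shape[0]} values, domain has {basis.n} nodes")
    beta = basis.vectors.T @ basis.apply_mass(u)
    return SpectralCoefficients(variable=variable, beta=beta, time=time)


def reconstruct(coeffs: SpectralCoefficients | np.ndarray, basis: SpectralBasis,
                variable: str = "", time: float = 0.0) -> BiomarkerField:
    """Reconstruct the nodal field ``u = sum_i beta_i phi_i``."""
    if isinstance(coeffs, SpectralCoefficients):
        beta, variable, time = coeffs.beta, coeffs.variable, coeffs.time
    else:
        beta = np.asarray(coeffs, dtype=float)
    if beta.shape[0] != basis.P:
        raise ValueError(f"expected {basis.P} coefficients, got {beta.shape[0]}")
    return BiomarkerField(variable=variable, values=basis.vectors @ beta, time=time)


def residual(beta_n: SpectralCoefficients | np.ndarray,
             beta_prev: SpectralCoefficients | np.ndarray,
             dt: float, alpha: float, basis: SpectralBasis) -> ResidualVector:
    """Discrete time-derivative-plus-diffusion residual over one interval.

    ``dt`` is the actual inter-visit gap in (possibly rescaled) years; it is
    never assumed uniform across a trajectory.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    bn = beta_n.beta if isinstance(beta_n, SpectralCoefficients) else np.asarray(beta_n, float)
    bp = beta_prev.beta if isinstance(beta_prev, SpectralCoefficients) else np.asarray(beta_prev, float)
    vals = (bn - bp) / dt + alpha * basis.eigenvalues * bn
    return ResidualVector(values=vals, dt=dt, alpha=alpha)
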