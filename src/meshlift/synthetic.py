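"""Synthetic inputs with known structure for verification.

Three families of fixtures make every stage testable without external data:

* draws from a Gaussian process with known hyperparameters (exercises the
  Kriging estimator against ground truth);
* closed-form transport profiles — the steady annular log profile, the
  well-mixed binding relaxation, and 1-D half-space diffusion — used as
  solver oracles and as noise-free learning targets;
* miniature mesh hierarchies (via :func:`meshlift.mesh.build_hierarchy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import erfc

from .gp import correlation
from .mesh import TriMesh
from .transport import ConcentrationField, TransportParameters, bound_equilibrium

__all__ = [
    "SyntheticGPSpec",
    "AnalyticProfile",
    "sample_gp",
    "annular_log_profile",
    "half_space_profile",
    "analytic_field",
]


@dataclass(frozen=True)
class SyntheticGPSpec:
    """Ground-truth GP from which to draw verification data."""

    q: int = 2
    l: int = 80
    theta_true: tuple = (5.0, 0.5)
    beta_true: float = 1.0
    sigma2_true: float = 2.0
    noise_var: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_true < 0 or self.noise_var < 0:
            raise ValueError("variances must be non-negative")
        if len(self.theta_true) != self.q:
            raise ValueError("theta_true must have length q")


def sample_gp(spec: SyntheticGPSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, y): X i.i.d. uniform in the unit box, y from the GP
    ``beta + Z(x) + noise`` with product power-exponential correlation."""
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(size=(spec.l, spec.q))
    K = spec.sigma2_true * correlation(X, X, np.asarray(spec.theta_true))
    K += (1e-12 * max(spec.sigma2_true, 1.0)) * np.eye(spec.l)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("implied covariance not positive definite") from exc
    y = spec.beta_true + L @ rng.standard_normal(spec.l)
    if spec.noise_var > 0:
        y = y + np.sqrt(spec.noise_var) * rng.standard_normal(spec.l)
    return X, y


@dataclass
class AnalyticProfile:
    """A closed-form field ``(x, y) -> value`` with a named kind."""

    kind: str
    evaluator: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        return self.evaluator(np.atleast_2d(coords))


def annular_log_profile(R: float, W: float, D: float, flux: float) -> AnalyticProfile:
    """Steady diffusion through an annulus with constant mural influx and a
    perfect outer sink: ``C(r) = (q R / D) ln((R+W)/r)``."""

    def ev(coords: np.ndarray) -> np.ndarray:
        r = np.hypot(coords[:, 0], coords[:, 1])
        if np.any(r <= 0):
            raise ValueError("profile undefined at r = 0")
        return flux * R / D * np.log((R + W) / r)

    return AnalyticProfile("annular_log", ev, dict(R=R, W=W, D=D, flux=flux))


def binding_equilibrium_profile(
    params: TransportParameters, free_profile: AnalyticProfile
) -> AnalyticProfile:
    """Bound drug in local equilibrium with a given free-drug profile
    (the t -> infinity limit of the binding kinetics at fixed C)."""

    def ev(coords: np.ndarray) -> np.ndarray:
        return bound_equilibrium(free_profile(coords), params)

    return AnalyticProfile("binding_equilibrium", ev, dict(free=free_profile.kind))


def half_space_profile(D: float, C_s: float, t: float, x0: float = 0.0) -> AnalyticProfile:
    """1-D half-space diffusion from a constant-concentration face:
    ``C(x, t) = C_s erfc((x - x0) / (2 sqrt(D t)))`` evaluated on the
    x-coordinate; a transient solver oracle for early times."""

    def ev(coords: np.ndarray) -> np.ndarray:
        return C_s * erfc((coords[:, 0] - x0) / (2.0 * np.sqrt(D * t)))

    return AnalyticProfile("half_space", ev, dict(D=D, C_s=C_s, t=t, x0=x0))


def analytic_field(
    profile: AnalyticProfile, mesh: TriMesh, *, time: float = 0.0, as_output: str = "free"
) -> ConcentrationField:
    """Evaluate a closed-form profile at the mesh nodes as a field.

    ``as_output`` selects whether the values populate the free (C) or bound
    (B) slot; the other slot is zero.  Used both as a solver oracle and as a
    noise-free learning target for full-pipeline closure tests.
    """
    vals = profile(mesh.node_coords)
    zeros = np.zeros(mesh.n_nodes)
    if as_output == "free":
        return ConcentrationField(mesh=mesh, C=vals, B=zeros, time=time)
    if as_output == "bound":
        return ConcentrationField(mesh=mesh, C=zeros, B=vals, time=time)
    raise ValueError("as_output must be 'free' or 'bound'")
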