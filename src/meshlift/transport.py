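"""Transient free/bound drug transport in the arterial wall.

The model is diffusion of free drug with reversible saturable binding to
tissue sites::

    dC/dt = D_w * lap(C) - k_a * C * (B_M - B) + k_d * B
    dB/dt =               k_a * C * (B_M - B) - k_d * B

with zero initial concentrations, a perfect-sink Dirichlet condition
``C = 0`` on the perivascular (outer) boundary, zero-flux for bound drug
everywhere (it does not diffuse), and a prescribed time-dependent molar flux
``J_b(t)`` on the mural (inner) boundary while the balloon is inflated.

Discretization is P1 finite elements with a lumped mass matrix; the
method-of-lines system is integrated with a variable-order implicit BDF
scheme (orders 1-5) using an analytic sparse Jacobian, so the reaction terms
are handled fully implicitly together with diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import spsolve

from .mesh import INTERIOR, MURAL, PERIVASCULAR, TriMesh

__all__ = [
    "TransportParameters",
    "SolverSettings",
    "ConcentrationField",
    "DiscreteOperators",
    "balloon_flux",
    "released_mass_per_area",
    "assemble_operators",
    "solve_transient",
    "solve_steady_diffusion",
    "bound_equilibrium",
    "binding_relaxation",
]


@dataclass(frozen=True)
class TransportParameters:
    """Physical constants for zotarolimus delivery from a coated balloon.

    Units are SI throughout with concentrations in mol m^-3 (numerically
    equal to mmol l^-1, so the printed millimolar values can be used as-is).
    The association/dissociation rates are derived on construction:
    ``k_a = D_w * Da / (B_M * W**2)`` and ``k_d = k_a * K_d``.  Setting
    ``Da = 0`` disables binding entirely (k_a = k_d = 0), which is the
    verification configuration for the pure-diffusion analytic oracle.

    ``coat_thickness`` is the geometric factor (coating volume per unit
    balloon surface area, metres) that converts the volumetric release
    kinetics amplitude ``A_1`` (kg m^-3) into an areal molar flux.
    """

    D_w: float = 1.712e-11      # apparent net diffusivity, m^2/s
    B_M: float = 0.356          # net tissue binding capacity, mol/m^3
    Da: float = 50_000.0        # Damkoehler number, dimensionless
    K_d: float = 0.0326         # equilibrium dissociation constant, mol/m^3
    A_1: float = 23.95          # release kinetics amplitude, kg/m^3
    k_1: float = 0.009208       # release kinetics rate, 1/s
    Z_MW: float = 966.21        # drug molecular weight, g/mol
    t_0: float = 30.0           # balloon inflation time, s
    W: float = 0.5e-3           # wall thickness, m
    coat_thickness: float = 20e-6  # balloon coating thickness, m

    def __post_init__(self) -> None:
        positive = {
            "D_w": self.D_w, "B_M": self.B_M, "K_d": self.K_d, "A_1": self.A_1,
            "k_1": self.k_1, "Z_MW": self.Z_MW, "t_0": self.t_0, "W": self.W,
            "coat_thickness": self.coat_thickness,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.Da < 0:
            raise ValueError("Da must be non-negative (0 disables binding)")

    @property
    def k_a(self) -> float:
        """Association rate, m^3 mol^-1 s^-1 (derived)."""
        return self.D_w * self.Da / (self.B_M * self.W**2)

    @property
    def k_d_rate(self) -> float:
        """Dissociation rate, s^-1 (derived; distinct from the equilibrium
        constant K_d, with which it shares a printed symbol)."""
        return self.k_a * self.K_d


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive BDF integrator controls."""

    rtol: float = 1e-9
    atol: float = 1e-6
    max_order: int = 5
    t_end: float = 3600.0  # fields are extracted at 1 h from inflation onset

    def __post_init__(self) -> None:
        if not (self.rtol > 0 and self.atol > 0 and self.t_end > 0):
            raise ValueError("tolerances and end time must be positive")


@dataclass
class ConcentrationField:
    """Free (C) and bound (B) drug concentrations per node at one time."""

    mesh: TriMesh
    C: np.ndarray
    B: np.ndarray
    time: float

    def values(self, output_kind: str) -> np.ndarray:
        if output_kind == "free":
            return self.C
        if output_kind == "bound":
            return self.B
        raise ValueError(f"unknown output_kind {output_kind!r}; use 'free' or 'bound'")


@dataclass
class DiscreteOperators:
    """P1 finite-element operators on a tagged mesh."""

    mass: sp.csr_matrix            # consistent mass matrix, SPD
    mass_lumped: np.ndarray        # row sums of mass (diagonal lumping)
    stiffness: sp.csr_matrix       # Laplacian stiffness, symmetric PSD
    mural_mass_lumped: np.ndarray  # lumped boundary mass on mural nodes only


def balloon_flux(t: float | np.ndarray, params: TransportParameters) -> float | np.ndarray:
    """Molar drug flux from the inflated balloon into the mural surface.

    ``J_b(t) = (A_1 * h_c * k_1 / Z_MW) * exp(-k_1 t)`` for ``0 <= t <= t_0``
    and exactly zero once the balloon is deflated (``t > t_0``), in
    mol m^-2 s^-1.  ``Z_MW`` converts the mass-based kinetics to moles and the
    coating thickness ``h_c`` supplies the per-area geometric factor.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("flux is undefined for negative time")
    amp = params.A_1 * params.coat_thickness * params.k_1 / (params.Z_MW * 1e-3)
    out = np.where(t_arr <= params.t_0, amp * np.exp(-params.k_1 * t_arr), 0.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def released_mass_per_area(t: float, params: TransportParameters) -> float:
    """Closed-form cumulative released moles per unit mural area up to ``t``."""
    amp = params.A_1 * params.coat_thickness * params.k_1 / (params.Z_MW * 1e-3)
    tc = min(t, params.t_0)
    return amp * (1.0 - np.exp(-params.k_1 * tc)) / params.k_1


def _boundary_edges(mesh: TriMesh, tag: int) -> np.ndarray:
    """Element edges lying on the boundary loop with the given tag
    (edges used exactly once whose endpoints both carry the tag)."""
    e = mesh.elements
    pairs = np.vstack([e[:, [0, 1]], e[:, [1, 2]], e[:, [2, 0]]])
    pairs.sort(axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    bnd = uniq[counts == 1]
    both = (mesh.boundary_tag[bnd[:, 0]] == tag) & (mesh.boundary_tag[bnd[:, 1]] == tag)
    return bnd[both]


def assemble_operators(mesh: TriMesh) -> DiscreteOperators:
    """Assemble P1 mass, stiffness and mural boundary-mass operators."""
    if not np.any(mesh.boundary_tag == MURAL) or not np.any(
        mesh.boundary_tag == PERIVASCULAR
    ):
        raise ValueError("mesh must have both mural and perivascular boundary tags")
    n = mesh.n_nodes
    tri = mesh.elements
    p = mesh.node_coords[tri]  # (m, 3, 2)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    # gradients of barycentric basis functions
    b = np.stack(
        [p[:, 1, 1] - p[:, 2, 1], p[:, 2, 1] - p[:, 0, 1], p[:, 0, 1] - p[:, 1, 1]],
        axis=1,
    )
    c = np.stack(
        [p[:, 2, 0] - p[:, 1, 0], p[:, 0, 0] - p[:, 2, 0], p[:, 1, 0] - p[:, 0, 0]],
        axis=1,
    )
    rows, cols, kvals, mvals = [], [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(tri[:, i])
            cols.append(tri[:, j])
            kvals.append((b[:, i] * b[:, j] + c[:, i] * c[:, j]) / (4.0 * area))
            mvals.append(area * ((1 + (i == j)) / 12.0))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    K = sp.csr_matrix((np.concatenate(kvals), (rows, cols)), shape=(n, n))
    M = sp.csr_matrix((np.concatenate(mvals), (rows, cols)), shape=(n, n))

    mural_edges = _boundary_edges(mesh, MURAL)
    lengths = np.linalg.norm(
        mesh.node_coords[mural_edges[:, 0]] - mesh.node_coords[mural_edges[:, 1]], axis=1
    )
    bmass = np.zeros(n)
    np.add.at(bmass, mural_edges[:, 0], 0.5 * lengths)
    np.add.at(bmass, mural_edges[:, 1], 0.5 * lengths)

    return DiscreteOperators(
        mass=M,
        mass_lumped=np.asarray(M.sum(axis=1)).ravel(),
        stiffness=K,
        mural_mass_lumped=bmass,
    )


def solve_steady_diffusion(
    mesh: TriMesh, D: float, flux_value: float
) -> np.ndarray:
    """Steady pure diffusion with constant mural influx and outer sink.

    Solves ``-D lap(C) = 0`` with Neumann flux ``flux_value`` (mol m^-2 s^-1)
    on the mural boundary and ``C = 0`` on the perivascular boundary; used as
    the verification counterpart of the annular log-profile closed form.
    """
    ops = assemble_operators(mesh)
    free = np.flatnonzero(mesh.boundary_tag != PERIVASCULAR)
    A = (D * ops.stiffness)[free][:, free].tocsc()
    rhs = flux_value * ops.mural_mass_lumped[free]
    C = np.zeros(mesh.n_nodes)
    C[free] = spsolve(A, rhs)
    return C


def bound_equilibrium(C: float | np.ndarray, params: TransportParameters) -> float | np.ndarray:
    """Equilibrium bound concentration for a fixed free level:
    ``B_eq = B_M * C / (K_d + C)`` (saturable Langmuir isotherm)."""
    return params.B_M * np.asarray(C, dtype=float) / (params.K_d + np.asarray(C, dtype=float))


def binding_relaxation(
    C: float, t: float | np.ndarray, params: TransportParameters, B0: float = 0.0
) -> float | np.ndarray:
    """Closed-form bound-drug kinetics when the free level is held fixed.

    ``dB/dt = k_a C (B_M - B) - k_d B`` is linear in B for constant C, so
    B relaxes to the Langmuir equilibrium with rate ``k_a C + k_d``.
    """
    rate = params.k_a * C + params.k_d_rate
    beq = bound_equilibrium(C, params)
    return beq + (B0 - beq) * np.exp(-rate * np.asarray(t, dtype=float))


class ConvergenceError(RuntimeError):
    """Raised when the implicit integrator fails before reaching t_end."""


def solve_transient(
    mesh: TriMesh,
    params: TransportParameters,
    settings: SolverSettings = SolverSettings(),
    *,
    flux_fn=None,
    C0: np.ndarray | float = 0.0,
    B0: np.ndarray | float = 0.0,
    outer_bc: str = "sink",
    clamp_free: bool = False,
    t_eval: np.ndarray | None = None,
):
    """Integrate the transport system and return the field at ``t_end``.

    Parameters
    ----------
    flux_fn : optional callable ``t -> mol m^-2 s^-1`` replacing the balloon
        flux (verification hook); ``None`` uses :func:`balloon_flux`.
    C0, B0 : initial conditions (scalars broadcast to all nodes).
    outer_bc : ``"sink"`` (Dirichlet C = 0 on the perivascular boundary, the
        physical condition) or ``"noflux"`` (closed outer wall, used by the
        mass-balance and well-mixed verification problems).
    clamp_free : freeze the free-drug field at its initial value and evolve
        only the binding kinetics — isolates the reaction terms against the
        scalar-ODE closed form.
    t_eval : optional times at which to also record the trajectory; when
        given, returns ``(field, times, C_traj, B_traj)``.
    """
    if outer_bc not in ("sink", "noflux"):
        raise ValueError("outer_bc must be 'sink' or 'noflux'")
    ops = assemble_operators(mesh)
    n = mesh.n_nodes
    if outer_bc == "sink":
        free_idx = np.flatnonzero(mesh.boundary_tag != PERIVASCULAR)
    else:
        free_idx = np.arange(n)
    nf = free_idx.size

    Kff = (params.D_w * ops.stiffness)[free_idx][:, free_idx].tocsr()
    m_lump = ops.mass_lumped[free_idx]
    b_mural = ops.mural_mass_lumped[free_idx] / m_lump
    Minv_K = sp.diags(1.0 / m_lump) @ Kff

    ka, kd, BM = params.k_a, params.k_d_rate, params.B_M
    flux = flux_fn if flux_fn is not None else (lambda t: balloon_flux(t, params))

    C_init = np.full(n, float(C0)) if np.isscalar(C0) else np.asarray(C0, dtype=float).copy()
    B_init = np.full(n, float(B0)) if np.isscalar(B0) else np.asarray(B0, dtype=float).copy()
    if outer_bc == "sink":
        C_init[mesh.boundary_tag == PERIVASCULAR] = 0.0

    # state layout: u = [C at free nodes (nf), B at all nodes (n)]
    def rhs(t, u):
        C = u[:nf]
        B = u[nf:]
        C_full = np.zeros(n)
        C_full[free_idx] = C
        react = ka * C_full * (BM - B) - kd * B
        if clamp_free:
            dC = np.zeros_like(C)
        else:
            dC = -(Minv_K @ C) + flux(t) * b_mural - react[free_idx]
        return np.concatenate([dC, react])

    rows_sel = np.arange(nf)

    def jac(t, u):
        C = u[:nf]
        B = u[nf:]
        C_full = np.zeros(n)
        C_full[free_idx] = C
        # d(react)/dC : (n, nf) nonzero on rows free_idx
        dr_dC = sp.csr_matrix(
            (ka * (BM - B[free_idx]), (free_idx, rows_sel)), shape=(n, nf)
        )
        dr_dB = sp.diags(-ka * C_full - kd)
        if clamp_free:
            top = sp.hstack([sp.csr_matrix((nf, nf)), sp.csr_matrix((nf, n))])
        else:
            tl = -Minv_K - sp.diags(ka * (BM - B[free_idx]))
            tr = sp.csr_matrix(
                (ka * C + kd, (rows_sel, free_idx)), shape=(nf, n)
            )
            top = sp.hstack([tl, tr])
        bot = sp.hstack([dr_dC, dr_dB])
        return sp.vstack([top, bot], format="csc")

    u0 = np.concatenate([C_init[free_idx], B_init])
    t0_cut = params.t_0 if flux_fn is None else None
    breakpoints = [0.0]
    if t0_cut is not None and 0.0 < t0_cut < settings.t_end:
        breakpoints.append(t0_cut)  # flux switches off discontinuously
    breakpoints.append(settings.t_end)

    times_out, C_out, B_out = [], [], []
    u = u0
    for ta, tb in zip(breakpoints[:-1], breakpoints[1:]):
        seg_eval = None
        if t_eval is not None:
            mask = (np.asarray(t_eval) > ta) & (np.asarray(t_eval) <= tb)
            seg_eval = np.asarray(t_eval)[mask]
            if seg_eval.size == 0:
                seg_eval = None
        sol = solve_ivp(
            rhs,
            (ta, tb),
            u,
            method="BDF",
            jac=jac,
            rtol=settings.rtol,
            atol=settings.atol,
            t_eval=seg_eval,
        )
        if not sol.success:
            raise ConvergenceError(
                f"BDF integration failed at t={sol.t[-1] if sol.t.size else ta:.3g}s: "
                f"{sol.message}"
            )
        if t_eval is not None and sol.t.size:
            times_out.extend(sol.t.tolist())
            for col in sol.y.T:
                C_full = np.zeros(n)
                C_full[free_idx] = col[:nf]
                C_out.append(C_full)
                B_out.append(col[nf:].copy())
        if seg_eval is not None:
            # re-integrate endpoint state exactly for the next segment
            sol_end = solve_ivp(
                rhs, (sol.t[-1], tb), sol.y[:, -1], method="BDF", jac=jac,
                rtol=settings.rtol, atol=settings.atol,
            ) if sol.t[-1] < tb else sol
            u = sol_end.y[:, -1]
        else:
            u = sol.y[:, -1]

    C_final = np.zeros(n)
    C_final[free_idx] = u[:nf]
    if clamp_free:
        C_final = C_init
    B_final = u[nf:]
    field = ConcentrationField(mesh=mesh, C=C_final, B=B_final, time=settings.t_end)
    if t_eval is not None:
        return field, np.asarray(times_out), np.asarray(C_out), np.asarray(B_out)
    return field
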