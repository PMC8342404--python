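"""Moving-grid finite-element solver for the nonlinear contraction model.

The six fields (c, N, M, rho, v, eps) are discretized with linear basis
functions on a 1D mesh whose nodes move with the tissue (mesh velocity =
material velocity v, so the basis functions satisfy D(phi)/Dt = 0).  With
the Leibniz-Reynolds transport theorem the conservative convection terms
d(z v)/dx disappear into the motion of the mass matrix:

    d/dt [ M(t) z ] = F(z),

and the strain equation reduces to the material form
D(eps)/Dt = (1 - eps) dv/dx - alpha*eps along node trajectories.

Time integration is backward Euler with a monolithic system over all six
fields and inner Picard iterations: every nonlinear coefficient (Hill
factors, logistic terms, the frozen velocity in the mesh motion, rho in the
stress and body force) is evaluated at the previous iterate so the unknowns
enter linearly.  Mass matrices are lumped by default, which preserves the
discrete maximum principle of the diffusion operators on uniform meshes.

The monolithic matrix is stored in banded form (unknowns interleaved per
node in the order c, N, M, rho, v, eps, bandwidth 11) and factorized with
``scipy.linalg.solve_banded``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .params import EquilibriumState, ParameterSet

logger = logging.getLogger(__name__)

FIELD_NAMES = ("c", "N", "M", "rho", "v", "eps")
NFIELDS = 6
#: banded half-bandwidth: node-neighbour coupling (6) + in-node coupling (5)
BANDWIDTH = 11


class BlowUpError(RuntimeError):
    """Numerical blow-up: singular system, NaN fields, mesh tangling or
    diverging Picard iterations.  Carries the last finite state."""

    def __init__(self, reason: str, t: float, fields=None, mesh=None):
        super().__init__(f"blow-up at t = {t:g} days: {reason}")
        self.reason = reason
        self.t = t
        self.fields = fields
        self.mesh = mesh


@dataclass
class FieldState:
    """Nodal values of the six fields at one instant.

    c, rho in g/cm^3; N, M in cells/cm^3; v in cm/day; eps dimensionless.
    Densities are expected non-negative; small undershoots are logged as
    monotonicity-loss warnings, not errors.
    """

    c: np.ndarray
    N: np.ndarray
    M: np.ndarray
    rho: np.ndarray
    v: np.ndarray
    eps: np.ndarray

    def __post_init__(self):
        m = len(self.c)
        for name in FIELD_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"field {name} has shape {arr.shape}, expected ({m},)")
            setattr(self, name, arr)

    @classmethod
    def equilibrium(cls, m: int, eq: EquilibriumState) -> "FieldState":
        return cls(
            c=np.full(m, eq.c_bar), N=np.full(m, eq.N_bar),
            M=np.full(m, eq.M_bar), rho=np.full(m, eq.rho_bar),
            v=np.full(m, eq.v_bar), eps=np.full(m, eq.eps_bar),
        )

    @classmethod
    def from_vector(cls, z: np.ndarray) -> "FieldState":
        zz = z.reshape(-1, NFIELDS)
        return cls(*(zz[:, j].copy() for j in range(NFIELDS)))

    def to_vector(self) -> np.ndarray:
        return np.column_stack([getattr(self, f) for f in FIELD_NAMES]).ravel()

    def copy(self) -> "FieldState":
        return FieldState(*(getattr(self, f).copy() for f in FIELD_NAMES))

    @property
    def n_nodes(self) -> int:
        return len(self.c)


@dataclass
class MeshState:
    """Moving mesh: node coordinates (cm), accumulated displacement u (cm)
    and time t (days).  Nodes must stay strictly increasing."""

    nodes: np.ndarray
    u: np.ndarray = None
    t: float = 0.0

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.u is None:
            self.u = np.zeros_like(self.nodes)
        self.validate()

    def validate(self):
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("mesh nodes must be strictly increasing")

    @classmethod
    def uniform(cls, length: float, n_elements: int, x0: float = 0.0) -> "MeshState":
        return cls(nodes=np.linspace(x0, x0 + length, n_elements + 1))

    @property
    def h(self) -> np.ndarray:
        return np.diff(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def copy(self) -> "MeshState":
        return MeshState(nodes=self.nodes.copy(), u=self.u.copy(), t=self.t)


@dataclass(frozen=True)
class SolverConfig:
    """Time-stepping and nonlinear-iteration settings.

    dt_schedule is piecewise constant: ((t_start, dt), ...) with the step
    active from its start time until the next entry.  boundary_mode 'full'
    imposes the equilibrium Dirichlet data (c=0, N=N_bar, M=0, v=0) on both
    ends; 'half' imposes them on the left end only and treats the right end
    as a symmetry plane (v=0, zero flux for c, N, M).
    """

    dt_schedule: tuple = ((0.0, 0.5),)
    picard_tol: float = 1e-8
    picard_max: int = 25
    picard_fail_tol: float = 1e-2
    lumping: bool = True
    boundary_mode: str = "full"

    def __post_init__(self):
        if self.picard_max < 1:
            raise ValueError("picard_max must be >= 1")
        for _, dt in self.dt_schedule:
            if dt <= 0:
                raise ValueError("every dt in the schedule must be > 0")
        if self.boundary_mode not in ("full", "half"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")

    def dt_at(self, t: float) -> float:
        dt = self.dt_schedule[0][1]
        for t0, step in self.dt_schedule:
            if t >= t0 - 1e-12:
                dt = step
        return dt

    def replace(self, **kw) -> "SolverConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Nonlinear kinetics (reference form, used for cross-checks and diagnostics)
# ---------------------------------------------------------------------------

def reaction_rates(fields: FieldState, params: ParameterSet) -> dict:
    """Pointwise nonlinear reaction terms of the six equations (no transport).

    Returns dz/dt contributions per field as arrays; the strain 'reaction'
    excludes the (1-eps)*dv/dx production which involves a spatial
    derivative.  This is the reference nonlinear form that the hard-coded
    linearization is tested against.
    """
    p = params
    c, N, M, rho, eps = fields.c, fields.N, fields.M, fields.rho, fields.eps
    mmp = (N + p.eta_II * M) / (1.0 + p.a_c_II * c)
    f_c = (p.k_c * c / (p.a_c_I + c) * (N + p.eta_I * M)
           - p.delta_c * mmp * rho * c)
    growN = np.where(N > 0, np.power(np.where(N > 0, N, 1.0), 1.0 + p.q), 0.0)
    growM = np.where(M > 0, np.power(np.where(M > 0, M, 1.0), 1.0 + p.q), 0.0)
    crowd = 1.0 - p.kappa_F * (N + M)
    f_N = (p.r_F * (1.0 + p.r_F_max * c / (p.a_c_III + c)) * crowd * growN
           - p.k_F * c * N - p.delta_N * N)
    f_M = (p.r_F * ((1.0 + p.r_F_max) * c / (p.a_c_III + c)) * crowd * growM
           + p.k_F * c * N - p.delta_M * M)
    f_rho = (p.k_rho * (1.0 + p.k_rho_max * c / (p.a_c_IV + c)) * (N + p.eta_I * M)
             - p.delta_rho * mmp * rho * rho)
    f_eps = -p.zeta * (N + p.eta_II * M) * c / (1.0 + p.a_c_II * c) * eps
    return {"c": f_c, "N": f_N, "M": f_M, "rho": f_rho,
            "v": np.zeros_like(c), "eps": f_eps}


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class StepSystem:
    """One backward-Euler/Picard linear system in banded storage.

    ab is the (2*BANDWIDTH+1, 6*m) diagonal-ordered band matrix of
    ``scipy.linalg.solve_banded``; rhs the right-hand side.
    """

    ab: np.ndarray
    rhs: np.ndarray
    n_nodes: int

    def to_dense(self) -> np.ndarray:
        ntot = NFIELDS * self.n_nodes
        A = np.zeros((ntot, ntot))
        for r in range(self.ab.shape[0]):
            offset = BANDWIDTH - r  # diagonal index: A[i, i+offset]
            for j in range(ntot):
                i = j - offset
                if 0 <= i < ntot:
                    A[i, j] = self.ab[r, j]
        return A

    def solve(self) -> np.ndarray:
        return scipy.linalg.solve_banded(
            (BANDWIDTH, BANDWIDTH), self.ab, self.rhs)


def _elem_mean(z: np.ndarray) -> np.ndarray:
    return 0.5 * (z[:-1] + z[1:])


def _lumped_mass(h: np.ndarray) -> np.ndarray:
    m = np.zeros(len(h) + 1)
    m[:-1] += 0.5 * h
    m[1:] += 0.5 * h
    return m


class _Band:
    """Accumulator for the interleaved banded matrix."""

    def __init__(self, m: int):
        self.m = m
        self.ab = np.zeros((2 * BANDWIDTH + 1, NFIELDS * m))
        self.rhs = np.zeros(NFIELDS * m)
        self._p = np.arange(m - 1)

    def add_diag(self, f: int, vals: np.ndarray):
        idx = NFIELDS * np.arange(self.m) + f
        self.ab[BANDWIDTH, idx] += vals

    def add_elem_block(self, f_row: int, f_col: int,
                       wpp, wpq, wqp, wqq):
        """Add per-element 2x2 blocks [[wpp, wpq],[wqp, wqq]] for the
        (f_row, f_col) field pair; w* are arrays over elements."""
        p = self._p
        gi_p = NFIELDS * p + f_row
        gi_q = gi_p + NFIELDS
        gj_p = NFIELDS * p + f_col
        gj_q = gj_p + NFIELDS
        for gi, gj, w in ((gi_p, gj_p, wpp), (gi_p, gj_q, wpq),
                          (gi_q, gj_p, wqp), (gi_q, gj_q, wqq)):
            np.add.at(self.ab, (BANDWIDTH + gi - gj, gj), w)

    def add_rhs(self, f: int, vals: np.ndarray):
        self.rhs[NFIELDS * np.arange(self.m) + f] += vals

    def set_dirichlet(self, node: int, f: int, value: float):
        i = NFIELDS * node + f
        ntot = NFIELDS * self.m
        for j in range(max(0, i - BANDWIDTH), min(ntot, i + BANDWIDTH + 1)):
            self.ab[BANDWIDTH + i - j, j] = 0.0
        self.ab[BANDWIDTH, i] = 1.0
        self.rhs[i] = value


def _stiffness(band: _Band, f: int, w_e: np.ndarray, h: np.ndarray):
    k = w_e / h
    band.add_elem_block(f, f, k, -k, -k, k)


def _mass_like(band: _Band, f_row: int, f_col: int, coeff_nodes: np.ndarray,
               h: np.ndarray, lumping: bool, sign: float = 1.0):
    """Add sign * integral(coeff * z * phi_i); coeff given at nodes."""
    if lumping:
        mass = _lumped_mass(h) * coeff_nodes
        if f_row == f_col:
            band.add_diag(f_row, sign * mass)
        else:
            # lumped off-diagonal field coupling: diagonal in node index
            idx_i = NFIELDS * np.arange(band.m) + f_row
            idx_j = NFIELDS * np.arange(band.m) + f_col
            np.add.at(band.ab, (BANDWIDTH + idx_i - idx_j, idx_j), sign * mass)
    else:
        w_e = _elem_mean(coeff_nodes)
        band.add_elem_block(f_row, f_col,
                            sign * w_e * h / 3.0, sign * w_e * h / 6.0,
                            sign * w_e * h / 6.0, sign * w_e * h / 3.0)


def assemble_step_system(fields: FieldState, mesh: MeshState,
                         params: ParameterSet, dt: float,
                         picard_iterate: tuple,
                         config: SolverConfig,
                         eq: EquilibriumState) -> StepSystem:
    """Assemble the monolithic Galerkin system for one implicit step.

    ``fields``/``mesh`` are the converged state at time t; ``picard_iterate``
    is an (iterate_fields, iterate_mesh) pair at t + dt used to freeze all
    nonlinear coefficients and the mesh geometry.  Dirichlet rows implement
    the boundary data; collagen and strain carry no boundary rows (their
    equations have no spatial flux term).
    """
    p = params
    it, it_mesh = picard_iterate
    m = mesh.n_nodes
    h_old = mesh.h
    h_new = it_mesh.h
    if np.any(h_new <= 0):
        raise BlowUpError("mesh tangling in Picard iterate", mesh.t,
                          fields, mesh)
    lump = config.lumping
    band = _Band(m)
    m_old = _lumped_mass(h_old)
    ones = np.ones(m)

    F = {name: i for i, name in enumerate(FIELD_NAMES)}
    c_s, N_s, M_s, rho_s, eps_s = it.c, it.N, it.M, it.rho, it.eps

    # --- time-derivative terms: (M_new z - M_old z_old)/dt ------------------
    for name in FIELD_NAMES:
        f = F[name]
        w = p.rho_t if name == "v" else 1.0
        _mass_like(band, f, f, ones * (w / dt), h_new, lump)
        if lump:
            band.add_rhs(f, (w / dt) * m_old * getattr(fields, name))
        else:
            w_e = np.full(m - 1, w / dt)
            zo = getattr(fields, name)
            r = np.zeros(m)
            r[:-1] += w_e * h_old * (zo[:-1] / 3.0 + zo[1:] / 6.0)
            r[1:] += w_e * h_old * (zo[:-1] / 6.0 + zo[1:] / 3.0)
            band.add_rhs(f, r)

    # --- signaling molecules ------------------------------------------------
    _stiffness(band, F["c"], np.full(m - 1, p.D_c), h_new)
    decay_c = p.delta_c * (N_s + p.eta_II * M_s) * rho_s / (1.0 + p.a_c_II * c_s)
    secr_c = p.k_c * (N_s + p.eta_I * M_s) / (p.a_c_I + c_s)
    _mass_like(band, F["c"], F["c"], decay_c - secr_c, h_new, lump)

    # --- fibroblasts and myofibroblasts ------------------------------------
    dF_e = p.D_F * _elem_mean(N_s + M_s)
    gc_e = np.diff(c_s) / h_new                    # frozen chemo gradient
    chemo = 0.5 * p.chi_F * gc_e
    for name in ("N", "M"):
        f = F[name]
        _stiffness(band, f, dF_e, h_new)
        band.add_elem_block(f, f, -chemo, -chemo, chemo, chemo)
    crowd = 1.0 - p.kappa_F * (N_s + M_s)
    hillIII = c_s / (p.a_c_III + c_s)
    posN = N_s > 0
    prolif_N = np.where(
        posN,
        p.r_F * (1.0 + p.r_F_max * hillIII) * crowd
        * np.power(np.where(posN, N_s, 1.0), p.q),
        0.0)
    _mass_like(band, F["N"], F["N"],
               p.delta_N + p.k_F * c_s - prolif_N, h_new, lump)
    _mass_like(band, F["M"], F["M"], np.full(m, p.delta_M), h_new, lump)
    # differentiation source and myofibroblast proliferation (explicit at the
    # iterate: M_bar = 0 makes an implicit M**q coefficient singular)
    posM = M_s > 0
    prolif_M = np.where(
        posM,
        p.r_F * ((1.0 + p.r_F_max) * hillIII) * crowd
        * np.power(np.where(posM, M_s, 1.0), 1.0 + p.q),
        0.0)
    band.add_rhs(F["M"], _lumped_mass(h_new) * (p.k_F * c_s * N_s + prolif_M)
                 if lump else _consistent_rhs(h_new, p.k_F * c_s * N_s + prolif_M))

    # --- collagen -----------------------------------------------------------
    decay_rho = p.delta_rho * (N_s + p.eta_II * M_s) * rho_s / (1.0 + p.a_c_II * c_s)
    _mass_like(band, F["rho"], F["rho"], decay_rho, h_new, lump)
    src_rho = p.k_rho * (1.0 + p.k_rho_max * c_s / (p.a_c_IV + c_s)) \
        * (N_s + p.eta_I * M_s)
    band.add_rhs(F["rho"], _lumped_mass(h_new) * src_rho
                 if lump else _consistent_rhs(h_new, src_rho))

    # --- displacement velocity ---------------------------------------------
    _stiffness(band, F["v"], np.full(m - 1, p.mu), h_new)
    el = 0.5 * p.E * np.sqrt(_elem_mean(rho_s))
    band.add_elem_block(F["v"], F["eps"], -el, -el, el, el)
    body_e = p.xi * _elem_mean(M_s * rho_s / (p.R ** 2 + rho_s ** 2))
    rv = np.zeros(m)
    rv[:-1] += body_e
    rv[1:] -= body_e
    band.add_rhs(F["v"], rv)

    # --- effective strain ---------------------------------------------------
    alpha = p.zeta * (N_s + p.eta_II * M_s) * c_s / (1.0 + p.a_c_II * c_s)
    _mass_like(band, F["eps"], F["eps"], alpha, h_new, lump)
    # on the material mesh the strain equation reduces exactly to
    # d/dt int(eps phi) = int(phi (dv/dx - alpha eps)): the v coupling is
    # the linear projection -int(phi_i dphi_j/dx), no frozen coefficient
    g = np.full(m - 1, 0.5)
    band.add_elem_block(F["eps"], F["v"], g, -g, g, -g)

    # --- boundary conditions ------------------------------------------------
    left = {"c": 0.0, "N": eq.N_bar, "M": 0.0, "v": 0.0}
    for name, val in left.items():
        band.set_dirichlet(0, F[name], val)
    if config.boundary_mode == "full":
        for name, val in left.items():
            band.set_dirichlet(m - 1, F[name], val)
    else:  # half: symmetry plane on the right
        band.set_dirichlet(m - 1, F["v"], 0.0)

    return StepSystem(ab=band.ab, rhs=band.rhs, n_nodes=m)


def _consistent_rhs(h: np.ndarray, src_nodes: np.ndarray) -> np.ndarray:
    w = np.zeros(len(h) + 1)
    w[:-1] += h * (src_nodes[:-1] / 3.0 + src_nodes[1:] / 6.0)
    w[1:] += h * (src_nodes[:-1] / 6.0 + src_nodes[1:] / 3.0)
    return w


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

@dataclass
class StepInfo:
    converged: bool
    iterations: int
    error: float


def _apply_dirichlet_exactly(fields: FieldState, config: SolverConfig,
                             eq: EquilibriumState) -> None:
    """Re-impose the boundary data bit-exactly (LU pivoting can leave
    O(1e-20) residues on constrained unknowns, which would slowly drift the
    mesh endpoints)."""
    values = {"c": 0.0, "N": eq.N_bar, "M": 0.0, "v": 0.0}
    for name, val in values.items():
        getattr(fields, name)[0] = val
        if config.boundary_mode == "full":
            getattr(fields, name)[-1] = val
    if config.boundary_mode == "half":
        fields.v[-1] = 0.0


def _update_error(new: FieldState, old: FieldState) -> float:
    err = 0.0
    for name in FIELD_NAMES:
        a = getattr(new, name)
        b = getattr(old, name)
        scale = max(float(np.max(np.abs(a))), 1e-300)
        err = max(err, float(np.max(np.abs(a - b))) / scale)
    return err


def advance(fields: FieldState, mesh: MeshState, config: SolverConfig,
            params: ParameterSet, eq: EquilibriumState,
            dt: float | None = None):
    """One backward-Euler step with inner Picard iterations.

    Returns (fields', mesh', StepInfo).  Nodes move by dt * v at the new
    time level and the displacement u accumulates the same increment.
    Raises :class:`BlowUpError` on singular systems, non-finite solutions,
    mesh tangling, or diverging Picard iterations.
    """
    if dt is None:
        dt = config.dt_at(mesh.t)
    it_fields = fields.copy()
    err = math.inf
    converged = False
    iterations = 0
    for iterations in range(1, config.picard_max + 1):
        new_nodes = mesh.nodes + dt * it_fields.v
        if np.any(np.diff(new_nodes) <= 0):
            raise BlowUpError("mesh tangling", mesh.t, fields, mesh)
        it_mesh = MeshState(nodes=new_nodes, u=mesh.u, t=mesh.t)
        system = assemble_step_system(fields, mesh, params, dt,
                                      (it_fields, it_mesh), config, eq)
        if not np.all(np.isfinite(system.ab)) or not np.all(np.isfinite(system.rhs)):
            raise BlowUpError("non-finite entries in assembled system",
                              mesh.t, fields, mesh)
        try:
            sol = system.solve()
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise BlowUpError(f"singular step matrix ({exc})", mesh.t,
                              fields, mesh) from exc
        if not np.all(np.isfinite(sol)):
            raise BlowUpError("NaN in solution", mesh.t, fields, mesh)
        new_fields = FieldState.from_vector(sol)
        _apply_dirichlet_exactly(new_fields, config, eq)
        err = _update_error(new_fields, it_fields)
        it_fields = new_fields
        if err < config.picard_tol:
            converged = True
            break
    if not converged and err > config.picard_fail_tol:
        raise BlowUpError(
            f"Picard iterations diverged (update {err:.3g} after "
            f"{iterations} iterations)", mesh.t, fields, mesh)

    new_nodes = mesh.nodes + dt * it_fields.v
    if np.any(np.diff(new_nodes) <= 0):
        raise BlowUpError("mesh tangling", mesh.t, fields, mesh)
    new_mesh = MeshState(nodes=new_nodes, u=mesh.u + dt * it_fields.v,
                         t=mesh.t + dt)
    neg = [name for name in ("c", "N", "M", "rho")
           if float(np.min(getattr(it_fields, name))) < 0.0]
    if neg:
        logger.warning("monotonicity loss at t=%.4g: negative %s",
                       new_mesh.t, ", ".join(neg))
    return it_fields, new_mesh, StepInfo(converged, iterations, err)


def relative_surface_area(mesh: MeshState, markers: Sequence[int],
                          initial_distance: float) -> float:
    """Current distance between the wound-edge marker nodes over the initial
    distance; equals 1 at t = 0 and falls below 1 under contraction."""
    i, j = markers
    d = mesh.nodes[j] - mesh.nodes[i]
    if d <= 0:
        raise ValueError("wound markers have crossed (nonphysical)")
    return d / initial_distance


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time series and final state of one simulation run."""

    history: dict                 # column -> list of per-step values
    final_fields: FieldState
    final_mesh: MeshState
    termination: str              # 'completed' | 'blow-up'
    reason: str = ""
    blowup_time: float | None = None
    markers: tuple | None = None
    snapshots: list = field(default_factory=list)

    def frame(self):
        import pandas as pd
        return pd.DataFrame(self.history)


def simulate(fields: FieldState, mesh: MeshState, config: SolverConfig,
             params: ParameterSet, eq: EquilibriumState, t_end: float,
             markers: Sequence[int] | None = None,
             observers: Sequence[Callable] | None = None,
             events: Sequence[tuple] | None = None,
             snapshot_times: Sequence[float] | None = None) -> Trajectory:
    """Run the solver to t_end, recording extrema, RSAW and Picard counts.

    events: optional ((time, fn), ...) applied as fields = fn(fields, mesh)
    when the simulation reaches that time (the step is clipped to land on
    it).  On blow-up the partial trajectory is returned with the termination
    reason instead of raising.
    """
    fields = fields.copy()
    mesh = mesh.copy()
    d0 = None
    if markers is not None:
        d0 = mesh.nodes[markers[1]] - mesh.nodes[markers[0]]
    events = sorted(events or [], key=lambda e: e[0])
    snaps = sorted(snapshot_times or [])
    hist: dict = {k: [] for k in
                  ["t"] + [f"{f}_{s}" for f in FIELD_NAMES for s in ("min", "max")]
                  + [f"{f}_center" for f in FIELD_NAMES]
                  + (["rsaw"] if markers is not None else [])
                  + ["picard_iterations"]}
    snapshots = []

    def record():
        hist["t"].append(mesh.t)
        for f in FIELD_NAMES:
            arr = getattr(fields, f)
            hist[f"{f}_min"].append(float(arr.min()))
            hist[f"{f}_max"].append(float(arr.max()))
            hist[f"{f}_center"].append(float(arr[-1]))
        if markers is not None:
            hist["rsaw"].append(relative_surface_area(mesh, markers, d0))
        hist["picard_iterations"].append(last_info.iterations if last_info else 0)
        if observers:
            for obs in observers:
                for key, val in obs(mesh.t, fields, mesh).items():
                    hist.setdefault(key, []).append(val)

    last_info = None
    record()
    termination, reason, blow_t = "completed", "", None
    while mesh.t < t_end - 1e-9:
        dt = config.dt_at(mesh.t)
        dt = min(dt, t_end - mesh.t)
        for t_ev, _fn in events:
            if mesh.t < t_ev - 1e-9:
                dt = min(dt, t_ev - mesh.t)
                break
        try:
            fields, mesh, last_info = advance(fields, mesh, config, params,
                                              eq, dt=dt)
        except BlowUpError as exc:
            termination, reason, blow_t = "blow-up", exc.reason, exc.t
            break
        while events and mesh.t >= events[0][0] - 1e-9:
            _, fn = events.pop(0)
            fields = fn(fields, mesh)
        if snaps and mesh.t >= snaps[0] - 1e-9:
            snaps.pop(0)
            snapshots.append((mesh.t, fields.copy(), mesh.copy()))
        record()
    return Trajectory(history=hist, final_fields=fields, final_mesh=mesh,
                      termination=termination, reason=reason,
                      blowup_time=blow_t,
                      markers=tuple(markers) if markers is not None else None,
                      snapshots=snapshots)
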