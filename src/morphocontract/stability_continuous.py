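"""Fourier-mode linear stability of the continuous contraction model.

Perturbations around the equilibrium (0, N_bar, 0, rho_bar, 0, eps_bar) are
expanded in a complex Fourier series; each mode k obeys y' + A y = 0 with a
6x6 matrix A whose leading 4x4 block is lower triangular in the canonical
variable order (c, M, N, rho, v, eps).  The eigenvalues are therefore the
first four diagonal entries plus the roots of the mechanical 2x2 block,

    lambda = A55/2 +- sqrt(A55**2 + 4*A56*A65)/2,

and the equilibrium is linearly stable iff Re(lambda) >= 0 for every mode:

1. delta_c * rho_bar >= k_c / a_c_I          (signaling-molecule decay),
2. q * delta_N <= kappa_F * r_F * N_bar**(1+q)  (fibroblast crowding),
3. eps_bar <= 1                               (small-strain requirement).

Convergence is monotonic (all eigenvalues real) iff
mu >= sqrt(rho_t * E * sqrt(rho_bar) * (1 - eps_bar)) / pi, evaluated at the
slowest wave k = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .params import EquilibriumState, InvalidEquilibriumError, ParameterSet

#: canonical ordering of the perturbation variables in the linearized system
VARIABLE_ORDER = ("c", "M", "N", "rho", "v", "eps")

#: sparsity pattern of the 6x6 linearized matrix (True where an entry may be
#: nonzero); the leading 4x4 block is lower triangular
SPARSITY = np.array([
    [1, 0, 0, 0, 0, 0],
    [1, 1, 0, 0, 0, 0],
    [1, 1, 1, 0, 0, 0],
    [1, 1, 0, 1, 0, 0],
    [0, 1, 0, 1, 1, 1],
    [1, 0, 0, 0, 1, 0],
], dtype=bool)


@dataclass(frozen=True)
class FourierMode:
    """Integer Fourier mode k on a periodic domain of length omega_len (cm).

    The mode function is exp(2*pi*i*k*x/omega_len); k=0 is the constant
    (spatially uniform) perturbation.
    """

    k: int
    omega_len: float = 1.0

    def __post_init__(self):
        if int(self.k) != self.k:
            raise ValueError(f"mode index k must be an integer, got {self.k}")
        if self.omega_len <= 0:
            raise ValueError(f"omega_len must be > 0, got {self.omega_len}")

    @property
    def wavenumber(self) -> float:
        """The factor standing in for (2*pi*k): 2*pi*k/|Omega|, 1/cm."""
        return 2.0 * math.pi * self.k / self.omega_len


@dataclass(frozen=True)
class LinearizedSystem:
    """One Fourier/Von Neumann mode of the linearized model, y' + A y = 0."""

    A: np.ndarray          # 6x6 complex
    mode: object           # FourierMode or DiscreteMode

    def __post_init__(self):
        A = np.asarray(self.A, dtype=complex)
        if A.shape != (6, 6):
            raise ValueError(f"A must be 6x6, got {A.shape}")
        if np.any(A[~SPARSITY] != 0):
            raise ValueError("matrix violates the triangular-pivot sparsity pattern")
        object.__setattr__(self, "A", A)

    def entry(self, i: int, j: int) -> complex:
        """1-based entry accessor, e.g. entry(5, 6) -> A56."""
        return self.A[i - 1, j - 1]


def _assemble(params: ParameterSet, eq: EquilibriumState,
              theta2: float, theta1: float, mode,
              conj_sign: float = 1.0) -> LinearizedSystem:
    """Build the 6x6 mode matrix given the two wavenumber substitutions.

    theta2 stands in for (2*pi*k)^2 (second derivatives) and theta1 for the
    signed first-derivative factor (2*pi*k); the first-derivative entries
    carry +-i*theta1, with conj_sign = -1 for the semi-discrete convention
    (conjugate mode functions, exp(-i...)).
    """
    p, N, rho, eps = params, eq.N_bar, eq.rho_bar, eq.eps_bar
    if p.kappa_F * N >= 1.0:
        raise InvalidEquilibriumError(
            f"kappa_F * N_bar = {p.kappa_F * N:g} >= 1")

    i1 = conj_sign * 1j * theta1

    A = np.zeros((6, 6), dtype=complex)
    # signaling molecules
    A[0, 0] = p.D_c * theta2 + N * (p.delta_c * rho - p.k_c / p.a_c_I)
    # myofibroblasts
    A[1, 0] = -p.k_F * N
    A[1, 1] = p.D_F * N * theta2 + p.delta_M
    # fibroblasts
    A[2, 0] = (-p.chi_F * N * theta2
               - N * (p.r_F * p.r_F_max / p.a_c_III
                      * (1.0 - p.kappa_F * N) * N ** p.q - p.k_F))
    A[2, 1] = p.r_F * p.kappa_F * N ** (1.0 + p.q)
    A[2, 2] = (p.D_F * N * theta2 + p.delta_N
               - p.r_F * N ** p.q
               * ((1.0 + p.q) * (1.0 - p.kappa_F * N) - p.kappa_F * N))
    # collagen
    A[3, 0] = -p.delta_rho * rho ** 2 * N * (p.k_rho_max / p.a_c_IV + p.a_c_II)
    A[3, 1] = p.delta_rho * rho ** 2 * (p.eta_II - p.eta_I)
    A[3, 3] = 2.0 * p.delta_rho * N * rho
    # displacement velocity
    A[4, 1] = -i1 * p.xi * rho / (p.rho_t * (p.R ** 2 + rho ** 2))
    A[4, 3] = -i1 * p.E * eps / (2.0 * p.rho_t * math.sqrt(rho))
    A[4, 4] = p.mu / p.rho_t * theta2
    A[4, 5] = -i1 * p.E * math.sqrt(rho) / p.rho_t
    # effective strain
    A[5, 0] = p.zeta * eps * N
    A[5, 4] = i1 * (eps - 1.0)
    return LinearizedSystem(A=A, mode=mode)


def assemble_continuous(params: ParameterSet, eq: EquilibriumState,
                        mode: FourierMode) -> LinearizedSystem:
    """The 6x6 Fourier-mode matrix of the continuous linearized model."""
    th = mode.wavenumber
    return _assemble(params, eq, th * th, th, mode)


def eigenvalues_continuous(sys: LinearizedSystem) -> np.ndarray:
    """Analytic eigenvalues via the triangular pivot structure.

    Returns the six eigenvalues {A11, A22, A33, A44, A55/2 +- sqrt(...)/2}.
    The product A56*A65 is real for both the continuous and the semi-discrete
    convention, so the mechanical pair is either real or a complex-conjugate
    pair.
    """
    A = sys.A
    a55 = A[4, 4]
    disc = a55 * a55 + 4.0 * A[4, 5] * A[5, 4]
    root = np.sqrt(complex(disc))
    mech = np.array([0.5 * a55 + 0.5 * root, 0.5 * a55 - 0.5 * root])
    return np.concatenate([np.diag(A)[:4], mech])


@dataclass(frozen=True)
class StabilityReport:
    """Verdict of the three closed-form criteria plus per-mode eigenvalues."""

    eigenvalues: Mapping[int, np.ndarray]   # mode index -> 6 eigenvalues
    cond_signaling: bool      # delta_c * rho_bar >= k_c / a_c_I
    cond_fibroblast: bool     # q * delta_N <= kappa_F * r_F * N_bar**(1+q)
    cond_strain: bool         # eps_bar <= 1
    monotonic: bool           # all eigenvalues real (mu above threshold)
    mu_threshold: float       # (N day)/cm^2
    marginal: bool = False    # some criterion holds with equality (tol 1e-12)
    meta: dict = field(default_factory=dict)

    @property
    def stable(self) -> bool:
        return self.cond_signaling and self.cond_fibroblast and self.cond_strain

    @property
    def min_real_part(self) -> float:
        return min(float(np.min(ev.real)) for ev in self.eigenvalues.values())

    def to_dict(self) -> dict:
        return {
            "stable": self.stable,
            "cond_signaling": self.cond_signaling,
            "cond_fibroblast": self.cond_fibroblast,
            "cond_strain": self.cond_strain,
            "monotonic": self.monotonic,
            "marginal": self.marginal,
            "mu_threshold": self.mu_threshold,
            "min_real_part": self.min_real_part,
            "eigenvalues": {
                str(k): [[z.real, z.imag] for z in ev]
                for k, ev in self.eigenvalues.items()
            },
            **self.meta,
        }


def criteria(params: ParameterSet, eq: EquilibriumState,
             tol: float = 1e-12):
    """The three closed-form stability booleans plus a marginality flag."""
    lhs1 = params.delta_c * eq.rho_bar
    rhs1 = params.k_c / params.a_c_I
    lhs2 = params.q * params.delta_N
    rhs2 = params.kappa_F * params.r_F * eq.N_bar ** (1.0 + params.q)
    c1 = lhs1 >= rhs1 - tol * max(abs(rhs1), 1.0)
    c2 = lhs2 <= rhs2 + tol * max(abs(rhs2), 1.0)
    c3 = eq.eps_bar <= 1.0 + tol
    marginal = (
        math.isclose(lhs1, rhs1, rel_tol=tol, abs_tol=tol)
        or math.isclose(lhs2, rhs2, rel_tol=tol, abs_tol=tol)
        or math.isclose(eq.eps_bar, 1.0, rel_tol=tol, abs_tol=tol)
    )
    return c1, c2, c3, marginal


def mu_threshold_continuous(params: ParameterSet, eq: EquilibriumState) -> float:
    """Viscosity above which all eigenvalues are real (monotone decay), k=1.

    mu >= sqrt(rho_t * E * sqrt(rho_bar) * (1 - eps_bar)) / pi.  For
    eps_bar >= 1 the restoring force vanishes or reverses (saddle/degenerate
    case) and the threshold is not applicable.
    """
    if eq.eps_bar > 1.0:
        raise ValueError(
            "eps_bar > 1: saddle/degenerate case, no monotonicity threshold")
    return math.sqrt(
        params.rho_t * params.E * math.sqrt(eq.rho_bar) * (1.0 - eq.eps_bar)
    ) / math.pi


def delta_N_upper_bound(params: ParameterSet, eq: EquilibriumState) -> float:
    """Largest apoptosis rate compatible with the crowding criterion (k=0).

    The fibroblast criterion bounds the exponent by
    q <= kappa_F N_bar / (1 - kappa_F N_bar); through the logistic balance
    this caps delta_N at r_F (1 - kappa_F N_bar) N_bar**q_max.
    """
    kN = params.kappa_F * eq.N_bar
    if kN >= 1.0:
        raise InvalidEquilibriumError(f"kappa_F * N_bar = {kN:g} >= 1")
    q_max = kN / (1.0 - kN)
    return params.r_F * (1.0 - kN) * eq.N_bar ** q_max


def check_stability_continuous(params: ParameterSet, eq: EquilibriumState,
                               k_range: Iterable[int] = range(0, 11),
                               omega_len: float = 1.0,
                               tol: float = 1e-12) -> StabilityReport:
    """Full stability report: criteria booleans and per-mode eigenvalues."""
    c1, c2, c3, marginal = criteria(params, eq, tol)
    eigs = {
        k: eigenvalues_continuous(
            assemble_continuous(params, eq, FourierMode(k, omega_len)))
        for k in k_range
    }
    thr = mu_threshold_continuous(params, eq) if eq.eps_bar <= 1.0 else math.nan
    monotonic = bool(eq.eps_bar <= 1.0 and params.mu >= thr)
    return StabilityReport(
        eigenvalues=eigs, cond_signaling=bool(c1), cond_fibroblast=bool(c2),
        cond_strain=bool(c3), monotonic=monotonic, mu_threshold=thr,
        marginal=marginal,
        meta={"kind": "continuous", "omega_len": omega_len},
    )
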