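"""Von Neumann stability of the semi-discrete (spatially discretized) model.

On a uniform grid with spacing h (n intervals, h*n = |Omega| = 1) the
linearized equations with central differences admit discrete Fourier modes
exp(-2*pi*beta*k*h*i), beta = 1..n-1.  Each mode satisfies lambda*z = C*z
where C has the same triangular-pivot structure as the continuous mode
matrix, with the substitutions

    (2*pi*k)^2  ->  4*sin^2(pi*beta*h) / h^2      (second derivatives)
    (2*pi*k)    ->  sin(2*pi*beta*h) / h          (first derivatives)

Because 4*sin^2(pi*beta*h)/h^2 >= 0 and the mechanical product term is
proportional to sin^2(2*pi*beta*h) >= 0, the continuous stability criteria
imply the semi-discrete ones for every h > 0 (stability is unconditional in
the step size).  The discrete monotonicity threshold

    mu >= h/tan(pi*beta*h) * sqrt(rho_t*E*sqrt(rho_bar)*(1-eps_bar))

is never larger than the continuous one, since h/tan(pi*beta*h) <= 1/(pi*beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import EquilibriumState, ParameterSet
from .stability_continuous import (
    FourierMode,
    LinearizedSystem,
    StabilityReport,
    _assemble,
    assemble_continuous,
    criteria,
    eigenvalues_continuous,
)

#: guard band for the degenerate tan/sin cases (beta*h at integer or
#: half-integer values)
DEGENERACY_TOL = 1e-12


@dataclass(frozen=True)
class DiscreteMode:
    """Discrete Fourier mode beta on a uniform grid of n intervals.

    h is the grid spacing in cm with h*n = |Omega|; the analysis is carried
    out on the unit-length domain of the linearized problem, so h = 1/n.
    """

    beta: int
    h: float
    n: int

    def __post_init__(self):
        if not (1 <= self.beta <= self.n - 1):
            raise ValueError(
                f"beta must lie in 1..n-1, got beta={self.beta}, n={self.n}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")

    @property
    def theta2(self) -> float:
        """Substitute for (2*pi*k)^2: 4*sin^2(pi*beta*h)/h^2."""
        s = math.sin(math.pi * self.beta * self.h)
        return 4.0 * s * s / (self.h * self.h)

    @property
    def theta1(self) -> float:
        """Substitute for (2*pi*k): sin(2*pi*beta*h)/h (signed)."""
        return math.sin(2.0 * math.pi * self.beta * self.h) / self.h


def assemble_discrete(params: ParameterSet, eq: EquilibriumState,
                      mode: DiscreteMode) -> LinearizedSystem:
    """The 6x6 Von Neumann mode matrix of the semi-discrete model.

    The imaginary first-derivative entries carry the opposite sign to the
    continuous matrix (conjugate mode-function convention); eigenvalues and
    all stability quantities are unaffected.
    """
    return _assemble(params, eq, mode.theta2, mode.theta1, mode,
                     conj_sign=-1.0)


def eigenvalues_discrete(sys: LinearizedSystem) -> np.ndarray:
    """Analytic eigenvalues; identical pivot structure to the continuous case."""
    return eigenvalues_continuous(sys)


def mu_threshold_discrete(params: ParameterSet, eq: EquilibriumState,
                          h: float, beta: int) -> float:
    """Discrete monotonicity threshold h/tan(pi*beta*h) * sqrt(rho_t*E*sqrt(rho_bar)*(1-eps_bar)).

    Always <= the continuous threshold.  At beta*h = 1/2 (mod 1) the tangent
    diverges and the threshold is 0; at integer beta*h the mode degenerates
    (sin = 0) and the threshold is undefined.
    """
    if eq.eps_bar > 1.0:
        raise ValueError(
            "eps_bar > 1: saddle/degenerate case, no monotonicity threshold")
    x = beta * h
    frac = x - math.floor(x)
    if min(frac, 1.0 - frac) < DEGENERACY_TOL:
        raise ValueError(
            f"beta*h = {x:g} is an integer: degenerate (aliased) mode")
    if abs(frac - 0.5) < DEGENERACY_TOL:
        return 0.0
    amp = math.sqrt(
        params.rho_t * params.E * math.sqrt(eq.rho_bar) * (1.0 - eq.eps_bar))
    return h / math.tan(math.pi * x) * amp


def check_stability_discrete(params: ParameterSet, eq: EquilibriumState,
                             h: float, n: int,
                             tol: float = 1e-12) -> StabilityReport:
    """Stability report over all discrete modes beta = 1..n-1.

    By the unconditional-stability result the verdict coincides with the
    continuous one for the same parameters, for every h.
    """
    if abs(h * n - 1.0) > 1e-9:
        raise ValueError(f"expected h*n = 1 (unit domain), got {h * n:g}")
    c1, c2, c3, marginal = criteria(params, eq, tol)
    eigs = {
        beta: eigenvalues_discrete(
            assemble_discrete(params, eq, DiscreteMode(beta, h, n)))
        for beta in range(1, n)
    }
    thr = mu_threshold_discrete(params, eq, h, 1) if eq.eps_bar <= 1.0 else math.nan
    monotonic = bool(eq.eps_bar <= 1.0 and params.mu >= thr)
    return StabilityReport(
        eigenvalues=eigs, cond_signaling=bool(c1), cond_fibroblast=bool(c2),
        cond_strain=bool(c3), monotonic=monotonic, mu_threshold=thr,
        marginal=marginal,
        meta={"kind": "discrete", "h": h, "n": n},
    )


def consistency_gap(params: ParameterSet, eq: EquilibriumState, k: int,
                    h_list: Sequence[float]) -> dict:
    """Observed order of |lambda_discrete(h) - lambda_continuous| in h.

    For fixed mode index k = beta, the eigenvalue gap shrinks as O(h^2); the
    log-log slope per eigenvalue is fitted by least squares over h_list.
    Eigenvalues whose gap is identically ~0 (e.g. the collagen rate, which
    carries no spatial operator) are reported with slope nan.
    """
    h_arr = np.asarray(sorted(h_list, reverse=True), dtype=float)
    if np.any(h_arr <= 0) or len(h_arr) < 2:
        raise ValueError("need at least two positive spacings")
    cont = np.sort_complex(eigenvalues_continuous(
        assemble_continuous(params, eq, FourierMode(k))))
    gaps = np.empty((len(h_arr), 6))
    for i, h in enumerate(h_arr):
        n = int(round(1.0 / h))
        disc = np.sort_complex(eigenvalues_discrete(
            assemble_discrete(params, eq, DiscreteMode(k, h, n))))
        gaps[i] = np.abs(disc - cont)
    scale = max(np.abs(cont).max(), 1e-300)
    slopes = np.full(6, np.nan)
    for j in range(6):
        g = gaps[:, j]
        if np.all(g > 1e-13 * scale):
            slopes[j] = np.polyfit(np.log(h_arr), np.log(g), 1)[0]
    return {"h": h_arr, "gaps": gaps, "slopes": slopes,
            "continuous": cont}


def gershgorin_bounds(sys: LinearizedSystem) -> np.ndarray:
    """Secondary check only: Gershgorin lower bounds on Re(lambda) per row.

    Far less sharp than the analytic eigenvalues; exposed for diagnostics,
    never used in the stability verdict.
    """
    A = sys.A
    centers = np.diag(A).real
    radii = np.sum(np.abs(A), axis=1) - np.abs(np.diag(A))
    return centers - radii
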