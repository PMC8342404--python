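"""Initial-value scenarios: the wound profile and perturbed equilibria.

Two families of initial conditions are generated:

* :class:`WoundScenario` — a 10 cm stretch of skin with a 4 cm wound in the
  middle.  Inside the wound the fibroblast, signaling-molecule and collagen
  densities take depressed wound values; over a 1 cm ramp on each side they
  blend back to the healthy equilibrium by a half-period sine (cosine)
  transition.  Used for the convergence study.
* :class:`PerturbationScenario` — small perturbations around the healthy
  equilibrium on the half-domain [0, 1] cm (the right end is the symmetry
  plane at the wound centre).  Fields with nonzero equilibrium (N, rho) and
  the mechanical fields (v, eps) are perturbed by sine waves with k half
  periods; the zero-equilibrium densities (M, c) use non-negative natural
  cubic-spline bumps through 2k+1 uniform knots whose interior values
  alternate between a low and a high level, starting with the low one.
  Used for the stability-validation runs.

Profiles are defined as continuous functions of x and sampled at the mesh
nodes, so refining the mesh changes the samples, never the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .params import EquilibriumState
from .solver import FieldState, MeshState


@dataclass(frozen=True)
class WoundScenario:
    """Geometry and wound-state values of the convergence-study scenario.

    Lengths in cm; the wound plateau is centred.  c_w, rho_w in g/cm^3 and
    N_w in cells/cm^3 are the depressed densities inside the wound.
    """

    domain_length: float = 10.0
    wound_length: float = 4.0
    ramp_length: float = 1.0
    c_w: float = 1.0e-8
    N_w: float = 2000.0
    rho_w: float = 0.01125

    def __post_init__(self):
        if self.wound_length + 2 * self.ramp_length > self.domain_length:
            raise ValueError("wound plus ramps exceed the domain")
        if min(self.domain_length, self.wound_length, self.ramp_length) <= 0:
            raise ValueError("geometry lengths must be positive")

    @property
    def edges(self) -> tuple[float, float]:
        """x positions of the wound (plateau) edges."""
        c = 0.5 * self.domain_length
        return (c - 0.5 * self.wound_length, c + 0.5 * self.wound_length)


@dataclass(frozen=True)
class PerturbationScenario:
    """Perturbed-equilibrium initial state on the half-domain [0, 1].

    k counts half periods of the sine perturbations; amp_N (cells/cm^3),
    amp_rho (g/cm^3), amp_v (cm/day) and amp_eps are the wave amplitudes.
    M and c use spline bumps with interior knot levels (low, high)
    alternating, in cells/cm^3 and g/cm^3 respectively.
    """

    k: int = 1
    amp_N: float = 10.0
    amp_rho: float = 1.0e-2
    amp_v: float = 0.05
    amp_eps: float = 0.5
    M_low: float = 3.0
    M_high: float = 6.0
    c_low: float = 0.5e-15
    c_high: float = 2.0e-15
    domain_length: float = 1.0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if min(self.M_low, self.M_high, self.c_low, self.c_high) < 0:
            raise ValueError("spline knot levels must be non-negative")


def _ramp_profile(scn: WoundScenario, z_w: float, z_eq: float):
    """Continuous profile: z_w inside the plateau, z_eq outside the ramps,
    half-sine blend across each ramp (the ramp midpoint takes the mean)."""
    a = 0.5 * scn.wound_length
    r = scn.ramp_length
    centre = 0.5 * scn.domain_length

    def profile(x):
        d = np.abs(np.asarray(x, dtype=float) - centre)
        t = np.clip((d - a) / r, 0.0, 1.0)
        return z_w + (z_eq - z_w) * 0.5 * (1.0 - np.cos(math.pi * t))

    return profile


def make_wound_profile(scn: WoundScenario, mesh: MeshState,
                       eq: EquilibriumState) -> FieldState:
    """Sample the wound initial condition at the mesh nodes.

    Myofibroblasts, velocity and strain start at zero everywhere.
    """
    x = mesh.nodes
    if x[0] > 1e-12 or abs(x[-1] - scn.domain_length) > 1e-9:
        raise ValueError(
            f"mesh [{x[0]:g}, {x[-1]:g}] does not span the scenario domain "
            f"[0, {scn.domain_length:g}]")
    return FieldState(
        c=_ramp_profile(scn, scn.c_w, eq.c_bar)(x),
        N=_ramp_profile(scn, scn.N_w, eq.N_bar)(x),
        M=np.zeros_like(x),
        rho=_ramp_profile(scn, scn.rho_w, eq.rho_bar)(x),
        v=np.zeros_like(x),
        eps=np.zeros_like(x),
    )


def wound_marker_indices(scn: WoundScenario, mesh: MeshState,
                         tol: float = 1e-9) -> tuple[int, int]:
    """Node indices at the wound edges (for RSAW tracking).

    The edges must coincide with mesh nodes (they do on every ladder grid).
    """
    idx = []
    for edge in scn.edges:
        i = int(np.argmin(np.abs(mesh.nodes - edge)))
        if abs(mesh.nodes[i] - edge) > tol:
            raise ValueError(f"wound edge x = {edge:g} is not a mesh node")
        idx.append(i)
    return tuple(idx)


def _spline_bump(k: int, low: float, high: float, length: float):
    """Shape-preserving cubic spline through 2k+1 uniform knots: zero at the
    ends, interior values alternating low, high, low, ...

    A monotonicity-preserving (PCHIP) cubic is used rather than a natural
    interpolating spline: the latter overshoots below zero near the end
    knots for k >= 5, violating the required non-negativity of the density
    profiles.  PCHIP stays within the knot range, so positivity of the knot
    values guarantees positivity of the profile; the check below still
    guards the invariant.
    """
    knots_x = np.linspace(0.0, length, 2 * k + 1)
    vals = np.zeros(2 * k + 1)
    inner = np.arange(1, 2 * k)
    vals[inner] = np.where(inner % 2 == 1, low, high)
    spl = PchipInterpolator(knots_x, vals)
    xx = np.linspace(0.0, length, max(4001, 200 * k))
    if float(spl(xx).min()) < -1e-12 * max(low, high):
        raise ValueError(
            "generated spline bump is negative; choose other knot levels")
    return spl


def make_perturbation_profile(scn: PerturbationScenario, mesh: MeshState,
                              eq: EquilibriumState) -> FieldState:
    """Sample the perturbed-equilibrium initial condition at the mesh nodes.

    All perturbations vanish at both ends of [0, L], so the Dirichlet data
    (c=0, N=N_bar, M=0, v=0) holds exactly on the boundary.
    """
    x = mesh.nodes
    L = scn.domain_length
    if x[0] > 1e-12 or abs(x[-1] - L) > 1e-9:
        raise ValueError(
            f"mesh [{x[0]:g}, {x[-1]:g}] does not span [0, {L:g}]")
    wave = np.sin(scn.k * math.pi * x / L)
    spl_M = _spline_bump(scn.k, scn.M_low, scn.M_high, L)
    spl_c = _spline_bump(scn.k, scn.c_low, scn.c_high, L)
    return FieldState(
        c=np.maximum(spl_c(x), 0.0),
        N=eq.N_bar + scn.amp_N * wave,
        M=np.maximum(spl_M(x), 0.0),
        rho=eq.rho_bar + scn.amp_rho * wave,
        v=scn.amp_v * wave,
        eps=eq.eps_bar + scn.amp_eps * wave,
    )
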