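"""Model parameters and closed-form equilibrium relations.

The contraction model couples four constituents (signaling molecules c,
fibroblasts N, myofibroblasts M, collagen rho) to the tissue mechanics
(displacement velocity v, effective strain eps).  Around the healthy
equilibrium (c, N, M, rho, v, eps) = (0, N_bar, 0, rho_bar, 0, eps_bar)
three algebraic relations tie the kinetic constants together:

* the fibroblast apoptosis rate follows from the logistic balance,
  ``delta_N = r_F (1 - kappa_F N_bar) N_bar**q``;
* inverting that relation fixes the crowding exponent ``q``;
* the collagen equilibrium is ``rho_bar = sqrt(k_rho / delta_rho)``.

Units are documented metadata; no runtime unit algebra is performed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


class InvalidEquilibriumError(ValueError):
    """Raised when kappa_F * N_bar >= 1, which would force delta_N <= 0."""


# Fields that are allowed to be zero or negative; everything else must be
# strictly positive.  q may take either sign (it is -0.4151 for the default
# parameter set); the dimensionless enhancement factors may be zero.
_SIGN_EXEMPT = {"q"}
_NONNEG = {"eta_II", "r_F_max", "k_rho_max"}


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic and mechanical constants of the contraction model.

    Attributes
    ----------
    D_c : float
        Diffusion coefficient of the signaling molecules, cm^2/day.
    D_F : float
        (Myo)fibroblast diffusion coefficient, cm^5/(cells day).
    chi_F : float
        Chemotaxis coefficient, cm^5/(g day).
    k_c : float
        Maximum net secretion rate of signaling molecules, g/(cells day).
    r_F : float
        Cell division rate, cm^{3q}/(cells^q day).
    r_F_max : float
        Maximum division-rate enhancement factor, dimensionless.
    k_rho : float
        Collagen secretion rate, g/(cells day).
    k_rho_max : float
        Maximum collagen-secretion enhancement factor, dimensionless.
    a_c_I, a_c_III, a_c_IV : float
        Half-maximum concentrations of the Hill factors, g/cm^3.
    a_c_II : float
        MMP-secretion inhibition coefficient, cm^3/g.
    eta_I, eta_II : float
        Myofibroblast-to-fibroblast ratios in secretion, dimensionless.
    k_F : float
        Differentiation rate of fibroblasts to myofibroblasts, cm^3/(g day).
    kappa_F : float
        Crowding coefficient, cm^3/cells.
    q : float
        Crowding exponent, dimensionless (may be negative).
    delta_c, delta_rho, zeta : float
        Breakdown / morphoelastic-change rate parameters, cm^6/(cells g day).
    delta_N, delta_M : float
        Apoptosis rates, 1/day.
    rho_t : float
        Total mass density of dermal tissue, g/cm^3.
    mu : float
        Viscosity, (N day)/cm^2.
    E : float
        Stiffness coefficient (Young's modulus is E*sqrt(rho)), N/((g cm)^0.5).
    xi : float
        Generated stress per unit myofibroblast density, (N g)/(cells cm^2).
    R : float
        Body-force saturation constant, g/cm^3.
    """

    D_c: float
    D_F: float
    chi_F: float
    k_c: float
    r_F: float
    r_F_max: float
    k_rho: float
    k_rho_max: float
    a_c_I: float
    a_c_II: float
    a_c_III: float
    a_c_IV: float
    eta_I: float
    eta_II: float
    k_F: float
    kappa_F: float
    q: float
    delta_c: float
    delta_N: float
    delta_M: float
    delta_rho: float
    zeta: float
    rho_t: float
    mu: float
    E: float
    xi: float
    R: float

    def validate(self) -> "ParameterSet":
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v}")
            if f.name in _SIGN_EXEMPT:
                continue
            if f.name in _NONNEG:
                if v < 0:
                    raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")
        return self

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class EquilibriumState:
    """The analysed equilibrium (c, N, M, rho, v, eps) = (0, N_bar, 0, rho_bar, 0, eps_bar).

    c_bar, rho_bar in g/cm^3; N_bar, M_bar in cells/cm^3; v_bar in cm/day;
    eps_bar dimensionless.  eps_bar <= 1 is both a stability and a physical
    (small-strain) requirement; values above 1 are permitted here but flagged
    by the stability report.
    """

    N_bar: float
    rho_bar: float
    eps_bar: float = 0.0
    c_bar: float = 0.0
    M_bar: float = 0.0
    v_bar: float = 0.0

    @classmethod
    def from_params(cls, params: ParameterSet, N_bar: float = 1.0e4,
                    eps_bar: float = 0.0) -> "EquilibriumState":
        """Build the equilibrium implied by a parameter set.

        rho_bar follows from the collagen kinetics; N_bar is a free input
        (the default is the homeostatic fibroblast density of the packaged
        parameter set).
        """
        if params.kappa_F * N_bar >= 1.0:
            raise InvalidEquilibriumError(
                f"kappa_F * N_bar = {params.kappa_F * N_bar:g} >= 1: "
                "the logistic balance would force delta_N <= 0"
            )
        return cls(N_bar=N_bar,
                   rho_bar=collagen_equilibrium(params.k_rho, params.delta_rho),
                   eps_bar=eps_bar)


# ---------------------------------------------------------------------------
# Closed-form relations
# ---------------------------------------------------------------------------

def derive_delta_N(r_F: float, kappa_F: float, N_bar: float, q: float) -> float:
    """Apoptosis rate implied by the logistic equilibrium of the fibroblasts.

    delta_N = r_F * (1 - kappa_F * N_bar) * N_bar**q   (1/day)
    """
    if N_bar <= 0:
        raise ValueError(f"N_bar must be > 0, got {N_bar}")
    if kappa_F * N_bar >= 1.0:
        raise InvalidEquilibriumError(
            f"kappa_F * N_bar = {kappa_F * N_bar:g} >= 1 gives delta_N <= 0"
        )
    return r_F * (1.0 - kappa_F * N_bar) * N_bar ** q


def derive_q(delta_N: float, r_F: float, kappa_F: float, N_bar: float) -> float:
    """Crowding exponent consistent with a prescribed apoptosis rate.

    q = [ln(delta_N) - ln(r_F (1 - kappa_F N_bar))] / ln(N_bar)

    Natural logarithms are used; any consistent base gives the same ratio.
    Inverse of :func:`derive_delta_N` in its last argument.
    """
    if min(delta_N, r_F, N_bar) <= 0:
        raise ValueError("delta_N, r_F and N_bar must all be > 0")
    if kappa_F * N_bar >= 1.0:
        raise InvalidEquilibriumError(
            f"kappa_F * N_bar = {kappa_F * N_bar:g} >= 1 is inconsistent "
            "with a positive apoptosis rate"
        )
    if N_bar == 1.0:
        raise ZeroDivisionError("N_bar = 1 makes the exponent indeterminate")
    return (math.log(delta_N) - math.log(r_F * (1.0 - kappa_F * N_bar))) \
        / math.log(N_bar)


def collagen_equilibrium(k_rho: float, delta_rho: float) -> float:
    """Collagen equilibrium density rho_bar = sqrt(k_rho / delta_rho), g/cm^3."""
    if k_rho <= 0 or delta_rho <= 0:
        raise ValueError("k_rho and delta_rho must be > 0")
    return math.sqrt(k_rho / delta_rho)


def apoptosis_rate_from_lifespan(PD: float, DT: float) -> float:
    """Apoptosis rate from cell lifespan: ln(2) / (PD * DT / 24), 1/day.

    PD is the lifespan in population doublings, DT the doubling time in hours.
    """
    if PD <= 0 or DT <= 0:
        raise ValueError("PD and DT must be > 0")
    return math.log(2.0) / (PD * DT / 24.0)


# ---------------------------------------------------------------------------
# Serialization: flat key-value config and JSON
# ---------------------------------------------------------------------------

_PARAM_NAMES = tuple(f.name for f in dataclasses.fields(ParameterSet))


def parse_kv_text(text: str) -> dict:
    """Parse the package's plain-text key=value format into a str->str dict."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in out:
            raise ValueError(f"line {lineno}: duplicate key {key!r}")
        out[key] = val
    return out


def params_from_mapping(mapping: dict, *, validate: bool = True) -> ParameterSet:
    unknown = sorted(set(mapping) - set(_PARAM_NAMES))
    if unknown:
        raise ValueError(f"unknown parameter key(s): {', '.join(unknown)}")
    missing = sorted(set(_PARAM_NAMES) - set(mapping))
    if missing:
        raise ValueError(f"missing parameter key(s): {', '.join(missing)}")
    p = ParameterSet(**{k: float(mapping[k]) for k in _PARAM_NAMES})
    return p.validate() if validate else p


def read_params(path: str | Path) -> ParameterSet:
    """Read a parameter set from a key=value or .json file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return params_from_mapping(json.loads(text))
    return params_from_mapping(parse_kv_text(text))


def write_params(params: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True) + "\n")
    else:
        lines = [f"{k} = {getattr(params, k)!r}" for k in _PARAM_NAMES]
        path.write_text("\n".join(lines) + "\n")


def default_params() -> ParameterSet:
    """The packaged default parameter set (the published baseline values)."""
    text = resources.files("morphocontract.data").joinpath("defaults.cfg").read_text()
    return params_from_mapping(parse_kv_text(text))


def default_equilibrium(params: ParameterSet | None = None,
                        eps_bar: float = 0.0) -> EquilibriumState:
    """Equilibrium of the packaged defaults: N_bar = 1e4 cells/cm^3."""
    return EquilibriumState.from_params(params or default_params(), N_bar=1.0e4,
                                        eps_bar=eps_bar)
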