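"""Numerical experiments: convergence ladder, stability validation, reversion.

The convergence study contracts the 10 cm / 4 cm wound for one simulated
day on a ladder of node counts n in {41, 81, 161, 321, 641, 1281}
(n - 1 elements, h = 10/(n-1), time step dt = h^2) and measures, against
the finest run as reference, four error norms per variable:

* eps_41      — sum of absolute differences at the material nodes that
                started at the 41 coarse-grid positions (shared by the whole
                nested ladder);
* eps_L1      — trapezoid approximation of the integral of |z - z_h| on the
                reference mesh after linear interpolation of the coarse run;
* eps_L2      — likewise for the root of the integral of (z - z_h)^2;
* eps_boundary— absolute difference at the material node that started on the
                wound edge (x = 3 cm).

Least-squares log-log slopes of error vs h quantify the observed order
(expected about 2 for linear elements and dt = h^2).

The stability-validation matrix perturbs the equilibrium on the half-domain
[0, 1] (n = 500 elements) and varies the signaling-molecule decay rate
delta_c in {2e-4, 3e-4, 5e-4} cm^6/(cells g day) and the viscosity mu in
{1, 100} (N day)/cm^2, classifying each run as convergence to the healthy
equilibrium, convergence to a shifted equilibrium, or numerical blow-up,
and reporting the analytic criterion verdict alongside the empirical one.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import EquilibriumState, ParameterSet
from .scenarios import (
    PerturbationScenario,
    WoundScenario,
    make_perturbation_profile,
    make_wound_profile,
    wound_marker_indices,
)
from .solver import (
    FIELD_NAMES,
    FieldState,
    MeshState,
    SolverConfig,
    Trajectory,
    reaction_rates,
    simulate,
)
from .stability_continuous import check_stability_continuous

NORM_NAMES = ("eps_41", "eps_L1", "eps_L2", "eps_boundary")
LADDER = (41, 81, 161, 321, 641, 1281)

#: scales used for 'distance to equilibrium' of the perturbation runs: the
#: equilibrium magnitude where nonzero, else the initial perturbation size
PERTURBATION_SCALES = {"c": 2.0e-15, "N": 1.0e4, "M": 6.0, "rho": 0.1125,
                      "v": 0.05, "eps": 0.5}


# ---------------------------------------------------------------------------
# Error norms
# ---------------------------------------------------------------------------

def error_norm_41(z_h: np.ndarray, z_ref: np.ndarray) -> float:
    """Sum of absolute differences at the 41 shared coarse-grid nodes."""
    z_h = np.asarray(z_h, dtype=float)
    z_ref = np.asarray(z_ref, dtype=float)
    if z_h.shape != z_ref.shape:
        raise ValueError(
            f"mismatched evaluation points: {z_h.shape} vs {z_ref.shape}")
    return float(np.sum(np.abs(z_ref - z_h)))


@dataclass(frozen=True)
class ErrorNorms:
    eps_41: float
    eps_L1: float
    eps_L2: float
    eps_boundary: float

    def as_dict(self) -> dict:
        return {"eps_41": self.eps_41, "eps_L1": self.eps_L1,
                "eps_L2": self.eps_L2, "eps_boundary": self.eps_boundary}


def error_norms(z_h: np.ndarray, z_ref: np.ndarray,
                mesh_h: MeshState, mesh_ref: MeshState,
                coarse_idx_h: np.ndarray, coarse_idx_ref: np.ndarray,
                boundary_idx_h: int, boundary_idx_ref: int) -> ErrorNorms:
    """All four error norms between a coarse and a reference solution.

    coarse_idx_* select the material nodes that started on the 41-node grid;
    boundary_idx_* the material node that started on the wound edge.  The L1
    and L2 norms interpolate the coarse solution (piecewise linear on its own
    moved mesh) onto the reference mesh and integrate there by the composite
    trapezoid rule.
    """
    e41 = error_norm_41(z_h[coarse_idx_h], z_ref[coarse_idx_ref])
    z_on_ref = np.interp(mesh_ref.nodes, mesh_h.nodes, z_h)
    diff = z_on_ref - z_ref
    eL1 = float(np.trapezoid(np.abs(diff), mesh_ref.nodes))
    eL2 = float(math.sqrt(np.trapezoid(diff * diff, mesh_ref.nodes)))
    eb = float(abs(z_h[boundary_idx_h] - z_ref[boundary_idx_ref]))
    return ErrorNorms(e41, eL1, eL2, eb)


def fit_loglog_slope(h: np.ndarray, err: np.ndarray) -> float:
    """Ordinary least-squares slope of log(err) versus log(h)."""
    h = np.asarray(h, dtype=float)
    err = np.asarray(err, dtype=float)
    mask = err > 0
    if mask.sum() < 2:
        return float("nan")
    return float(np.polyfit(np.log(h[mask]), np.log(err[mask]), 1)[0])


# ---------------------------------------------------------------------------
# Convergence study
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceTable:
    """Per-resolution errors and fitted log-log slopes of the ladder."""

    resolutions: tuple                 # node counts, incl. the reference
    h: np.ndarray                      # spacings of the non-reference runs
    errors: dict                       # (variable, norm) -> array over h
    slopes: dict                       # (variable, norm) -> float
    rsaw_errors: np.ndarray
    rsaw_slope: float
    meta: dict = field(default_factory=dict)

    def slope_frame(self) -> pd.DataFrame:
        """Slopes, one row per variable, one column per norm plus average."""
        rows = {}
        for var in FIELD_NAMES:
            vals = [self.slopes[(var, nm)] for nm in NORM_NAMES]
            rows[var] = vals + [float(np.mean(vals))]
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(NORM_NAMES) + ["averaged"])

    def error_frame(self) -> pd.DataFrame:
        recs = []
        for i, n in enumerate(self.resolutions[:-1]):
            for var in FIELD_NAMES:
                rec = {"n": n, "h": self.h[i], "variable": var}
                for nm in NORM_NAMES:
                    rec[nm] = self.errors[(var, nm)][i]
                recs.append(rec)
            recs.append({"n": n, "h": self.h[i], "variable": "rsaw",
                         "eps_41": self.rsaw_errors[i]})
        return pd.DataFrame.from_records(recs)


def _run_wound(params: ParameterSet, eq: EquilibriumState,
               scenario: WoundScenario, n_nodes: int, t_end: float,
               lumping: bool = True) -> tuple[Trajectory, tuple]:
    mesh = MeshState.uniform(scenario.domain_length, n_nodes - 1)
    h = scenario.domain_length / (n_nodes - 1)
    fields = make_wound_profile(scenario, mesh, eq)
    markers = wound_marker_indices(scenario, mesh)
    config = SolverConfig(dt_schedule=((0.0, h * h),), boundary_mode="full",
                          lumping=lumping)
    traj = simulate(fields, mesh, config, params, eq, t_end, markers=markers)
    if traj.termination != "completed":
        raise RuntimeError(
            f"convergence run n={n_nodes} blew up: {traj.reason}")
    return traj, markers


def convergence_study(params: ParameterSet, eq: EquilibriumState,
                      scenario: WoundScenario | None = None,
                      resolutions: tuple = LADDER,
                      t_end: float = 1.0,
                      coarse_nodes: int = 41) -> ConvergenceTable:
    """Run the ladder and tabulate errors and slopes against the finest run.

    Solutions are compared at material nodes matched by initial coordinate
    (the ladder is nested, so the coarse-grid material points exist on every
    finer grid).
    """
    scenario = scenario or WoundScenario()
    resolutions = tuple(sorted(resolutions))
    for n in resolutions:
        if (n - 1) % (coarse_nodes - 1):
            raise ValueError(f"resolution {n} is not nested over {coarse_nodes}")
    runs = {n: _run_wound(params, eq, scenario, n, t_end)
            for n in resolutions}
    n_ref = resolutions[-1]
    traj_ref, markers_ref = runs[n_ref]

    def coarse_idx(n):
        stride = (n - 1) // (coarse_nodes - 1)
        return np.arange(coarse_nodes) * stride

    L = scenario.domain_length
    h_arr = np.array([L / (n - 1) for n in resolutions[:-1]])
    errors = {(var, nm): np.empty(len(h_arr))
              for var in FIELD_NAMES for nm in NORM_NAMES}
    rsaw_err = np.empty(len(h_arr))
    ref_fields, ref_mesh = traj_ref.final_fields, traj_ref.final_mesh
    rsaw_ref = traj_ref.history["rsaw"][-1]
    for i, n in enumerate(resolutions[:-1]):
        traj, markers = runs[n]
        for var in FIELD_NAMES:
            en = error_norms(
                getattr(traj.final_fields, var), getattr(ref_fields, var),
                traj.final_mesh, ref_mesh,
                coarse_idx(n), coarse_idx(n_ref),
                markers[0], markers_ref[0])
            for nm in NORM_NAMES:
                errors[(var, nm)][i] = getattr(en, nm)
        rsaw_err[i] = abs(traj.history["rsaw"][-1] - rsaw_ref)
    slopes = {key: fit_loglog_slope(h_arr, err) for key, err in errors.items()}
    return ConvergenceTable(
        resolutions=resolutions, h=h_arr, errors=errors, slopes=slopes,
        rsaw_errors=rsaw_err, rsaw_slope=fit_loglog_slope(h_arr, rsaw_err),
        meta={"t_end": t_end, "dt": "h^2",
              "norms": "eps_L1/eps_L2/eps_boundary are reconstructions: "
                       "trapezoid integrals on the reference mesh and the "
                       "wound-edge material-node difference"},
    )


# ---------------------------------------------------------------------------
# Stability validation
# ---------------------------------------------------------------------------

#: the time-step schedule of the oscillatory (low-viscosity) runs
OSCILLATORY_SCHEDULE = ((0.0, 0.01), (2.0, 1.0), (50.0, 2.0))


@dataclass
class RunSummary:
    """Outcome of one stability-validation run."""

    delta_c: float
    mu: float
    k: int
    outcome: str                 # 'converged-to-equilibrium' |
                                 # 'converged-to-new-equilibrium' | 'blow-up'
    criterion_stable: bool       # analytic verdict for these parameters
    criterion_monotonic: bool
    center_values: dict          # field -> value at the symmetry plane
    equilibrium_distance: dict   # field -> scaled end-state distance
    blowup_time: float | None
    v_sign_changes: int          # sign changes of d/dt of the max |v|
    trajectory: Trajectory

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items()
             if k != "trajectory"}
        return d


def _count_norm_direction_changes(t: np.ndarray, vnorm: np.ndarray) -> int:
    """Sign changes of the time derivative of a norm history (ignoring
    near-zero flat stretches)."""
    dv = np.diff(vnorm)
    tol = 1e-12 * max(float(vnorm.max()), 1e-300)
    signs = np.sign(dv[np.abs(dv) > tol])
    if len(signs) < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


def stability_validation_run(delta_c: float, mu: float, k: int,
                             t_end: float,
                             params: ParameterSet | None = None,
                             n_elements: int = 500,
                             dt_schedule: tuple | None = None,
                             eps_tol: float = 0.01,
                             settle_window: float = 0.05) -> RunSummary:
    """One cell of the (delta_c, mu, k) validation matrix.

    Perturbs the equilibrium on the half-domain [0, 1] and classifies the
    end state.  'Distance to equilibrium' is scaled per field by the
    equilibrium magnitude (N, rho) or the initial perturbation amplitude
    (c, M, v, eps); the run counts as converged when every distance is below
    eps_tol, and as settled on a new equilibrium when the center values move
    by less than eps_tol over the trailing settle_window fraction of the run.
    """
    from .params import default_params

    base = params or default_params()
    p = base.replace(delta_c=delta_c, mu=mu)
    eq = EquilibriumState.from_params(p)
    report = check_stability_continuous(p, eq, k_range=range(0, 11))
    if dt_schedule is None:
        dt_schedule = OSCILLATORY_SCHEDULE if not report.monotonic \
            else ((0.0, 0.5),)
    config = SolverConfig(dt_schedule=dt_schedule, boundary_mode="half")
    scn = PerturbationScenario(k=k)
    mesh = MeshState.uniform(scn.domain_length, n_elements)
    fields = make_perturbation_profile(scn, mesh, eq)
    traj = simulate(fields, mesh, config, p, eq, t_end)

    hist = traj.frame()
    center = {f: float(getattr(traj.final_fields, f)[-1]) for f in FIELD_NAMES}
    eq_vals = {"c": eq.c_bar, "N": eq.N_bar, "M": eq.M_bar,
               "rho": eq.rho_bar, "v": eq.v_bar, "eps": None}
    dist = {}
    for f in FIELD_NAMES:
        if eq_vals[f] is None:      # strain has a continuum of equilibria
            continue
        arr = getattr(traj.final_fields, f)
        dist[f] = float(np.max(np.abs(arr - eq_vals[f]))) / PERTURBATION_SCALES[f]
    vmax = np.maximum(np.abs(hist["v_min"].to_numpy()),
                      np.abs(hist["v_max"].to_numpy()))
    sign_changes = _count_norm_direction_changes(hist["t"].to_numpy(), vmax)

    if traj.termination == "blow-up":
        outcome = "blow-up"
    elif max(dist.values()) < eps_tol:
        outcome = "converged-to-equilibrium"
    else:
        # the end state may oscillate around the new attractor, so settling
        # is judged on the drift of trailing-window means (three windows):
        # a field has settled when that drift is below tolerance or shrinking
        t = hist["t"].to_numpy()
        edges = [t[-1] * (1.0 - m * settle_window) for m in (3, 2, 1, 0)]
        settled = True
        for f in ("c", "N", "M", "rho"):
            cv = hist[f"{f}_center"].to_numpy()
            means = [float(np.mean(cv[(t >= lo) & (t <= hi)]))
                     for lo, hi in zip(edges[:-1], edges[1:])]
            scale = max(abs(means[-1]), PERTURBATION_SCALES[f])
            d12 = abs(means[1] - means[0]) / scale
            d23 = abs(means[2] - means[1]) / scale
            if not (d23 < eps_tol or d23 < d12):
                settled = False
        outcome = ("converged-to-new-equilibrium" if settled
                   else "transient")
    return RunSummary(
        delta_c=delta_c, mu=mu, k=k, outcome=outcome,
        criterion_stable=report.stable,
        criterion_monotonic=report.monotonic,
        center_values=center, equilibrium_distance=dist,
        blowup_time=traj.blowup_time, v_sign_changes=sign_changes,
        trajectory=traj,
    )


def shifted_kinetic_equilibrium(params: ParameterSet,
                                guess=(4e-11, 9.7e3, 76.0, 0.135)) -> dict:
    """Spatially uniform steady state of the reaction kinetics with c > 0.

    Solves the four coupled balance equations (secretion = breakdown for c
    and rho, proliferation + differentiation = apoptosis for N and M) with
    scipy; used as an independent cross-check of the attractor the PDE
    solver settles on when the signaling criterion is mildly violated.
    """
    from scipy.optimize import fsolve

    p = params

    def residual(x):
        lc, N, M, lrho = x
        c, rho = 10.0 ** lc, 10.0 ** lrho
        st = FieldState(*(np.array([val]) for val in
                          (c, N, M, rho, 0.0, 0.0)))
        r = {key: val[0] for key, val in reaction_rates(st, p).items()}
        return [r["c"] / 1e-15, r["N"], r["M"], r["rho"] / 1e-4]

    x0 = [math.log10(guess[0]), guess[1], guess[2], math.log10(guess[3])]
    x, info, ier, msg = fsolve(residual, x0, full_output=True)
    if ier != 1:
        raise RuntimeError(f"kinetic steady-state solve failed: {msg}")
    return {"c": 10.0 ** x[0], "N": x[1], "M": x[2], "rho": 10.0 ** x[3]}


# ---------------------------------------------------------------------------
# Reversion experiment
# ---------------------------------------------------------------------------

@dataclass
class ReversionSummary:
    recovery_times: dict       # field -> days after the reset to 95% recovery
    ordering_ok: bool          # myofibroblasts, then collagen, then fibroblasts
    reset_time: float
    trajectory: Trajectory


def reversion_experiment(run: RunSummary, extra_days: float = 1400.0,
                         dt: float = 0.5,
                         recovery_fraction: float = 0.95) -> ReversionSummary:
    """Reset the signaling molecules to zero and watch the scar revert.

    Starting from the end state of a shifted-equilibrium run, c is set to 0
    everywhere (the stimulation is lifted) and the simulation continues.
    The recovery time of each constituent is the first time it closes
    ``recovery_fraction`` of its initial gap to the healthy equilibrium and
    stays there; the expected ordering is myofibroblasts first, then
    collagen, then fibroblasts.
    """
    from .params import default_params

    p = default_params().replace(delta_c=run.delta_c, mu=run.mu)
    eq = EquilibriumState.from_params(p)
    fields = run.trajectory.final_fields.copy()
    mesh = run.trajectory.final_mesh.copy()
    t0 = mesh.t
    fields.c[:] = 0.0
    config = SolverConfig(dt_schedule=((0.0, dt),), boundary_mode="half")
    traj = simulate(fields, mesh, config, p, eq, t0 + extra_days)
    hist = traj.frame()
    t = hist["t"].to_numpy() - t0
    eq_vals = {"M": eq.M_bar, "rho": eq.rho_bar, "N": eq.N_bar}
    times = {}
    for f, target in eq_vals.items():
        gap = np.abs(hist[f"{f}_center"].to_numpy() - target)
        thresh = (1.0 - recovery_fraction) * gap[0]
        below = gap <= thresh
        # first index from which the gap stays closed
        idx = None
        for i in range(len(below)):
            if below[i:].all():
                idx = i
                break
        times[f] = float(t[idx]) if idx is not None else math.inf
    ordering_ok = times["M"] < times["rho"] < times["N"]
    return ReversionSummary(recovery_times=times, ordering_ok=ordering_ok,
                            reset_time=t0, trajectory=traj)
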