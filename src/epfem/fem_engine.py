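"""Quasi-static nonlinear field solver.

At each time step the electric potential satisfies the charge-conservation
equation with the dynamic, field-dependent conductivity and the capacitive
charge source/sink term,

    div( sigma(E) grad u ) = div( j_C ),        E = -grad u,

with Dirichlet conditions on the two electrode surfaces (applied voltage on
electrode A, ground on electrode B) and zero normal current on the outer
boundary.  Linear (P1) tetrahedra give a constant field per element, matching
the element-wise constitutive state.  The nonlinear system is solved with
full Newton iteration using the analytic field derivative of the
conductivity law (one-sided at the clamp points of the linear poration
ramp), with step halving and a Picard fallback as safeguards.  The
capacitive source is explicit in time: it is evaluated from the previous
step's filtered potential, which preserves the exp(-dt/RC) spike behaviour
without a transient PDE.

Time integration uses an adaptive schedule: every pulse edge is hit exactly,
steps stay at ``dtMin`` inside a refinement window after each edge, and grow
geometrically up to ``dtMax`` elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import model_core, observables
from .mesh_geometry import ELECTRODE_A, ELECTRODE_B, Mesh
from .model_core import TissueState
from .params import TissueParameters
from .traces_io import PulseTrain, Trace

__all__ = [
    "SolverControls", "FieldSolution", "NonConvergenceError",
    "solve_potential", "schedule_time_steps", "constant_step_count",
    "run_simulation", "plate_oracle", "refinement_study",
]


class NonConvergenceError(RuntimeError):
    """Newton iteration failed to reach the tolerance."""

    def __init__(self, message: str, residual_history: list[float], time: float | None = None):
        super().__init__(message)
        self.residual_history = residual_history
        self.time = time


@dataclass
class SolverControls:
    """Numerical controls of the Newton/time-stepping scheme."""

    newtonTol: float = 1e-9           # relative residual tolerance
    newtonMaxIter: int = 25
    dtMin: float = 2e-6               # s
    dtMax: float = 0.99               # s
    edgeRefinementWindow: float = 10e-6   # s of dtMin steps after each edge
    growthFactor: float = 2.0

    def __post_init__(self) -> None:
        if self.newtonTol <= 0:
            raise ValueError("newtonTol must be positive")
        if self.growthFactor <= 1:
            raise ValueError("growthFactor must exceed 1")
        if not (self.dtMax >= self.dtMin > 0):
            raise ValueError("require dtMax >= dtMin > 0")

    @classmethod
    def from_params(cls, params: TissueParameters, **overrides) -> "SolverControls":
        kw = dict(dtMin=params.dtMin, dtMax=params.dtMax)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class FieldSolution:
    """Converged potential and the tissue state advanced to ``time``."""

    u: np.ndarray                  # nodal potential, V
    EmagPerElement: np.ndarray     # V/m
    state: TissueState
    time: float
    newtonIterations: int
    appliedVoltage: float
    residualHistory: list[float] = field(default_factory=list)
    reaction: np.ndarray | None = None   # consistent nodal flux K u - f, A


# ---------------------------------------------------------------------------
# geometric pre-assembly (cached per mesh)


def _fem_cache(mesh: Mesh) -> dict:
    cache = getattr(mesh, "_fem_cache_data", None)
    if cache is not None:
        return cache
    nodes, tets = mesh.nodes, mesh.tets
    d = nodes[tets[:, 1:]] - nodes[tets[:, 0]][:, None, :]   # (M, 3, 3) edge rows
    dinv = np.linalg.inv(d)                                  # (M, 3, 3)
    g123 = np.transpose(dinv, (0, 2, 1))                     # grad lambda_1..3 as rows
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)               # (M, 4, 3)
    vol = mesh.element_volumes
    geo = np.einsum("mik,mjk->mij", grads, grads) * vol[:, None, None]  # (M,4,4)
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    cache = {"grads": grads, "geo": geo, "vol": vol, "rows": rows, "cols": cols}
    mesh._fem_cache_data = cache
    return cache


def _element_grad(mesh: Mesh, u: np.ndarray) -> np.ndarray:
    """Constant gradient of the P1 potential per element, (M, 3)."""
    c = _fem_cache(mesh)
    return np.einsum("mij,mi->mj", c["grads"], u[mesh.tets])


def _residual(mesh: Mesh, u: np.ndarray, sigma: np.ndarray,
              f_elem: np.ndarray | None) -> np.ndarray:
    """Nodal residual K(sigma) u - f, assembled element-wise."""
    c = _fem_cache(mesh)
    w = _element_grad(mesh, u)
    r_e = np.einsum("mij,mj->mi", c["grads"], w) * (c["vol"] * sigma)[:, None]
    if f_elem is not None:
        r_e = r_e - np.einsum("mij,mj->mi", c["grads"], f_elem) * c["vol"][:, None]
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.tets.reshape(-1), r_e.reshape(-1))
    return out


def _jacobian(mesh: Mesh, u: np.ndarray, sigma: np.ndarray,
              dsigma: np.ndarray | None) -> sp.csr_matrix:
    c = _fem_cache(mesh)
    data = sigma[:, None, None] * c["geo"]
    if dsigma is not None and np.any(dsigma):
        w = _element_grad(mesh, u)
        wmag = np.linalg.norm(w, axis=1)
        cw = np.einsum("mij,mj->mi", c["grads"], w)          # (M, 4)
        coef = np.where(wmag > 0, dsigma / np.where(wmag, wmag, 1.0), 0.0) * c["vol"]
        data = data + coef[:, None, None] * cw[:, :, None] * cw[:, None, :]
    K = sp.coo_matrix((data.reshape(-1), (c["rows"], c["cols"])),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsr()


# ---------------------------------------------------------------------------
# single-step solve


def solve_potential(
    mesh: Mesh,
    state: TissueState,
    appliedVoltage: float,
    dt: float,
    controls: SolverControls,
    params: TissueParameters,
    *,
    pulse_on: bool | None = None,
    u_init: np.ndarray | None = None,
    jcap_source: np.ndarray | None = None,
    freeze_sigma: bool = False,
    time: float | None = None,
) -> FieldSolution:
    """Solve one quasi-static step and advance the tissue state.

    Electrode A is held at ``appliedVoltage``, electrode B at 0 V; the outer
    surface carries zero normal current (natural boundary condition).  The
    conductivity is re-evaluated from the trial field inside every Newton
    iteration; after convergence the subsidiary variables are committed from
    the converged field without an inner loop.
    """
    if not np.isfinite(appliedVoltage):
        raise ValueError("appliedVoltage must be finite")
    t_new = state.t + dt if time is None else time
    if pulse_on is None:
        pulse_on = abs(appliedVoltage) > 0.0

    nodes_a = mesh.surface_nodes(ELECTRODE_A)
    nodes_b = mesh.surface_nodes(ELECTRODE_B)
    if nodes_a.size == 0 and nodes_b.size == 0:
        raise NonConvergenceError("no Dirichlet nodes: system is singular", [], t_new)
    fixed = np.zeros(mesh.n_nodes, dtype=bool)
    fixed[nodes_a] = True
    fixed[nodes_b] = True
    free = ~fixed

    u = np.zeros(mesh.n_nodes) if u_init is None else u_init.astype(float).copy()
    u[nodes_a] = appliedVoltage
    u[nodes_b] = 0.0

    def sigma_of(u_vec):
        if freeze_sigma:
            return state.sigma, None
        Emag = np.linalg.norm(_element_grad(mesh, u_vec), axis=1)
        return model_core.conductivity_and_slope(
            state.p, state.dP, state.dT, Emag, dt, params)

    # load scale: boundary-lift residual at the initial conductivity
    u_lift = np.zeros(mesh.n_nodes)
    u_lift[nodes_a] = appliedVoltage
    sig0, _ = sigma_of(u_lift)
    scale = np.linalg.norm(_residual(mesh, u_lift, sig0, jcap_source)[free])

    history: list[float] = []
    n_solves = 0
    if scale <= 0.0:
        u[free] = 0.0
        sigma, _ = sigma_of(u)
    else:
        sigma, dsigma = sigma_of(u)
        res = _residual(mesh, u, sigma, jcap_source)
        rnorm = np.linalg.norm(res[free])
        history.append(rnorm)
        while rnorm > controls.newtonTol * scale:
            if n_solves >= controls.newtonMaxIter:
                raise NonConvergenceError(
                    f"Newton did not converge in {controls.newtonMaxIter} iterations "
                    f"(relative residual {rnorm / scale:.3e})", history, t_new)
            J = _jacobian(mesh, u, sigma, dsigma)
            du = np.zeros(mesh.n_nodes)
            try:
                du[free] = spla.spsolve(J[free][:, free].tocsc(), -res[free])
            except Exception:
                # Picard fallback: drop the field-derivative rank-one terms
                J = _jacobian(mesh, u, sigma, None)
                du[free] = spla.spsolve(J[free][:, free].tocsc(), -res[free])
            n_solves += 1
            step = 1.0
            for _ in range(5):
                u_try = u + step * du
                sigma_try, dsigma_try = sigma_of(u_try)
                res_try = _residual(mesh, u_try, sigma_try, jcap_source)
                rnorm_try = np.linalg.norm(res_try[free])
                if rnorm_try < rnorm or rnorm_try <= controls.newtonTol * scale:
                    break
                step *= 0.5
            u, sigma, dsigma, res, rnorm = u_try, sigma_try, dsigma_try, res_try, rnorm_try
            history.append(rnorm)

    w = _element_grad(mesh, u)
    Evec = -w
    u_local = u[mesh.tets].mean(axis=1)
    if freeze_sigma:
        new_state = state.copy()
        new_state.Emag = np.linalg.norm(Evec, axis=1)
        new_state.jCond = sigma[:, None] * Evec
        Edir = np.where(new_state.Emag[:, None] > 0,
                        Evec / np.where(new_state.Emag, new_state.Emag, 1.0)[:, None], 0.0)
        jCap, capMem = model_core.capacitive_current_density(
            u_local, state.capMemory, dt, Edir, params)
        new_state.jCap = np.atleast_2d(jCap)
        new_state.capMemory = np.asarray(capMem)
        new_state.t = t_new
    else:
        new_state = model_core.advance_state(
            state, Evec, u_local, dt, pulse_on, params, t_new)

    reaction = _residual(mesh, u, new_state.sigma if not freeze_sigma else sigma,
                         jcap_source)
    return FieldSolution(
        u=u, EmagPerElement=new_state.Emag, state=new_state, time=t_new,
        newtonIterations=n_solves, appliedVoltage=float(appliedVoltage),
        residualHistory=history, reaction=reaction,
    )


# ---------------------------------------------------------------------------
# time stepping


def schedule_time_steps(pulseTrain: PulseTrain, controls: SolverControls,
                        until: float | None = None) -> np.ndarray:
    """Adaptive step schedule for a pulse train.

    Every pulse corner is hit exactly; steps stay at ``dtMin`` inside the
    refinement window after each corner and grow geometrically (capped at
    ``dtMax`` and at the next corner) elsewhere.
    """
    edges = pulseTrain.edge_times()
    if np.any(np.diff(edges) <= 0):
        raise ValueError("pulse edges overlap")
    t_end = pulseTrain.end_time if until is None else float(until)
    eps = controls.dtMin * 1e-6
    times = [pulseTrain.startTime]
    t = times[0]
    last_edge = t
    dt_base = controls.dtMin
    while t < t_end - eps:
        if t - last_edge < controls.edgeRefinementWindow - eps:
            dt_base = controls.dtMin
        else:
            dt_base = min(dt_base * controls.growthFactor, controls.dtMax)
        future = edges[edges > t + eps]
        nxt = min(future[0], t_end) if future.size else t_end
        dt = dt_base
        rem = nxt - t
        if rem <= dt * 1.5 + eps:
            dt = rem
        t = t + dt
        times.append(t)
        if np.any(np.abs(edges - t) < eps):
            last_edge = t
            dt_base = controls.dtMin
    return np.array(times)


def constant_step_count(pulseTrain: PulseTrain, dt: float | None = None,
                        controls: SolverControls | None = None) -> int:
    """Steps a constant-step integration of the full train would need."""
    if dt is None:
        dt = (controls or SolverControls()).dtMin
    return int(np.ceil(pulseTrain.span / dt))


# ---------------------------------------------------------------------------
# full runs


def _drive_of(drive) -> tuple[np.ndarray | None, callable, float]:
    if isinstance(drive, PulseTrain):
        return None, drive.voltage_at, abs(drive.peakVoltage)
    if isinstance(drive, Trace):
        if drive.kind != "voltage":
            raise ValueError("drive trace must be a voltage trace")
        peak = float(np.max(np.abs(drive.values))) if len(drive) else 0.0
        return drive.times, drive.interp, peak
    raise TypeError(f"unsupported drive type {type(drive).__name__}")


def run_simulation(
    mesh: Mesh,
    drive: PulseTrain | Trace,
    params: TissueParameters,
    controls: SolverControls | None = None,
    *,
    freeze_sigma: bool = False,
    snapshot_every: int = 0,
    until: float | None = None,
) -> "observables.SimulationResult":
    """Simulate a full drive program on a mesh.

    A :class:`PulseTrain` drive is integrated on the adaptive schedule (plus
    one refinement window past the last edge); a voltage :class:`Trace` is
    integrated on its own sample times.  Per step the converged electrode
    current is recorded; the run is deterministic for identical inputs.
    """
    controls = controls or SolverControls.from_params(params)
    trace_times, voltage_at, peak = _drive_of(drive)
    if trace_times is None:
        stop = until if until is not None else drive.end_time + controls.edgeRefinementWindow
        times = schedule_time_steps(drive, controls, until=stop)
    else:
        times = trace_times if until is None else trace_times[trace_times <= until]
        if times.size < 2:
            raise ValueError("drive trace does not cover the simulated interval")
    on_threshold = 1e-9 + 1e-6 * peak

    state = TissueState.virgin(mesh.n_elements, params, t=float(times[0]))
    u = np.zeros(mesh.n_nodes)
    n = len(times)
    current = np.zeros(n)
    volts = np.zeros(n)
    iters = np.zeros(n, dtype=int)
    volts[0] = float(voltage_at(times[0]))
    snapshots = []
    residual_histories: list[list[float]] = []

    for k in range(1, n):
        dt = float(times[k] - times[k - 1])
        U = float(voltage_at(times[k]))
        u_local_prev = u[mesh.tets].mean(axis=1)
        jcap_pred, _ = model_core.capacitive_current_density(
            u_local_prev, state.capMemory, dt, _unit_rows(-_element_grad(mesh, u)),
            params)
        jcap_pred = np.atleast_2d(jcap_pred)
        try:
            sol = solve_potential(
                mesh, state, U, dt, controls, params,
                pulse_on=abs(U) > on_threshold, u_init=u,
                jcap_source=jcap_pred, freeze_sigma=freeze_sigma,
                time=float(times[k]))
        except NonConvergenceError as exc:
            raise NonConvergenceError(
                f"step at t={times[k]:.6g}s failed: {exc}",
                exc.residual_history, float(times[k])) from exc
        u = sol.u
        state = sol.state
        volts[k] = U
        iters[k] = sol.newtonIterations
        residual_histories.append(sol.residualHistory)
        current[k] = observables.electrode_current(sol, mesh, ELECTRODE_A)
        if snapshot_every and (k % snapshot_every == 0 or k == n - 1):
            snapshots.append(observables.Snapshot(time=float(times[k]),
                                                  state=state.copy(), u=u.copy()))

    return observables.SimulationResult(
        times=times.copy(), simulatedCurrent=current, appliedVoltage=volts,
        perStepIterations=iters, snapshots=snapshots or None,
        residualHistories=residual_histories, finalState=state, mesh=mesh,
    )


def _unit_rows(v: np.ndarray) -> np.ndarray:
    mag = np.linalg.norm(v, axis=1)
    return np.where(mag[:, None] > 0, v / np.where(mag, mag, 1.0)[:, None], 0.0)


def refinement_study(
    edge_lengths: list[float],
    params: TissueParameters,
    appliedVoltage: float = 500.0,
    controls: SolverControls | None = None,
    **geometry_kwargs,
) -> list[dict]:
    """Baseline-current mesh-convergence harness for the needle geometry.

    For each target edge length, builds the two-needle mesh, solves one
    frozen-conductivity (virgin tissue) step and records the element count,
    the surface-sampled current I_S and the consistent (reaction) flux.
    """
    from .mesh_geometry import build_two_needle_geometry

    controls = controls or SolverControls.from_params(params)
    rows = []
    for h in edge_lengths:
        mesh = build_two_needle_geometry(targetEdgeLength=h, **geometry_kwargs)
        state = TissueState.virgin(mesh.n_elements, params)
        sol = solve_potential(mesh, state, appliedVoltage, controls.dtMin,
                              controls, params, freeze_sigma=True)
        rows.append({
            "edge_length": float(h),
            "n_elements": mesh.n_elements,
            "I_S": observables.electrode_current(sol, mesh, ELECTRODE_A),
            "I_reaction": observables.signed_electrode_current(sol, mesh, ELECTRODE_A),
        })
    return rows


def plate_oracle(
    voltage: float | PulseTrain,
    gap: float,
    area: float,
    params: TissueParameters,
    duration: float | None = None,
    controls: SolverControls | None = None,
) -> "observables.SimulationResult":
    """Analytic 1-D two-plate configuration with the identical state updates.

    The field is uniform, E = U/gap, so no FEM solve is needed; the same
    constitutive code advances a single-element state.  Serves as the
    independent oracle for FEM equivalence checks: at t = 0+ the current is
    sigma0*E*area, and with damage terms disabled a long pulse saturates at
    sigmaMax*E*area.
    """
    if gap <= 0 or area <= 0:
        raise ValueError("gap and area must be positive")
    controls = controls or SolverControls.from_params(params)
    if isinstance(voltage, PulseTrain):
        train = voltage
        stop = duration if duration is not None else train.end_time + controls.edgeRefinementWindow
        times = schedule_time_steps(train, controls, until=stop)
        voltage_at = train.voltage_at
        peak = abs(train.peakVoltage)
    else:
        if duration is None or duration <= 0:
            raise ValueError("constant-voltage oracle needs a positive duration")
        train = PulseTrain(peakVoltage=float(voltage), pulseDuration=duration,
                           repetitionFrequency=0.5 / duration, pulseCount=1,
                           riseTime=min(controls.dtMin, duration / 4),
                           fallTime=min(controls.dtMin, duration / 4))
        times = schedule_time_steps(train, controls,
                                    until=train.startTime + train.riseTime + duration)
        voltage_at = train.voltage_at
        peak = abs(float(voltage))

    state = TissueState.virgin(1, params, t=float(times[0]))
    n = len(times)
    current = np.zeros(n)
    volts = np.zeros(n)
    on_threshold = 1e-9 + 1e-6 * peak
    zhat = np.array([[0.0, 0.0, 1.0]])
    for k in range(1, n):
        dt = float(times[k] - times[k - 1])
        U = float(voltage_at(times[k]))
        Evec = zhat * (U / gap)
        state = model_core.advance_state(
            state, Evec, np.array([U / 2.0]), dt, abs(U) > on_threshold,
            params, float(times[k]))
        j_tot = state.jCond + state.jCap
        current[k] = float(np.linalg.norm(j_tot[0]) * area)
        volts[k] = U
    return observables.SimulationResult(
        times=times.copy(), simulatedCurrent=current, appliedVoltage=volts,
        perStepIterations=np.zeros(n, dtype=int), snapshots=None,
        residualHistories=[], finalState=state, mesh=None,
    )
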