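"""Time integration of the constrained lumped network.

The inelastic constraints are holonomic distance constraints; differentiating
each twice gives the acceleration-level system ``A(q̇,q,t) q̈ = b(q̇,q,t)``.
Node accelerations then follow in closed form from the Udwadia-Kalaba
equation

    q̈ = M⁻¹Q + M^(-1/2) (A M^(-1/2))⁺ (b − A M⁻¹ Q)

with ⁺ the Moore-Penrose pseudo-inverse, which tolerates redundant
constraint rows.  Because the equation only enforces constraints at the
acceleration level, Baumgarte stabilization terms are folded into ``b`` to
keep position-level drift bounded.

Two solver families are available: explicit adaptive Runge-Kutta (fast on
non-stiff problems) and an implicit multistep method that remains efficient
when tissue stiffness makes the equations numerically stiff; the ``auto``
policy picks one from the estimated stiffness ratio.  Lift-off and recontact
of the unilateral contact units are located by the integrator's root finder
on a continuous contact margin and logged as events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import SystemModel, contact_margin

__all__ = [
    "DynamicsState",
    "Trajectory",
    "SteadyStateResult",
    "ConstraintInconsistencyError",
    "SteadyStateError",
    "assemble_constraints",
    "uk_acceleration",
    "integrate",
    "steady_state",
    "estimate_stiffness_ratio",
]

# defaults (per-run overridable)
BAUMGARTE_ALPHA = 20.0  # 1/s
BAUMGARTE_BETA = 20.0  # 1/s
RTOL = 1e-6
ATOL = 1e-9
V_TOL = 1e-5  # m/s
F_TOL = 1e-4  # N
STIFFNESS_SWITCH = 1e6  # s^-2


class ConstraintInconsistencyError(RuntimeError):
    """b is not in the range of A beyond tolerance (no consistent q̈)."""

    def __init__(self, residual: float):
        self.residual = residual
        super().__init__(
            f"inconsistent constraints: residual ||A q̈ - b|| = {residual:.3e}"
        )


class SteadyStateError(RuntimeError):
    """The system failed to settle within the allotted time."""

    def __init__(self, history: list[dict]):
        self.history = history
        last = history[-1] if history else {}
        super().__init__(
            "no steady state reached within t_max; last residuals: "
            f"{last}"
        )


@dataclass
class DynamicsState:
    """Stacked node coordinates and velocities at time t."""

    q: np.ndarray
    qdot: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != self.qdot.shape:
            raise ValueError("q and qdot must have equal length")


@dataclass
class Trajectory:
    """Sampled solution of one integration run."""

    times: np.ndarray
    states: np.ndarray  # (n_t, 2*ndof): q then qdot
    unit_normal_forces: np.ndarray  # (n_t, n_units)
    unit_tangential_forces: np.ndarray
    unit_compressions: np.ndarray
    link_tensions: np.ndarray  # (n_t, n_links)
    constraint_forces: np.ndarray  # (n_t, n_constraints) Lagrange multipliers
    events: list[dict] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_dof(self) -> int:
        return self.states.shape[1] // 2

    def q(self, i: int = -1) -> np.ndarray:
        return self.states[i, : self.n_dof]

    def qdot(self, i: int = -1) -> np.ndarray:
        return self.states[i, self.n_dof :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: time, entity_id, quantity, value."""
        rows = []
        for j in range(self.unit_normal_forces.shape[1]):
            for i, t in enumerate(self.times):
                rows.append((t, f"unit_{j}", "normal_force_N", self.unit_normal_forces[i, j]))
                rows.append(
                    (t, f"unit_{j}", "tangential_force_N", self.unit_tangential_forces[i, j])
                )
        for j in range(self.link_tensions.shape[1]):
            for i, t in enumerate(self.times):
                rows.append((t, f"link_{j}", "tension_N", self.link_tensions[i, j]))
        return pd.DataFrame(rows, columns=["time_s", "entity_id", "quantity", "value"])


@dataclass
class SteadyStateResult:
    """Settled configuration and the interface forces at equilibrium."""

    state: DynamicsState
    unit_states: list[dict]
    link_tensions: list[dict]
    residual_speed: float
    residual_force: float
    diagnostics: dict = field(default_factory=dict)


def assemble_constraints(
    system: SystemModel,
    q: np.ndarray,
    v: np.ndarray,
    t: float = 0.0,
    alpha: float = 0.0,
    beta: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Acceleration-level constraint system (A, b).

    Each distance constraint ``‖p_a − p_b‖² = d²`` contributes the row
    ``2(p_a − p_b)ᵀ`` on node a's columns (negated on node b's) with
    ``b = −2‖v_a − v_b‖²``; constraints to a moving ground additionally
    carry the ground-point acceleration in ``b``.  Nonzero ``alpha``/``beta``
    add Baumgarte stabilization ``−2α Ċ − β² C`` to each entry of b.
    """
    n_c = len(system.inelastic_constraints) + len(system.ground_constraints)
    ndof = system.n_dof
    A = np.zeros((n_c, ndof))
    b = np.zeros(n_c)
    row = 0
    for c in system.inelastic_constraints:
        ia, ib = system.node_index(c.node_a), system.node_index(c.node_b)
        r = q[2 * ia : 2 * ia + 2] - q[2 * ib : 2 * ib + 2]
        dv = v[2 * ia : 2 * ia + 2] - v[2 * ib : 2 * ib + 2]
        A[row, 2 * ia : 2 * ia + 2] = 2 * r
        A[row, 2 * ib : 2 * ib + 2] = -2 * r
        C = float(r @ r) - c.target_distance**2
        Cdot = 2 * float(r @ dv)
        b[row] = -2 * float(dv @ dv) - 2 * alpha * Cdot - beta**2 * C
        row += 1
    for c in system.ground_constraints:
        ia = system.node_index(c.node)
        frame = system.frames[c.frame]
        g = frame.point(c.anchor_local, t)
        gv = frame.point_velocity(c.anchor_local, t)
        ga = frame.point_acceleration(c.anchor_local, t)
        r = q[2 * ia : 2 * ia + 2] - g
        dv = v[2 * ia : 2 * ia + 2] - gv
        A[row, 2 * ia : 2 * ia + 2] = 2 * r
        C = float(r @ r) - c.target_distance**2
        Cdot = 2 * float(r @ dv)
        b[row] = (
            -2 * float(dv @ dv)
            + 2 * float(r @ ga)
            - 2 * alpha * Cdot
            - beta**2 * C
        )
        row += 1
    return A, b


def uk_acceleration(
    masses: np.ndarray,
    Q: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    check_tol: float = 1e-6,
    return_multipliers: bool = False,
):
    """Constrained accelerations by the Udwadia-Kalaba closed form.

    ``masses`` is the diagonal of the (positive definite) inertia matrix.
    Redundant constraint rows are harmless thanks to the pseudo-inverse;
    genuinely inconsistent systems (b outside the range of A) raise
    :class:`ConstraintInconsistencyError` with the residual.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("all masses must be > 0")
    qdd_free = Q / masses
    if A.size == 0:
        if return_multipliers:
            return qdd_free, np.zeros(A.shape[0])
        return qdd_free
    m_inv_half = 1.0 / np.sqrt(masses)
    B = A * m_inv_half[np.newaxis, :]
    B_pinv = np.linalg.pinv(B)
    err = b - A @ qdd_free
    qdd = qdd_free + m_inv_half * (B_pinv @ err)
    residual = np.linalg.norm(A @ qdd - b)
    scale = max(1.0, np.linalg.norm(b), np.linalg.norm(A @ qdd))
    if residual > check_tol * scale:
        raise ConstraintInconsistencyError(residual)
    if return_multipliers:
        # constraint force Qc = M^(1/2) B⁺ err = Aᵀ λ (least-squares λ)
        Qc = np.sqrt(masses) * (B_pinv @ err)
        lam, *_ = np.linalg.lstsq(A.T, Qc, rcond=None)
        return qdd, lam
    return qdd


def estimate_stiffness_ratio(system: SystemModel, q=None, t: float = 0.0) -> float:
    """Crude upper bound on max(k_tangent/m) over units and links (s⁻²),
    used by the ``auto`` solver policy."""
    rates = [0.0]
    for unit in system.phrii_units:
        if unit._normal_law is None:
            unit.build_series_laws()
        m = system.nodes[system.node_index(unit.node)].mass
        k = max(np.max(unit._normal_law.slopes), np.max(unit._tangential_law.slopes))
        rates.append(k / m)
    for link in system.elastic_links:
        m = system.nodes[system.node_index(link.node_a)].mass
        k = np.max(link.stiffness_curve.slopes) / link.rest_length
        rates.append(k / m)
    return float(max(rates))


def _choose_method(system: SystemModel, policy: str, threshold: float) -> str:
    if policy == "explicit":
        return "RK45"
    if policy == "implicit":
        return "BDF"
    if policy == "auto":
        return "BDF" if estimate_stiffness_ratio(system) > threshold else "RK45"
    raise ValueError(f"unknown solver policy {policy!r}")


def integrate(
    system: SystemModel,
    load: Optional[Callable] = None,
    t_span: tuple[float, float] = (0.0, 1.0),
    policy: str = "auto",
    rtol: float = RTOL,
    atol: float = ATOL,
    alpha: float = BAUMGARTE_ALPHA,
    beta: float = BAUMGARTE_BETA,
    stiffness_threshold: float = STIFFNESS_SWITCH,
    initial_state: Optional[DynamicsState] = None,
    t_eval: Optional[np.ndarray] = None,
    track_events: bool = True,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the constrained system over ``t_span``.

    ``load`` maps ``(t, q, v)`` to a generalized applied-force vector.
    Samples are taken at the solver's accepted steps (or ``t_eval``); the
    per-sample interface forces, link tensions and constraint reactions are
    recomputed from the sampled states.  Raises a diagnostic error if the
    explicit solver collapses its step size (suggesting the implicit policy).
    """
    if any(u._normal_law is None for u in system.phrii_units):
        system.initialize(t_span[0])
    method = _choose_method(system, policy, stiffness_threshold)

    if initial_state is None:
        q0, v0 = system.state_vectors()
    else:
        q0, v0 = initial_state.q, initial_state.qdot
    y0 = np.concatenate([q0, v0])
    ndof = system.n_dof
    masses = system.masses()

    def rhs(t, y):
        q, v = y[:ndof], y[ndof:]
        Q = system.generalized_forces(t, q, v, load)
        A, b = assemble_constraints(system, q, v, t, alpha, beta)
        qdd = uk_acceleration(masses, Q, A, b)
        return np.concatenate([v, qdd])

    events = []
    if track_events:
        for j, unit in enumerate(system.phrii_units):
            if unit.is_null:
                continue

            def make_event(u):
                def ev(t, y):
                    i = system.node_index(u.node)
                    return contact_margin(
                        u, y[2 * i : 2 * i + 2], y[ndof + 2 * i : ndof + 2 * i + 2],
                        system.frames[u.frame], t,
                    )

                ev.terminal = False
                ev.direction = 0
                return ev

            events.append((j, make_event(unit)))

    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=[e for _, e in events] or None,
        max_step=max_step,
        dense_output=bool(events),
    )
    if not sol.success:
        hint = " (try the implicit policy)" if method == "RK45" else ""
        raise RuntimeError(f"integration failed: {sol.message}{hint}")

    times = sol.t
    n_units = len(system.phrii_units)
    n_links = len(system.elastic_links)
    n_con = len(system.inelastic_constraints) + len(system.ground_constraints)
    unit_fn = np.zeros((times.size, n_units))
    unit_ft = np.zeros((times.size, n_units))
    unit_c = np.zeros((times.size, n_units))
    link_t = np.zeros((times.size, n_links))
    con_f = np.zeros((times.size, n_con))
    for i, t in enumerate(times):
        y = sol.y[:, i]
        q, v = y[:ndof], y[ndof:]
        Q, ustates, ltens = system.generalized_forces(t, q, v, load, collect=True)
        for j, s in enumerate(ustates):
            unit_fn[i, j] = s["normal_force"]
            unit_ft[i, j] = s["tangential_force"]
            unit_c[i, j] = s["compression"]
        for j, s in enumerate(ltens):
            link_t[i, j] = s["tension"]
        if n_con:
            A, b = assemble_constraints(system, q, v, t, alpha, beta)
            _, lam = uk_acceleration(masses, Q, A, b, return_multipliers=True)
            con_f[i] = lam

    event_log = []
    if track_events and sol.t_events is not None:
        for (j, _), t_ev in zip(events, sol.t_events):
            for te in t_ev:
                # classify by the margin slope just after the crossing
                eps = max(1e-9, 1e-9 * abs(te))
                y_after = sol.sol(min(te + eps, t_span[1]))
                i_node = system.node_index(system.phrii_units[j].node)
                m_after = contact_margin(
                    system.phrii_units[j],
                    y_after[2 * i_node : 2 * i_node + 2],
                    y_after[ndof + 2 * i_node : ndof + 2 * i_node + 2],
                    system.frames[system.phrii_units[j].frame],
                    min(te + eps, t_span[1]),
                )
                event_log.append(
                    {
                        "time": float(te),
                        "unit": j,
                        "label": system.phrii_units[j].label,
                        "type": "recontact" if m_after > 0 else "liftoff",
                    }
                )
    event_log.sort(key=lambda e: e["time"])

    return Trajectory(
        times=times,
        states=sol.y.T.copy(),
        unit_normal_forces=unit_fn,
        unit_tangential_forces=unit_ft,
        unit_compressions=unit_c,
        link_tensions=link_t,
        constraint_forces=con_f,
        events=event_log,
        diagnostics={
            "method": method,
            "policy": policy,
            "accepted_steps": int(times.size - 1),
            "nfev": int(sol.nfev),
            "njev": int(getattr(sol, "njev", 0) or 0),
            "stiffness_ratio": estimate_stiffness_ratio(system),
        },
    )


def steady_state(
    system: SystemModel,
    load: Optional[Callable] = None,
    v_tol: float = V_TOL,
    f_tol: float = F_TOL,
    t_max: float = 3.0,
    chunk: float = 0.15,
    t_start: float = 0.0,
    policy: str = "auto",
    rtol: float = RTOL,
    atol: float = ATOL,
    **kwargs,
) -> SteadyStateResult:
    """Settle the system under a (post-ramp) time-invariant load.

    Integrates in chunks until the largest nodal speed drops below ``v_tol``
    and the largest net nodal force (mass x acceleration, which includes the
    constraint reactions) drops below ``f_tol``.  Steady forces are
    mass-independent because equilibrium does not involve the inertia.
    Raises :class:`SteadyStateError` with the residual history otherwise.
    """
    if any(u._normal_law is None for u in system.phrii_units) or system.phrii_units == []:
        system.initialize(t_start)
    ndof = system.n_dof
    masses = system.masses()
    state = DynamicsState(*system.state_vectors(), t=t_start)
    history: list[dict] = []
    steps = 0
    t = t_start
    while t < t_start + t_max:
        traj = integrate(
            system,
            load,
            (t, t + chunk),
            policy=policy,
            rtol=rtol,
            atol=atol,
            initial_state=state,
            track_events=False,
            **kwargs,
        )
        steps += traj.diagnostics["accepted_steps"]
        t += chunk
        state = DynamicsState(traj.q(-1), traj.qdot(-1), t)
        Q = system.generalized_forces(t, state.q, state.qdot, load)
        A, b = assemble_constraints(system, state.q, state.qdot, t)
        qdd = uk_acceleration(masses, Q, A, b)
        res_v = float(np.max(np.abs(state.qdot))) if ndof else 0.0
        res_f = float(np.max(np.abs(masses * qdd))) if ndof else 0.0
        history.append({"t": t, "max_speed": res_v, "max_force_residual": res_f})
        if res_v < v_tol and res_f < f_tol:
            _, ustates, ltens = system.generalized_forces(
                t, state.q, state.qdot, load, collect=True
            )
            return SteadyStateResult(
                state=state,
                unit_states=ustates,
                link_tensions=ltens,
                residual_speed=res_v,
                residual_force=res_f,
                diagnostics={
                    "settle_time": t - t_start,
                    "accepted_steps": steps,
                    "method": traj.diagnostics["method"],
                },
            )
    raise SteadyStateError(history)
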