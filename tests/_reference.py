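"""Independent reference solutions used as oracles by the tests.

The Lagrange-multiplier integrator solves the constrained equations of
motion through the saddle-point (KKT) system

    [ M  Aᵀ ] [q̈]   [Q]
    [ A  0  ] [λ ] = [b]

with a direct linear solve — an entirely different solution path from the
Udwadia-Kalaba pseudo-inverse formula it is used to check.
"""

import numpy as np
from scipy.integrate import solve_ivp


def kkt_acceleration(masses, Q, A, b):
    n = len(Q)
    m = A.shape[0]
    if m == 0:
        return Q / masses
    K = np.zeros((n + m, n + m))
    K[:n, :n] = np.diag(masses)
    K[:n, n:] = A.T
    K[n:, :n] = A
    rhs = np.concatenate([Q, b])
    sol = np.linalg.solve(K, rhs)
    return sol[:n]


def integrate_kkt(system, t_span, load=None, rtol=1e-10, atol=1e-12,
                  alpha=20.0, beta=20.0):
    """Integrate a SystemModel with the KKT reference accelerations."""
    from hurosim.dynamics import assemble_constraints

    q0, v0 = system.state_vectors()
    ndof = system.n_dof
    masses = system.masses()

    def rhs(t, y):
        q, v = y[:ndof], y[ndof:]
        Q = system.generalized_forces(t, q, v, load)
        A, b = assemble_constraints(system, q, v, t, alpha, beta)
        return np.concatenate([v, kkt_acceleration(masses, Q, A, b)])

    sol = solve_ivp(rhs, t_span, np.concatenate([q0, v0]), method="RK45",
                    rtol=rtol, atol=atol)
    assert sol.success
    return sol


def pendulum_closed_form(L, g, theta0, t_end, rtol=1e-12):
    """Planar pendulum angle (from +x axis) by direct ODE integration."""
    sol = solve_ivp(
        lambda t, y: [y[1], -g / L * np.cos(y[0])],
        (0.0, t_end),
        [theta0, 0.0],
        rtol=rtol,
        atol=1e-14,
    )
    assert sol.success
    return sol.y[0, -1], sol.y[1, -1]
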