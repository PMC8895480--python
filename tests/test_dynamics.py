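import numpy as np
import pytest

from hurosim.materials import StiffnessCurve, ViscoelasticElement
from hurosim.network import (
    GroundDistanceConstraint,
    GroundFrame,
    InelasticConstraint,
    Node,
    PHRIIUnit,
    SystemModel,
    add_rigid_body,
)
from hurosim.dynamics import (
    ConstraintInconsistencyError,
    DynamicsState,
    SteadyStateError,
    assemble_constraints,
    estimate_stiffness_ratio,
    integrate,
    steady_state,
    uk_acceleration,
)

from _reference import integrate_kkt

G = 9.81


def pendulum_system(L=0.5, m=0.2, theta=0.0):
    """Point mass on a rigid rod from the origin; theta from the +x axis."""
    system = SystemModel(gravity=True)
    system.frames["world"] = GroundFrame("world")
    system.add_node(Node(0, [L * np.cos(theta), L * np.sin(theta)], mass=m))
    system.ground_constraints.append(
        GroundDistanceConstraint(0, "world", [0.0, 0.0], L)
    )
    return system


class TestAssembleConstraints:
    def test_node_to_fixed_point_row(self):
        system = pendulum_system(L=0.5)
        system.nodes[0].velocity = np.array([0.0, 0.3])
        q, v = system.state_vectors()
        A, b = assemble_constraints(system, q, v)
        # row = 2(p - g)^T, b = -2||v||^2 for a static ground
        assert np.allclose(A, [[2 * 0.5, 0.0]])
        assert b[0] == pytest.approx(-2 * 0.3**2)

    def test_no_constraints_empty(self):
        system = SystemModel()
        system.add_node(Node(0, [0.0, 0.0]))
        q, v = system.state_vectors()
        A, b = assemble_constraints(system, q, v)
        assert A.shape == (0, 2)

    def test_rigid_triangle_full_rank(self):
        system = SystemModel()
        system.add_node(Node(0, [0.0, 0.0]))
        system.add_node(Node(1, [0.02, 0.0]))
        system.add_node(Node(2, [0.01, 0.017]))
        add_rigid_body(system, [0, 1, 2])
        q, v = system.state_vectors()
        A, _ = assemble_constraints(system, q, v)
        assert A.shape == (3, 6)
        assert np.linalg.matrix_rank(A) == 3


class TestUKAcceleration:
    def test_unconstrained_free_fall(self):
        m = 0.3
        qdd = uk_acceleration(
            np.array([m, m]), np.array([0.0, -m * G]), np.zeros((0, 2)), np.zeros(0)
        )
        assert np.allclose(qdd, [0.0, -G])

    @pytest.mark.parametrize("theta_from_vertical", [0.3, 1.0, 1.5])
    def test_pendulum_tangential_acceleration(self, theta_from_vertical):
        # hanging angle measured from the downward vertical
        theta = -np.pi / 2 + theta_from_vertical
        system = pendulum_system(theta=theta)
        q, v = system.state_vectors()
        A, b = assemble_constraints(system, q, v)
        Q = system.generalized_forces(0.0, q, v)
        qdd = uk_acceleration(system.masses(), Q, A, b)
        tangent = np.array([-np.sin(theta), np.cos(theta)])
        radial = np.array([np.cos(theta), np.sin(theta)])
        assert abs(qdd @ tangent) == pytest.approx(
            G * np.sin(theta_from_vertical), rel=1e-9
        )
        assert qdd @ radial == pytest.approx(0.0, abs=1e-9)  # at rest

    def test_redundant_rows_change_nothing(self):
        system = pendulum_system(theta=0.7)
        q, v = system.state_vectors()
        A, b = assemble_constraints(system, q, v)
        Q = system.generalized_forces(0.0, q, v)
        qdd1 = uk_acceleration(system.masses(), Q, A, b)
        A2 = np.vstack([A, A])
        b2 = np.concatenate([b, b])
        qdd2 = uk_acceleration(system.masses(), Q, A2, b2)
        assert np.allclose(qdd1, qdd2, atol=1e-10)

    def test_inconsistent_constraints_raise(self):
        A = np.array([[1.0, 0.0], [1.0, 0.0]])
        b = np.array([0.0, 1.0])
        with pytest.raises(ConstraintInconsistencyError):
            uk_acceleration(np.ones(2), np.zeros(2), A, b)


class TestIntegrate:
    def test_free_mass_constant_velocity(self):
        system = SystemModel()
        system.add_node(Node(0, [0.0, 0.0], velocity=[0.1, -0.2], mass=0.01))
        traj = integrate(system, t_span=(0.0, 1.0), policy="explicit")
        assert np.allclose(traj.q(-1), [0.1, -0.2], atol=1e-8)
        assert np.allclose(traj.qdot(-1), [0.1, -0.2], atol=1e-10)

    def test_single_unit_settles_to_load_equilibrium(self):
        # constant push onto one PHRII stack: equilibrium compression must
        # invert the series elastic law at the applied force
        k, rest = 2000.0, 0.002
        curve = StiffnessCurve.linear(k * rest)
        el = ViscoelasticElement(curve, curve, 8.0, 8.0, rest, 1.0)
        system = SystemModel()
        system.frames["world"] = GroundFrame("world")
        system.add_node(Node(0, [0.0, 2 * rest], mass=0.01))
        system.phrii_units.append(PHRIIUnit(0, "world", np.zeros(2), el, el))
        F = 0.5
        result = steady_state(system, lambda t, q, v: np.array([0.0, -F]))
        st = result.unit_states[0]
        assert st["normal_force"] == pytest.approx(F, abs=2e-4)
        assert st["compression"] == pytest.approx(F / (k / 2), rel=1e-3)

    def test_pendulum_matches_kkt_reference(self):
        system = pendulum_system(theta=0.3)
        ref = integrate_kkt(system, (0.0, 1.0))
        traj = integrate(system, t_span=(0.0, 1.0), policy="explicit",
                         rtol=1e-10, atol=1e-12)
        y_ref = ref.y[:, -1]
        y_uk = traj.states[-1]
        assert np.linalg.norm(y_uk - y_ref) / np.linalg.norm(y_ref) < 1e-6

    def test_event_log_records_liftoff_and_recontact(self):
        # a mass tossed off a contact stack lifts off and recontacts
        k, rest = 3000.0, 0.002
        curve = StiffnessCurve.linear(k * rest)
        el = ViscoelasticElement(curve, curve, 0.5, 0.5, rest, 1.0)
        system = SystemModel(gravity=True)
        system.frames["world"] = GroundFrame("world")
        system.add_node(Node(0, [0.0, 2 * rest - 0.001], mass=0.02))
        system.phrii_units.append(PHRIIUnit(0, "world", np.zeros(2), el, el))
        traj = integrate(system, t_span=(0.0, 0.6), policy="explicit")
        kinds = {e["type"] for e in traj.events}
        assert "liftoff" in kinds and "recontact" in kinds
        assert np.min(traj.unit_normal_forces) >= 0.0


class TestSteadyState:
    def test_pretensioned_antagonistic_straps_stay_put(self, hand_system):
        # zero applied load: the donned state settles with strap tensions
        # near the pretension and negligible net nodal force
        import copy

        system = copy.deepcopy(hand_system)
        result = steady_state(system, None)
        assert result.residual_force < 1e-4
        for s in result.link_tensions:
            assert 0.0 < s["tension"] < 2.5 * 5.0

    def test_mass_scaling_invariance(self):
        from hurosim.hand import (
            LoadProtocol,
            build_hand_system,
            make_mcp_moment_load,
        )

        forces = {}
        for scale in (1.0, 10.0):
            system = build_hand_system(node_mass=5e-3 * scale)
            load = make_mcp_moment_load(system, lambda t: 0.2 * min(1.0, t / 0.05))
            result = steady_state(system, load)
            forces[scale] = np.array(
                [s["normal_force"] for s in result.unit_states]
            )
        f1, f10 = forces[1.0], forces[10.0]
        mask = f1 > 0.05
        assert np.all(np.abs(f10[mask] - f1[mask]) / f1[mask] < 1e-3)

    def test_non_settling_raises_with_history(self):
        system = SystemModel()
        system.add_node(Node(0, [0.0, 0.0], velocity=[0.5, 0.0], mass=0.01))
        with pytest.raises(SteadyStateError) as err:
            steady_state(system, None, t_max=0.3)
        assert len(err.value.history) > 0

    def test_stiffness_ratio_drives_auto_policy(self, hand_system):
        assert estimate_stiffness_ratio(hand_system) > 1e6  # -> implicit
        free = SystemModel()
        free.add_node(Node(0, [0.0, 0.0]))
        assert estimate_stiffness_ratio(free) == 0.0
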