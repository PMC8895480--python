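"""Lumped-parameter network of the human-robot contact interface.

The wearable device is represented as point masses (:class:`Node`) moving in
the 2D sagittal plane, linked by inelastic distance constraints (rigid
plates are ternary triples of such constraints), compliant links (attachment
straps), and :class:`PHRIIUnit` contact stacks that couple selected nodes to
the human skeleton.  The skeleton itself is not simulated: it is a reference
ground, one rigid :class:`GroundFrame` per bone, which may move kinematically
(e.g. the proximal phalanx driven through the MCP joint angle).

Each PHRII unit stacks a tissue and a padding :class:`ViscoelasticElement`
in series.  Elastic behaviour is combined in series separately from the
viscous behaviour, and the normal and tangential directions are treated as
orthogonal and independent.  Contact is unilateral: the transmitted normal
force is clamped at zero, so the stack can only push, and a unit whose
series force clamps to zero (rapid withdrawal) or whose gap opens is lifted
and transmits no tangential force either.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import yaml

from .materials import (
    StiffnessCurve,
    ViscoelasticElement,
    series_compose,
    series_damping,
)

__all__ = [
    "Node",
    "GroundFrame",
    "InelasticConstraint",
    "GroundDistanceConstraint",
    "ElasticLink",
    "PHRIIUnit",
    "SystemModel",
    "add_rigid_body",
    "phrii_force",
    "serialize_system",
    "deserialize_system",
]

SCHEMA_VERSION = 1
GRAVITY = 9.81
TANGENTIAL_FADE_N = 0.01  # N; regularisation of shear hand-off at lift-off


def _rot(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


@dataclass
class Node:
    """Point mass of the lumped network."""

    id: int
    position: np.ndarray
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    mass: float = 5.0e-3

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.mass <= 0:
            raise ValueError(f"node {self.id}: mass must be > 0")


@dataclass
class GroundFrame:
    """Rigid reference frame of one bone.

    ``angle`` and ``origin`` give the static pose; ``angle_fn`` (rad vs.
    time) optionally drives the frame kinematically, in which case frame
    point velocities/accelerations are obtained by central differences.
    """

    name: str
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    angle: float = 0.0
    angle_fn: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)

    def _angle(self, t: float) -> float:
        return self.angle_fn(t) if self.angle_fn is not None else self.angle

    def point(self, local: np.ndarray, t: float = 0.0) -> np.ndarray:
        return self.origin + _rot(self._angle(t)) @ np.asarray(local, dtype=float)

    def direction(self, local: np.ndarray, t: float = 0.0) -> np.ndarray:
        return _rot(self._angle(t)) @ np.asarray(local, dtype=float)

    def point_velocity(self, local, t: float = 0.0, dt: float = 1.0e-6) -> np.ndarray:
        if self.angle_fn is None:
            return np.zeros(2)
        return (self.point(local, t + dt) - self.point(local, t - dt)) / (2 * dt)

    def point_acceleration(self, local, t: float = 0.0, dt: float = 1.0e-6) -> np.ndarray:
        if self.angle_fn is None:
            return np.zeros(2)
        return (
            self.point(local, t + dt) - 2 * self.point(local, t) + self.point(local, t - dt)
        ) / dt**2


@dataclass
class InelasticConstraint:
    """Rigid distance constraint between two nodes (a row of A, b)."""

    node_a: int
    node_b: int
    target_distance: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("inelastic constraint requires two distinct nodes")
        if self.target_distance <= 0:
            raise ValueError("target_distance must be > 0")


@dataclass
class GroundDistanceConstraint:
    """Rigid distance constraint between a node and a ground-frame point."""

    node: int
    frame: str
    anchor_local: np.ndarray
    target_distance: float

    def __post_init__(self) -> None:
        self.anchor_local = np.asarray(self.anchor_local, dtype=float)
        if self.target_distance <= 0:
            raise ValueError("target_distance must be > 0")


@dataclass
class ElasticLink:
    """Compliant (strap-like) link, between two nodes or node-to-ground.

    The elastic law acts on engineering strain ``extension / rest_length``;
    ``pretension`` is the tension at zero extension.  With ``tension_only``
    (straps) the transmitted force is clamped at zero in compression.
    ``length_offset`` adds to the geometric extension and models quasi-static
    path-length changes such as palmar cross-section bulge under muscle
    co-contraction.
    """

    node_a: int
    node_b: Optional[int]
    stiffness_curve: StiffnessCurve
    rest_length: float
    pretension: float = 0.0
    tension_only: bool = True
    damping: float = 0.0
    length_offset: float = 0.0
    frame: Optional[str] = None
    anchor_local: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.rest_length <= 0:
            raise ValueError("rest_length must be > 0")
        if self.pretension < 0:
            raise ValueError("pretension must be >= 0")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")
        if self.node_b is None and (self.frame is None or self.anchor_local is None):
            raise ValueError("ground-anchored link needs frame and anchor_local")
        if self.anchor_local is not None:
            self.anchor_local = np.asarray(self.anchor_local, dtype=float)

    @classmethod
    def linear_strap(
        cls,
        node_a: int,
        frame: str,
        anchor_local,
        rest_length: float,
        stiffness: float,
        pretension: float = 0.0,
        damping: float = 0.0,
        label: str = "",
    ) -> "ElasticLink":
        """Tension-only ground-anchored strap with linear stiffness (N/m)."""
        curve = StiffnessCurve.linear(stiffness * rest_length)  # N per unit strain
        return cls(
            node_a,
            None,
            curve,
            rest_length,
            pretension=pretension,
            tension_only=True,
            damping=damping,
            frame=frame,
            anchor_local=anchor_local,
            label=label,
        )

    def tension(self, length: float, length_rate: float = 0.0) -> float:
        """Axial force (positive = tension) at the given current length."""
        ext = length - self.rest_length + self.length_offset
        strain = ext / self.rest_length
        if strain >= 0:
            f = self.pretension + self.stiffness_curve.force(strain)
        else:
            f = self.pretension - self.stiffness_curve.force(-strain)
        f += self.damping * length_rate
        if self.tension_only:
            f = max(0.0, f)
        return f


@dataclass
class PHRIIUnit:
    """One contact point: tissue and padding elements in series.

    The unit connects ``node`` to the anchor point on its ground frame.
    ``contact_normal_local`` points from the bone surface toward the device.
    Compression is measured along that normal against the combined rest
    thickness of the two elements; the tangential offset is measured in the
    perpendicular direction relative to the configuration at initialisation.
    """

    node: int
    frame: str
    anchor_local: np.ndarray
    tissue: ViscoelasticElement
    padding: ViscoelasticElement
    contact_normal_local: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    tangential_cap: Optional[float] = None
    label: str = ""
    # caches built by SystemModel.initialize()
    _normal_law: Optional[StiffnessCurve] = field(default=None, repr=False)
    _tangential_law: Optional[StiffnessCurve] = field(default=None, repr=False)
    _r_normal: float = field(default=0.0, repr=False)
    _r_tangential: float = field(default=0.0, repr=False)
    _tangential_ref: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        self.anchor_local = np.asarray(self.anchor_local, dtype=float)
        n = np.asarray(self.contact_normal_local, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("contact normal must be a non-zero vector")
        self.contact_normal_local = n / norm

    @property
    def rest_total(self) -> float:
        return self.tissue.rest_thickness + self.padding.rest_thickness

    def build_series_laws(self) -> None:
        self._normal_law = series_compose(
            self.tissue.normal_law(), self.padding.normal_law()
        )
        self._tangential_law = series_compose(
            self.tissue.tangential_law(), self.padding.tangential_law()
        )
        self._r_normal = series_damping(
            self.tissue.damping_normal, self.padding.damping_normal
        )
        self._r_tangential = series_damping(
            self.tissue.damping_tangential, self.padding.damping_tangential
        )

    @property
    def is_null(self) -> bool:
        """True for zero-property units (they never transmit force)."""
        law = self._normal_law
        return (
            law is not None
            and law.max_force == 0.0
            and self._tangential_law.max_force == 0.0
            and self._r_normal == 0.0
        )


def phrii_force(
    unit: PHRIIUnit,
    node_position: np.ndarray,
    node_velocity: np.ndarray,
    frame: GroundFrame,
    t: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Contact force of one PHRII unit on its node, plus contact state.

    Returns ``(force_2vec_N, state)`` where ``state`` records the normal and
    tangential force components, compression, gap and the in_contact/lifted
    flags.  The normal force is the series elastic force at the current
    compression plus the series viscous force, clamped at zero (unilateral
    contact); when it clamps, the unit is lifted and the tangential force is
    zero as well.
    """
    if unit._normal_law is None:
        raise RuntimeError("unit not initialised; call SystemModel.initialize()")
    n = frame.direction(unit.contact_normal_local, t)
    tangent = np.array([-n[1], n[0]])
    anchor = frame.point(unit.anchor_local, t)
    anchor_v = frame.point_velocity(unit.anchor_local, t)

    separation = float((node_position - anchor) @ n)
    compression = unit.rest_total - separation
    comp_rate = -float((node_velocity - anchor_v) @ n)

    if compression > 0:
        f_elastic = unit._normal_law.force(compression)
        f_normal = f_elastic + unit._r_normal * comp_rate
        f_normal = max(0.0, f_normal)
    else:
        f_normal = 0.0
    in_contact = compression > 0 and f_normal > 0.0

    if in_contact:
        u = float((node_position - anchor) @ tangent) - unit._tangential_ref
        u_rate = float((node_velocity - anchor_v) @ tangent)
        f_t = -np.sign(u) * unit._tangential_law.force(abs(u)) - unit._r_tangential * u_rate
        if unit.tangential_cap is not None:
            f_t = float(np.clip(f_t, -unit.tangential_cap, unit.tangential_cap))
        # shear cannot be transmitted without normal load: fade the
        # tangential force continuously to zero at the lift-off boundary
        # (regularisation scale TANGENTIAL_FADE_N keeps the RHS continuous)
        f_t *= -np.expm1(-f_normal / TANGENTIAL_FADE_N)
    else:
        f_t = 0.0

    force = f_normal * n + f_t * tangent
    state = {
        "normal_force": f_normal,
        "tangential_force": f_t,
        "compression": compression,
        "gap": max(0.0, -compression),
        "in_contact": in_contact,
        "lifted": not in_contact,
    }
    return force, state


def contact_margin(
    unit: PHRIIUnit,
    node_position: np.ndarray,
    node_velocity: np.ndarray,
    frame: GroundFrame,
    t: float = 0.0,
) -> float:
    """Continuous scalar whose sign tracks contact: positive while the unit
    transmits normal force.  Used by the integrator's event locator; for
    negative compression the elastic law is extended with its first slope so
    the margin crosses zero continuously at lift-off and recontact."""
    if unit._normal_law is None:
        raise RuntimeError("unit not initialised")
    n = frame.direction(unit.contact_normal_local, t)
    anchor = frame.point(unit.anchor_local, t)
    anchor_v = frame.point_velocity(unit.anchor_local, t)
    compression = unit.rest_total - float((node_position - anchor) @ n)
    comp_rate = -float((node_velocity - anchor_v) @ n)
    if compression >= 0:
        f_el = unit._normal_law.force(compression)
    else:
        f_el = unit._normal_law.slopes[0] * compression
    return f_el + unit._r_normal * comp_rate


@dataclass
class SystemModel:
    """The full lumped network: nodes, constraints, straps, PHRII units."""

    nodes: list[Node] = field(default_factory=list)
    frames: dict[str, GroundFrame] = field(default_factory=dict)
    inelastic_constraints: list[InelasticConstraint] = field(default_factory=list)
    ground_constraints: list[GroundDistanceConstraint] = field(default_factory=list)
    elastic_links: list[ElasticLink] = field(default_factory=list)
    phrii_units: list[PHRIIUnit] = field(default_factory=list)
    gravity: bool = False
    metadata: dict = field(default_factory=dict)

    # -- bookkeeping -----------------------------------------------------

    def node_index(self, node_id: int) -> int:
        for i, n in enumerate(self.nodes):
            if n.id == node_id:
                return i
        raise KeyError(f"no node with id {node_id}")

    def add_node(self, node: Node) -> None:
        if any(n.id == node.id for n in self.nodes):
            raise ValueError(f"duplicate node id {node.id}")
        self.nodes.append(node)

    def validate(self) -> list[str]:
        """Referential-integrity check; returns a list of violations."""
        problems = []
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            problems.append("node ids are not unique")
        for i, c in enumerate(self.inelastic_constraints):
            for nid in (c.node_a, c.node_b):
                if nid not in ids:
                    problems.append(
                        f"inelastic constraint {i} references missing node {nid}"
                    )
        for i, c in enumerate(self.ground_constraints):
            if c.node not in ids:
                problems.append(f"ground constraint {i} references missing node {c.node}")
            if c.frame not in self.frames:
                problems.append(f"ground constraint {i} references missing frame {c.frame}")
        for i, l in enumerate(self.elastic_links):
            if l.node_a not in ids:
                problems.append(f"elastic link {i} references missing node {l.node_a}")
            if l.node_b is not None and l.node_b not in ids:
                problems.append(f"elastic link {i} references missing node {l.node_b}")
            if l.node_b is None and l.frame not in self.frames:
                problems.append(f"elastic link {i} references missing frame {l.frame}")
        for i, u in enumerate(self.phrii_units):
            if u.node not in ids:
                problems.append(f"phrii unit {i} references missing node {u.node}")
            if u.frame not in self.frames:
                problems.append(f"phrii unit {i} references missing frame {u.frame}")
        return problems

    def initialize(self, t: float = 0.0) -> "SystemModel":
        """Build series laws and tangential references; must be called after
        assembly and before simulation."""
        problems = self.validate()
        if problems:
            raise ValueError("invalid system: " + "; ".join(problems))
        for unit in self.phrii_units:
            unit.build_series_laws()
            frame = self.frames[unit.frame]
            n = frame.direction(unit.contact_normal_local, t)
            tangent = np.array([-n[1], n[0]])
            anchor = frame.point(unit.anchor_local, t)
            p = self.nodes[self.node_index(unit.node)].position
            unit._tangential_ref = float((p - anchor) @ tangent)
        return self

    # -- state vectors ---------------------------------------------------

    @property
    def n_dof(self) -> int:
        return 2 * len(self.nodes)

    def state_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        q = np.concatenate([n.position for n in self.nodes]) if self.nodes else np.zeros(0)
        v = np.concatenate([n.velocity for n in self.nodes]) if self.nodes else np.zeros(0)
        return q, v

    def masses(self) -> np.ndarray:
        return np.repeat([n.mass for n in self.nodes], 2)

    def link_length(self, link: ElasticLink, q: np.ndarray, t: float = 0.0):
        ia = self.node_index(link.node_a)
        pa = q[2 * ia : 2 * ia + 2]
        if link.node_b is not None:
            ib = self.node_index(link.node_b)
            pb = q[2 * ib : 2 * ib + 2]
        else:
            pb = self.frames[link.frame].point(link.anchor_local, t)
        d = pa - pb
        return float(np.linalg.norm(d)), d

    # -- force assembly --------------------------------------------------

    def generalized_forces(
        self,
        t: float,
        q: np.ndarray,
        v: np.ndarray,
        load: Optional[Callable[[float, np.ndarray, np.ndarray], np.ndarray]] = None,
        collect: bool = False,
    ):
        """Applied (non-constraint) generalized force vector Q.

        With ``collect=True`` also returns per-unit contact states and
        per-link tensions for reporting.
        """
        Q = np.zeros(self.n_dof)
        if self.gravity:
            for i, n in enumerate(self.nodes):
                Q[2 * i + 1] -= n.mass * GRAVITY

        unit_states = [] if collect else None
        link_tensions = [] if collect else None

        for unit in self.phrii_units:
            i = self.node_index(unit.node)
            p = q[2 * i : 2 * i + 2]
            vel = v[2 * i : 2 * i + 2]
            force, state = phrii_force(unit, p, vel, self.frames[unit.frame], t)
            Q[2 * i : 2 * i + 2] += force
            if collect:
                state["label"] = unit.label
                unit_states.append(state)

        for link in self.elastic_links:
            length, d = self.link_length(link, q, t)
            ia = self.node_index(link.node_a)
            va = v[2 * ia : 2 * ia + 2]
            if link.node_b is not None:
                ib = self.node_index(link.node_b)
                vb = v[2 * ib : 2 * ib + 2]
            else:
                ib = None
                vb = self.frames[link.frame].point_velocity(link.anchor_local, t)
            if length > 1e-12:
                axis = d / length
                rate = float((va - vb) @ axis)
            else:
                axis = np.zeros(2)
                rate = 0.0
            f = link.tension(length, rate)
            Q[2 * ia : 2 * ia + 2] += -f * axis
            if ib is not None:
                Q[2 * ib : 2 * ib + 2] += f * axis
            if collect:
                link_tensions.append({"label": link.label, "tension": f, "length": length})

        if load is not None:
            Q += np.asarray(load(t, q, v), dtype=float).reshape(-1)

        if collect:
            return Q, unit_states, link_tensions
        return Q


def add_rigid_body(system: SystemModel, node_ids) -> SystemModel:
    """Constrain three non-collinear nodes into a rigid ternary link.

    Adds the three pairwise inelastic distance constraints at the current
    node distances.  Idempotent: existing constraints on a pair are kept.
    """
    ids = list(node_ids)
    if len(ids) != 3 or len(set(ids)) != 3:
        raise ValueError("a rigid body needs exactly three distinct node ids")
    pts = [system.nodes[system.node_index(i)].position for i in ids]
    area2 = abs(
        (pts[1][0] - pts[0][0]) * (pts[2][1] - pts[0][1])
        - (pts[2][0] - pts[0][0]) * (pts[1][1] - pts[0][1])
    )
    scale = max(np.linalg.norm(pts[1] - pts[0]), np.linalg.norm(pts[2] - pts[0]))
    if area2 < 1e-12 * scale**2:
        raise ValueError("collinear nodes cannot form a rigid ternary link")
    existing = {
        frozenset((c.node_a, c.node_b)) for c in system.inelastic_constraints
    }
    for a, b in ((ids[0], ids[1]), (ids[1], ids[2]), (ids[0], ids[2])):
        if frozenset((a, b)) in existing:
            continue
        pa = system.nodes[system.node_index(a)].position
        pb = system.nodes[system.node_index(b)].position
        system.inelastic_constraints.append(
            InelasticConstraint(a, b, float(np.linalg.norm(pa - pb)))
        )
    bodies = system.metadata.setdefault("rigid_bodies", [])
    if ids not in bodies:
        bodies.append(ids)
    return system


# -- serialization -------------------------------------------------------


def _curve_to_dict(c: StiffnessCurve) -> dict:
    return {
        "breakpoints": c.breakpoints.tolist(),
        "slopes": c.slopes.tolist(),
        "smoothing_halfwidth": float(c.smoothing_halfwidth),
    }


def _curve_from_dict(d: dict) -> StiffnessCurve:
    return StiffnessCurve(
        np.asarray(d["breakpoints"], dtype=float),
        np.asarray(d["slopes"], dtype=float),
        float(d.get("smoothing_halfwidth", 0.0)),
    )


def _element_to_dict(e: ViscoelasticElement) -> dict:
    return {
        "elastic_normal": _curve_to_dict(e.elastic_normal),
        "elastic_tangential": _curve_to_dict(e.elastic_tangential),
        "damping_normal": e.damping_normal,
        "damping_tangential": e.damping_tangential,
        "rest_thickness": e.rest_thickness,
        "force_scale": e.force_scale,
    }


def _element_from_dict(d: dict) -> ViscoelasticElement:
    return ViscoelasticElement(
        _curve_from_dict(d["elastic_normal"]),
        _curve_from_dict(d["elastic_tangential"]),
        float(d.get("damping_normal", 0.0)),
        float(d.get("damping_tangential", 0.0)),
        float(d["rest_thickness"]),
        float(d.get("force_scale", 1.0)),
    )


def serialize_system(system: SystemModel, path) -> None:
    """Write a :class:`SystemModel` to a versioned YAML file.

    Kinematic drive functions (``angle_fn``) are run-time objects and are not
    serialized; frames round-trip with their static pose.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "gravity": system.gravity,
        "nodes": [
            {
                "id": n.id,
                "position": n.position.tolist(),
                "velocity": n.velocity.tolist(),
                "mass": n.mass,
            }
            for n in system.nodes
        ],
        "frames": [
            {"name": f.name, "origin": f.origin.tolist(), "angle": f.angle}
            for f in system.frames.values()
        ],
        "inelastic_constraints": [
            {"node_a": c.node_a, "node_b": c.node_b, "target_distance": c.target_distance}
            for c in system.inelastic_constraints
        ],
        "ground_constraints": [
            {
                "node": c.node,
                "frame": c.frame,
                "anchor_local": c.anchor_local.tolist(),
                "target_distance": c.target_distance,
            }
            for c in system.ground_constraints
        ],
        "elastic_links": [
            {
                "node_a": l.node_a,
                "node_b": l.node_b,
                "stiffness_curve": _curve_to_dict(l.stiffness_curve),
                "rest_length": l.rest_length,
                "pretension": l.pretension,
                "tension_only": l.tension_only,
                "damping": l.damping,
                "length_offset": l.length_offset,
                "frame": l.frame,
                "anchor_local": None if l.anchor_local is None else l.anchor_local.tolist(),
                "label": l.label,
            }
            for l in system.elastic_links
        ],
        "phrii_units": [
            {
                "node": u.node,
                "frame": u.frame,
                "anchor_local": u.anchor_local.tolist(),
                "tissue": _element_to_dict(u.tissue),
                "padding": _element_to_dict(u.padding),
                "contact_normal_local": u.contact_normal_local.tolist(),
                "tangential_cap": u.tangential_cap,
                "label": u.label,
            }
            for u in system.phrii_units
        ],
        "metadata": _plain(system.metadata),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(doc), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def deserialize_system(path) -> SystemModel:
    """Read a YAML system file; validates the schema and all references."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported or missing schema_version (expected {SCHEMA_VERSION})"
        )
    system = SystemModel(gravity=bool(doc.get("gravity", False)))
    for nd in doc.get("nodes", []):
        system.add_node(
            Node(int(nd["id"]), np.asarray(nd["position"], dtype=float),
                 np.asarray(nd.get("velocity", [0, 0]), dtype=float), float(nd["mass"]))
        )
    for fd in doc.get("frames", []):
        system.frames[fd["name"]] = GroundFrame(
            fd["name"], np.asarray(fd.get("origin", [0, 0]), dtype=float),
            float(fd.get("angle", 0.0))
        )
    for cd in doc.get("inelastic_constraints", []):
        system.inelastic_constraints.append(
            InelasticConstraint(int(cd["node_a"]), int(cd["node_b"]),
                                float(cd["target_distance"]))
        )
    for cd in doc.get("ground_constraints", []):
        system.ground_constraints.append(
            GroundDistanceConstraint(int(cd["node"]), cd["frame"],
                                     np.asarray(cd["anchor_local"], dtype=float),
                                     float(cd["target_distance"]))
        )
    for ld in doc.get("elastic_links", []):
        system.elastic_links.append(
            ElasticLink(
                int(ld["node_a"]),
                None if ld["node_b"] is None else int(ld["node_b"]),
                _curve_from_dict(ld["stiffness_curve"]),
                float(ld["rest_length"]),
                pretension=float(ld.get("pretension", 0.0)),
                tension_only=bool(ld.get("tension_only", True)),
                damping=float(ld.get("damping", 0.0)),
                length_offset=float(ld.get("length_offset", 0.0)),
                frame=ld.get("frame"),
                anchor_local=None if ld.get("anchor_local") is None
                else np.asarray(ld["anchor_local"], dtype=float),
                label=ld.get("label", ""),
            )
        )
    for ud in doc.get("phrii_units", []):
        system.phrii_units.append(
            PHRIIUnit(
                int(ud["node"]),
                ud["frame"],
                np.asarray(ud["anchor_local"], dtype=float),
                _element_from_dict(ud["tissue"]),
                _element_from_dict(ud["padding"]),
                contact_normal_local=np.asarray(ud["contact_normal_local"], dtype=float),
                tangential_cap=ud.get("tangential_cap"),
                label=ud.get("label", ""),
            )
        )
    system.metadata = doc.get("metadata", {})
    problems = system.validate()
    if problems:
        raise ValueError("invalid system file: " + "; ".join(problems))
    return system
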