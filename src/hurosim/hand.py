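"""Hand-dorsum exoskeleton scenario: isometric MCP moment loading.

Builds the planar (sagittal) lumped model of a hand exoskeleton attached to
the dorsum: a 50 mm rigid plate over the metacarpal and a 30 mm plate over
the proximal phalanx, each modelled as a rigid ternary body (two contact
nodes and one raised apex node whose contact properties are zero), coupled
to the underlying bone frames through tissue+padding PHRII stacks and held
down by pretensioned straps.  The proximal phalanx bone is a moving
reference ground driven by the MCP joint angle.

The isometric protocol applies a ramp-and-hold moment about the MCP.  An
extension moment (positive sign here) is resolved as the finger's reaction
couple on both attachment plates: the plate edge nearest the MCP on the
phalanx unloads (and can lift off), while on the metacarpal plate the edge
nearest the joint presses harder — the redistribution the hardware shows.

Each strap is one assembly of two tension-only links (the 2D section of a
strap wrapping the hand) running from the plate edges to palmar anchors;
the palmar soft-tissue stack is composed in series into the strap law.
Muscle co-contraction is modelled quasi-statically as a fractional bulge of
the palmar cross-section, which lengthens the strap path.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .materials import (
    StiffnessCurve,
    ViscoelasticElement,
    curves_from_table,
    default_material_table,
    series_compose,
)
from .network import (
    ElasticLink,
    GroundFrame,
    Node,
    PHRIIUnit,
    SystemModel,
    add_rigid_body,
)
from .dynamics import steady_state, SteadyStateResult
from .units import MPA_TO_PA

__all__ = [
    "HandGeometry",
    "LoadProtocol",
    "build_hand_system",
    "make_mcp_moment_load",
    "run_isometric_moment_study",
    "detect_liftoff_pattern",
    "strap_stiffness_study",
]


@dataclass
class HandGeometry:
    """Geometric description of the attachment (lengths in m, angle in rad)."""

    metacarpal_plate_length: float = 0.050
    phalanx_plate_length: float = 0.030
    strap_width: float = 0.010
    tissue_thickness_dorsal: float = 0.004
    tissue_thickness_palmar: float = 0.020
    padding_thickness: float = 0.003
    mcp_angle: float = 0.0
    apex_standoff: float = 0.005
    plate_clearance: float = 0.005
    palm_depth: float = 0.027
    palm_contact_length: float = 0.060

    def __post_init__(self) -> None:
        for name in (
            "metacarpal_plate_length",
            "phalanx_plate_length",
            "strap_width",
            "tissue_thickness_dorsal",
            "tissue_thickness_palmar",
            "padding_thickness",
            "apex_standoff",
            "plate_clearance",
            "palm_depth",
            "palm_contact_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class LoadProtocol:
    """Isometric loading protocol.

    ``applied_moment`` is the held moment about the MCP in N·m (positive =
    extension), reached through a linear ramp of ``ramp_time`` seconds.
    ``strap_pretension`` is the tension set in each strap at donning.
    ``cocontraction_bulge`` is the fractional quasi-static increase of the
    palmar cross-section thickness under muscle co-contraction.
    """

    applied_moment: float = 0.0
    max_moment: float = 0.5
    ramp_time: float = 0.05
    strap_pretension: float = 5.0
    cocontraction_bulge: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.applied_moment) > self.max_moment + 1e-12:
            raise ValueError(
                f"|applied_moment| exceeds the configured maximum {self.max_moment}"
            )
        if self.strap_pretension < 0:
            raise ValueError("strap_pretension must be >= 0")
        if self.cocontraction_bulge < 0:
            raise ValueError("cocontraction_bulge must be >= 0")


def _critical_damping(law: StiffnessCurve, mass: float, zeta: float = 1.0) -> float:
    k0 = float(law.slopes[law.slopes > 0][0]) if np.any(law.slopes > 0) else 0.0
    return 2.0 * zeta * np.sqrt(k0 * mass) if k0 > 0 else 0.0


def build_hand_system(
    geometry: HandGeometry | None = None,
    materials: Optional[dict] = None,
    *,
    node_mass: float = 5.0e-3,
    strap_stiffness: float = 5000.0,
    strap_pretension: float = 5.0,
    cocontraction_bulge: float = 0.0,
    damping_zeta: float = 1.0,
    stiffness_scale: float = 1.0,
) -> SystemModel:
    """Assemble the two-plate hand-dorsum system.

    ``materials`` maps (material, direction) to strain-domain
    :class:`StiffnessCurve` (defaults to the built-in table).
    ``strap_stiffness`` is the strap's own axial stiffness in N/m before
    series composition with the palmar tissue stack. ``stiffness_scale``
    multiplies every elastic slope (used for numerical-stiffness studies).
    """
    g = geometry or HandGeometry()
    if materials is None:
        materials = curves_from_table(default_material_table())

    def scaled(curve: StiffnessCurve) -> StiffnessCurve:
        if stiffness_scale == 1.0:
            return curve
        return StiffnessCurve(
            curve.breakpoints, curve.slopes * stiffness_scale, curve.smoothing_halfwidth
        )

    tissue_n = scaled(materials[("soft_tissue", "normal")])
    tissue_t = scaled(materials[("skin", "tangential")])
    pad_n = scaled(materials[("padding", "normal")])
    pad_t = scaled(materials[("padding", "tangential")])

    system = SystemModel(gravity=False)
    system.frames["metacarpal"] = GroundFrame("metacarpal")
    system.frames["phalanx"] = GroundFrame("phalanx", angle=-g.mcp_angle)

    rest_total = g.tissue_thickness_dorsal + g.padding_thickness
    c = g.plate_clearance

    plates = {
        "mc": {
            "frame": "metacarpal",
            "anchors_x": (-(c + g.metacarpal_plate_length), -c),
            "length": g.metacarpal_plate_length,
            "node_ids": (0, 1, 2),
        },
        "ph": {
            "frame": "phalanx",
            "anchors_x": (c, c + g.phalanx_plate_length),
            "length": g.phalanx_plate_length,
            "node_ids": (3, 4, 5),
        },
    }

    unit_labels: list[str] = []
    unit_areas: list[float] = []
    strap_labels: list[str] = []
    strap_indices: list[int] = []

    for key, p in plates.items():
        frame = system.frames[p["frame"]]
        x_lo, x_hi = p["anchors_x"]
        area = (p["length"] / 2.0) * g.strap_width
        n_lo, n_hi, n_apex = p["node_ids"]

        def element(curve_n, curve_t, rest, area=area):
            # stress curves are in MPa: force per unit strain = area * 1e6 Pa
            return ViscoelasticElement(curve_n, curve_t, 0.0, 0.0, rest, area * MPA_TO_PA)

        for nid, x in ((n_lo, x_lo), (n_hi, x_hi)):
            anchor = np.array([x, 0.0])
            pos = frame.point(anchor) + frame.direction([0.0, 1.0]) * rest_total
            system.add_node(Node(nid, pos, mass=node_mass))
            tissue = element(tissue_n, tissue_t, g.tissue_thickness_dorsal)
            padding = element(pad_n, pad_t, g.padding_thickness)
            unit = PHRIIUnit(
                nid,
                p["frame"],
                anchor,
                tissue,
                padding,
                label=f"{key}_{'prox' if x == x_lo else 'dist'}",
            )
            system.phrii_units.append(unit)
            unit_labels.append(unit.label)
            unit_areas.append(area)

        # raised apex node: present in the network, zero contact properties
        x_mid = 0.5 * (x_lo + x_hi)
        apex_anchor = np.array([x_mid, 0.0])
        apex_pos = (
            frame.point(apex_anchor)
            + frame.direction([0.0, 1.0]) * (rest_total + g.apex_standoff)
        )
        system.add_node(Node(n_apex, apex_pos, mass=node_mass))
        apex_unit = PHRIIUnit(
            n_apex,
            p["frame"],
            apex_anchor,
            ViscoelasticElement.zero(g.tissue_thickness_dorsal),
            ViscoelasticElement.zero(g.padding_thickness + g.apex_standoff),
            label=f"{key}_apex",
        )
        system.phrii_units.append(apex_unit)
        unit_labels.append(apex_unit.label)
        unit_areas.append(0.0)

        add_rigid_body(system, [n_lo, n_hi, n_apex])

        # strap assembly: two tension-only edge links through the palmar stack
        # (the strap bears on the palm over its full crossing length)
        palm_area = g.strap_width * g.palm_contact_length
        palm_law_disp = tissue_n.scaled(
            g.tissue_thickness_palmar, palm_area * MPA_TO_PA
        )
        for nid, x in ((n_lo, x_lo), (n_hi, x_hi)):
            anchor = np.array([x, -g.palm_depth])
            node_pos = system.nodes[system.node_index(nid)].position
            rest_len = float(np.linalg.norm(node_pos - frame.point(anchor)))
            strap_disp = StiffnessCurve.linear(strap_stiffness)
            combined = series_compose(strap_disp, palm_law_disp)
            strain_curve = combined.scaled(1.0 / rest_len, 1.0)
            link = ElasticLink(
                nid,
                None,
                strain_curve,
                rest_len,
                pretension=strap_pretension,
                tension_only=True,
                damping=2.0 * damping_zeta * np.sqrt(strap_stiffness * node_mass),
                # co-contraction thickens the palmar section of the hand:
                # the strap path lengthens by the fractional bulge over the
                # full palmar depth it wraps
                length_offset=cocontraction_bulge * g.palm_depth,
                frame=p["frame"],
                anchor_local=anchor,
                label=f"strap_{key}_{'prox' if x == x_lo else 'dist'}",
            )
            system.elastic_links.append(link)
            strap_labels.append(link.label)
            strap_indices.append(len(system.elastic_links) - 1)

    system.initialize()

    # viscous defaults: near-critical per unit from the series law's first slope
    for unit in system.phrii_units:
        if unit.is_null:
            continue
        m_eff = 1.5 * node_mass  # half a three-node plate per contact unit
        r_n = _critical_damping(unit._normal_law, m_eff, damping_zeta)
        r_t = _critical_damping(unit._tangential_law, m_eff, damping_zeta)
        unit.tissue.damping_normal = 2 * r_n
        unit.padding.damping_normal = 2 * r_n
        unit.tissue.damping_tangential = 2 * r_t
        unit.padding.damping_tangential = 2 * r_t
    system.initialize()

    system.metadata.update(
        {
            "scenario": "hand_dorsum",
            "geometry": asdict(g),
            "build_params": {
                "node_mass": node_mass,
                "strap_stiffness": strap_stiffness,
                "strap_pretension": strap_pretension,
                "cocontraction_bulge": cocontraction_bulge,
                "damping_zeta": damping_zeta,
                "stiffness_scale": stiffness_scale,
            },
            "unit_labels": unit_labels,
            "unit_areas_m2": unit_areas,
            "strap_labels": strap_labels,
            "strap_link_indices": strap_indices,
            "palm_pad_area_m2": g.strap_width * g.palm_contact_length,
            "n_straps": 2,
            "plate_nodes": {"mc": [0, 1, 2], "ph": [3, 4, 5]},
        }
    )
    return system


def make_mcp_moment_load(
    system: SystemModel, moment_fn: Callable[[float], float]
) -> Callable:
    """Generalized-force callable applying the MCP moment reaction couples.

    ``moment_fn(t)`` is the applied moment in N·m (positive = extension).
    The couple tilts each plate proximal-edge-up / distal-edge-down in the
    metacarpal-to-phalanx sense that reproduces the observed redistribution:
    near-MCP phalanx edge unloads, near-MCP metacarpal edge loads.
    """
    plate_nodes = system.metadata["plate_nodes"]
    pairs = [
        (system.node_index(plate_nodes["mc"][0]), system.node_index(plate_nodes["mc"][1])),
        (system.node_index(plate_nodes["ph"][0]), system.node_index(plate_nodes["ph"][1])),
    ]

    def load(t, q, v):
        Q = np.zeros_like(q)
        m = moment_fn(t)
        if m == 0.0:
            return Q
        for ia, ib in pairs:
            pa = q[2 * ia : 2 * ia + 2]
            pb = q[2 * ib : 2 * ib + 2]
            axis = pb - pa
            d = np.linalg.norm(axis)
            u = axis / d
            n = np.array([-u[1], u[0]])
            f = m / d
            Q[2 * ia : 2 * ia + 2] += f * n
            Q[2 * ib : 2 * ib + 2] += -f * n
        return Q

    return load


def _ramp(moment: float, ramp_time: float) -> Callable[[float], float]:
    def fn(t):
        if ramp_time <= 0:
            return moment
        return moment * min(1.0, max(0.0, t) / ramp_time)

    return fn


def _configure(system: SystemModel, protocol: LoadProtocol) -> SystemModel:
    """Deep-copied system with strap pretension/bulge from the protocol."""
    sys_run = copy.deepcopy(system)
    g = HandGeometry(**sys_run.metadata["geometry"])
    for idx in sys_run.metadata["strap_link_indices"]:
        link = sys_run.elastic_links[idx]
        link.pretension = protocol.strap_pretension
        link.length_offset = protocol.cocontraction_bulge * g.palm_depth
    return sys_run


def _plate_kinematics(
    system: SystemModel,
    result: SteadyStateResult,
    plate: str,
    reference_q: Optional[np.ndarray] = None,
):
    """Rotation and centroid displacement of a plate's contact-node pair.

    ``reference_q`` defaults to the construction state; passing the donned
    (pretension-settled, zero-load) state measures the operational relative
    displacement between the attachment and the bone.
    """
    ids = system.metadata["plate_nodes"][plate][:2]
    ia, ib = (system.node_index(i) for i in ids)
    q = result.state.q
    if reference_q is None:
        p0a = system.nodes[ia].position
        p0b = system.nodes[ib].position
    else:
        p0a = reference_q[2 * ia : 2 * ia + 2]
        p0b = reference_q[2 * ib : 2 * ib + 2]
    pa = q[2 * ia : 2 * ia + 2]
    pb = q[2 * ib : 2 * ib + 2]
    axis0 = p0b - p0a
    axis = pb - pa
    angle = np.arctan2(
        axis0[0] * axis[1] - axis0[1] * axis[0], float(axis0 @ axis)
    )
    centroid_disp = 0.5 * ((pa + pb) - (p0a + p0b))
    return float(angle), float(np.linalg.norm(centroid_disp))


def _steady_row(
    system: SystemModel,
    result: SteadyStateResult,
    reference_q: Optional[np.ndarray] = None,
) -> dict:
    labels = system.metadata["unit_labels"]
    areas = system.metadata["unit_areas_m2"]
    palm_area = system.metadata["palm_pad_area_m2"]
    row: dict = {}
    dorsal_pressures = []
    for s, label, area in zip(result.unit_states, labels, areas):
        if area <= 0:
            continue
        p = s["normal_force"] / area
        row[f"pressure_{label}_Pa"] = p
        row[f"normal_force_{label}_N"] = s["normal_force"]
        row[f"lifted_{label}"] = bool(s["lifted"])
        row[f"gap_{label}_m"] = s["gap"]
        dorsal_pressures.append(p)
    palm_pressures = []
    for s in result.link_tensions:
        row[f"tension_{s['label']}_N"] = s["tension"]
        palm_pressures.append(s["tension"] / palm_area)
    angle, rel = _plate_kinematics(system, result, "ph", reference_q)
    row["angle_deg"] = float(np.degrees(angle))
    row["rel_disp_mm"] = rel * 1e3
    row["peak_dorsal_pressure_kPa"] = max(dorsal_pressures) / 1e3
    row["peak_pressure_kPa"] = max(dorsal_pressures + palm_pressures) / 1e3
    row["settle_time_s"] = result.diagnostics["settle_time"]
    return row


def run_isometric_moment_study(
    system: SystemModel,
    protocol: LoadProtocol,
    moment_grid: Sequence[float],
    pretension_grid: Sequence[float],
    **solver_kwargs,
) -> pd.DataFrame:
    """Steady-state study over a (moment, pretension) grid.

    Returns one row per grid point with the phalanx-plate angular
    displacement, relative displacement of the attachment versus the bone,
    per-unit pressures and lift-off flags.
    """
    if len(moment_grid) == 0 or len(pretension_grid) == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for pre in pretension_grid:
        # donned reference state: pretension applied, no moment, no bulge
        base_proto = LoadProtocol(
            applied_moment=0.0,
            max_moment=protocol.max_moment,
            ramp_time=protocol.ramp_time,
            strap_pretension=pre,
            cocontraction_bulge=0.0,
        )
        sys_base = _configure(system, base_proto)
        base_q = steady_state(sys_base, None, **solver_kwargs).state.q
        for m in moment_grid:
            proto = LoadProtocol(
                applied_moment=m,
                max_moment=max(protocol.max_moment, abs(m)),
                ramp_time=protocol.ramp_time,
                strap_pretension=pre,
                cocontraction_bulge=protocol.cocontraction_bulge,
            )
            sys_run = _configure(system, proto)
            load = make_mcp_moment_load(sys_run, _ramp(m, proto.ramp_time))
            try:
                result = steady_state(sys_run, load, **solver_kwargs)
            except Exception as exc:
                raise RuntimeError(
                    f"steady state failed at moment={m}, pretension={pre}"
                ) from exc
            row = {"moment_Nm": m, "pretension_N": pre}
            row.update(_steady_row(sys_run, result, base_q))
            rows.append(row)
    return pd.DataFrame(rows)


def detect_liftoff_pattern(row: pd.Series | dict) -> dict:
    """Classify which phalanx-plate end has lifted in one study row."""
    row = dict(row)
    near = bool(row.get("lifted_ph_prox", False))
    far = bool(row.get("lifted_ph_dist", False))
    if near and not far:
        return {"which_end_lifted": "near_mcp", "gap": row.get("gap_ph_prox_m", 0.0)}
    if far and not near:
        return {"which_end_lifted": "far_mcp", "gap": row.get("gap_ph_dist_m", 0.0)}
    if near and far:
        gap = max(row.get("gap_ph_prox_m", 0.0), row.get("gap_ph_dist_m", 0.0))
        return {"which_end_lifted": "both", "gap": gap}
    return {"which_end_lifted": None, "gap": 0.0}


def strap_stiffness_study(
    system: SystemModel,
    stiffness_grid: Sequence[float],
    cocontraction_bulge: float = 0.0,
    moment: float = 0.1,
    pretension: float = 2.0,
    **solver_kwargs,
) -> pd.DataFrame:
    """Sweep strap stiffness at fixed load, with optional co-contraction.

    Without bulge, both the relative displacement and the peak interface
    pressure improve monotonically toward inelastic straps.  With a palmar
    bulge, stiff straps convert the thickness change into extra interface
    pressure, so the peak pressure acquires an interior optimum at finite
    strap stiffness while the displacement penalty there stays small.
    """
    if cocontraction_bulge < 0:
        raise ValueError("cocontraction_bulge must be >= 0")
    meta = system.metadata
    if meta.get("scenario") != "hand_dorsum":
        raise ValueError("strap_stiffness_study needs a hand scenario system")
    g = HandGeometry(**meta["geometry"])
    params = dict(meta["build_params"])
    rows = []
    for k in stiffness_grid:
        params_k = dict(params)
        params_k["strap_stiffness"] = float(k)
        params_k["strap_pretension"] = pretension
        params_k["cocontraction_bulge"] = 0.0
        sys_base = build_hand_system(g, **params_k)
        base_q = steady_state(sys_base, None, **solver_kwargs).state.q
        params_k["cocontraction_bulge"] = cocontraction_bulge
        sys_run = build_hand_system(g, **params_k)
        load = make_mcp_moment_load(sys_run, _ramp(moment, 0.05))
        result = steady_state(sys_run, load, **solver_kwargs)
        row = {
            "strap_stiffness_N_per_m": float(k),
            "cocontraction_bulge": cocontraction_bulge,
            "moment_Nm": moment,
            "pretension_N": pretension,
        }
        row.update(_steady_row(sys_run, result, base_q))
        rows.append(row)
    return pd.DataFrame(rows)
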