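"""Quasi-static design optimization of a rigid attachment plate interface.

A rigid plate of length L rests on the dorsum through a row of series
springs (device padding k_pHRI over tissue k_dorsum).  External loading is
resolved, by transmissibility, into a normal force F_L and a moment M_L at
the plate centre, plus the strap bias force F_b applied there.  Comfort is
scored by the peak reaction pressure along the contact.

Closed-form theory for the pressure distribution that minimises the peak:
it consists of two uniform regions; the high region has its centroid at

    x = M_L / (F_L + F_b),        P_peak = (F_L + F_b) / (L - 2 x),

and the bias force that minimises the peak for a given loading is the
smallest one yielding a non-negative low region,

    F_b = max(0, 4 M_L / L - F_L).

Sign convention: M_L is positive counter-clockwise and shifts the
high-pressure region toward +x, so the pressure field satisfies
``sum p_i s = F_L + F_b`` and ``sum p_i x_i s = M_L`` (first moment about
the plate centre equal to the applied moment).

The discrete model mirrors the numerical design study: the plate bears on
``n_points`` unilateral springs with a symmetric linear stiffness taper
(k_mid at the centre down to k_edge); equilibrium in translation and tilt is
solved with an active-set release of springs that would pull.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .materials import series_elastic

__all__ = [
    "PlateLoadCase",
    "PressureProfile",
    "StiffnessProfile",
    "InfeasibleDesignError",
    "peak_pressure_cost",
    "analytic_optimum",
    "optimal_bias_force",
    "simulate_discrete_interface",
    "design_sweep",
    "padding_stiffness",
    "padding_profile_from_map",
]


class InfeasibleDesignError(ValueError):
    """The requested load case admits no non-negative pressure solution."""


@dataclass
class PlateLoadCase:
    """External load resolved at the plate centre.

    ``F_L`` is the normal component of the external force (N), ``M_L`` the
    external moment (N·m, counter-clockwise positive), ``F_b`` the strap
    bias force (N), ``L`` the plate length (m).
    """

    F_L: float
    M_L: float
    F_b: float
    L: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("plate length L must be > 0")
        if self.F_L + self.F_b < 0:
            raise ValueError("net normal load F_L + F_b must be >= 0")

    @property
    def F_total(self) -> float:
        return self.F_L + self.F_b


@dataclass
class PressureProfile:
    """Line-pressure distribution along the plate (positions about centre).

    ``pressures`` are line pressures in N/m (divide by plate width for Pa);
    ``region_boundary`` marks the start of the high-pressure region and
    ``center_high_region`` its centroid for two-region analytic profiles.
    """

    positions: np.ndarray
    pressures: np.ndarray
    cell_width: float
    peak: float = field(init=False)
    region_boundary: Optional[float] = None
    center_high_region: Optional[float] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.positions.shape != self.pressures.shape:
            raise ValueError("positions and pressures must align")
        if np.any(self.pressures < -1e-12):
            raise ValueError("pressures must be non-negative")
        self.peak = float(np.max(self.pressures)) if self.pressures.size else 0.0

    def total_force(self) -> float:
        return float(np.sum(self.pressures) * self.cell_width)

    def total_moment(self) -> float:
        return float(np.sum(self.pressures * self.positions) * self.cell_width)


@dataclass
class StiffnessProfile:
    """Symmetric linear stiffness taper along the plate.

    ``k_mid`` and ``k_edge`` in N/m (per contact point); the per-point
    effective stiffness is linear in |x| from centre to edge.  The gradient
    is ``(k_mid - k_edge)/(L/2)`` in N/m per m.
    """

    k_mid: float
    k_edge: float
    L: float
    n_points: int = 15

    def __post_init__(self) -> None:
        if not (self.k_mid >= self.k_edge > 0):
            raise ValueError("requires k_mid >= k_edge > 0")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.L <= 0:
            raise ValueError("L must be > 0")

    @property
    def gradient(self) -> float:
        return (self.k_mid - self.k_edge) / (self.L / 2)

    def positions(self) -> np.ndarray:
        s = self.L / self.n_points
        return (np.arange(self.n_points) - (self.n_points - 1) / 2) * s

    def per_point(self) -> np.ndarray:
        x = self.positions()
        return self.k_mid - (self.k_mid - self.k_edge) * np.abs(x) / (self.L / 2)

    @classmethod
    def from_gradient(
        cls, mean_stiffness: float, gradient: float, L: float, n_points: int = 15
    ) -> "StiffnessProfile":
        """Profile of given spatial gradient at fixed mean stiffness
        (k_mid = k̄ + gL/4, k_edge = k̄ − gL/4), keeping total compliance
        comparable across a gradient sweep."""
        k_mid = mean_stiffness + gradient * L / 4
        k_edge = mean_stiffness - gradient * L / 4
        return cls(k_mid, k_edge, L, n_points)


def peak_pressure_cost(profile: PressureProfile) -> float:
    """Comfort cost: the maximum reaction pressure along the contact."""
    return profile.peak


def analytic_optimum(case: PlateLoadCase, n_points: int = 201) -> PressureProfile:
    """Minimum-peak-pressure distribution for a load case, in closed form.

    Two uniform regions: the high region of width ``L - 2x`` ends at the
    plate edge on the moment side with centroid at ``x = M_L/(F_L+F_b)`` and
    carries ``P_peak = (F_L+F_b)/(L-2x)``; the rest of the plate is at zero
    pressure.  With ``M_L = 0`` this degenerates to uniform pressure
    ``(F_L+F_b)/L``.  A clockwise moment mirrors the profile.
    """
    F, M, L = case.F_total, case.M_L, case.L
    if F <= 0:
        if M != 0:
            raise InfeasibleDesignError("cannot balance a moment with zero net force")
        x_pos = (np.arange(n_points) - (n_points - 1) / 2) * (L / n_points)
        return PressureProfile(x_pos, np.zeros(n_points), L / n_points)
    x = M / F
    if abs(x) >= L / 2:
        raise InfeasibleDesignError(
            f"high-region centre x={x:.4g} m lies outside the plate; "
            "increase the bias force F_b"
        )
    peak = F / (L - 2 * abs(x))
    s = L / n_points
    x_pos = (np.arange(n_points) - (n_points - 1) / 2) * s
    boundary = 2 * x - L / 2 if x >= 0 else 2 * x + L / 2
    # cell-averaged sampling of the two-region law: the force integral is
    # exact and the moment error is O(cell width squared)
    lo, hi = x_pos - s / 2, x_pos + s / 2
    if x >= 0:
        overlap = np.clip(hi - np.maximum(lo, boundary), 0.0, s)
    else:
        overlap = np.clip(np.minimum(hi, boundary) - lo, 0.0, s)
    pressures = peak * overlap / s
    return PressureProfile(
        x_pos,
        pressures,
        s,
        region_boundary=float(boundary),
        center_high_region=float(x),
    )


def analytic_peak(case: PlateLoadCase) -> float:
    """Closed-form P_peak = (F_L+F_b)/(L-2|x|) with x = M_L/(F_L+F_b)."""
    F, M, L = case.F_total, case.M_L, case.L
    if F <= 0:
        return 0.0
    x = abs(M / F)
    if x >= L / 2:
        raise InfeasibleDesignError("infeasible: |x| >= L/2; increase F_b")
    return F / (L - 2 * x)


def optimal_bias_force(F_L: float, M_L: float, L: float) -> float:
    """Bias force minimising the peak pressure: max(0, 4 M_L / L - F_L).

    It is the smallest bias for which the low-pressure region of the
    optimal distribution is non-negative; at this value the peak-vs-bias
    curve attains its minimum.
    """
    if L <= 0:
        raise ValueError("L must be > 0")
    if M_L < 0:
        raise ValueError("M_L must be >= 0 (mirror the case for clockwise loads)")
    return max(0.0, 4.0 * M_L / L - F_L)


def simulate_discrete_interface(
    profile: StiffnessProfile, case: PlateLoadCase
) -> tuple[PressureProfile, float, float]:
    """Rigid-plate equilibrium on a row of unilateral springs.

    Solves for the plate translation ``z`` (m, toward the tissue) and tilt
    ``theta`` (rad) such that the spring forces balance ``F_L + F_b`` and
    ``M_L``; springs that would pull are released (zero force) and the
    equilibrium re-solved (active-set iteration).  Returns the line-pressure
    profile (force / cell width), the relative displacement (largest plate
    penetration, ``|z| + |theta| L/2``) and the tilt.
    """
    if abs(profile.L - case.L) > 1e-12:
        raise ValueError("profile and load case disagree on plate length")
    k = profile.per_point()
    x = profile.positions()
    s = case.L / profile.n_points
    F, M = case.F_total, case.M_L

    active = np.ones_like(k, dtype=bool)
    for _ in range(profile.n_points + 1):
        ka = np.where(active, k, 0.0)
        S0 = ka.sum()
        S1 = float(ka @ x)
        S2 = float(ka @ (x * x))
        det = S0 * S2 - S1 * S1
        if S0 <= 0 or det <= 1e-300:
            raise InfeasibleDesignError(
                "no equilibrium: all springs released (moment too large for load)"
            )
        z = (S2 * F - S1 * M) / det
        theta = (S0 * M - S1 * F) / det
        c = z + theta * x
        new_active = c > 0
        if not np.any(new_active):
            raise InfeasibleDesignError(
                "no equilibrium: all springs released (moment too large for load)"
            )
        if np.array_equal(new_active, active):
            break
        active = new_active
    forces = np.where(active, k * np.maximum(c, 0.0), 0.0)
    pressures = forces / s
    prof = PressureProfile(x, pressures, s)
    rel_disp = abs(z) + abs(theta) * case.L / 2
    return prof, float(rel_disp), float(theta)


def design_sweep(
    F_b_grid: Sequence[float],
    gradient_grid: Sequence[float],
    base_case: PlateLoadCase,
    mean_stiffness: float,
    n_points: int = 15,
    M_L_grid: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Sweep bias force and stiffness-profile gradient (and optionally the
    applied moment), recording peak pressure and relative displacement of
    each discrete equilibrium."""
    if len(F_b_grid) == 0 or len(gradient_grid) == 0:
        raise ValueError("grids must be non-empty")
    moments = list(M_L_grid) if M_L_grid is not None else [base_case.M_L]
    rows = []
    for M in moments:
        for F_b in F_b_grid:
            case = PlateLoadCase(base_case.F_L, M, F_b, base_case.L)
            for g in gradient_grid:
                prof = StiffnessProfile.from_gradient(
                    mean_stiffness, g, base_case.L, n_points
                )
                pressure, rel, tilt = simulate_discrete_interface(prof, case)
                rows.append(
                    {
                        "M_L_Nm": M,
                        "F_b_N": F_b,
                        "gradient_N_per_m2": g,
                        "peak_pressure_N_per_m": pressure.peak,
                        "rel_disp_m": rel,
                        "tilt_rad": tilt,
                        "force_balance_err": pressure.total_force() - case.F_total,
                        "moment_balance_err": pressure.total_moment() - M,
                    }
                )
    return pd.DataFrame(rows)


def padding_profile_from_map(
    k_eff_per_point: Sequence[float], k_dorsum_per_point: Sequence[float]
) -> np.ndarray:
    """Pointwise padding synthesis from a measured dorsum stiffness map.

    Applies the series inversion at every attachment point: given the
    target effective stiffness profile and the measured dorsum stiffness at
    the same locations (consistent units, e.g. both N/mm), returns the
    padding stiffness k_pHRI per point.  Points where the dorsum alone is
    softer than the target raise :class:`InfeasibleDesignError`.
    """
    k_eff = np.asarray(k_eff_per_point, dtype=float)
    k_d = np.asarray(k_dorsum_per_point, dtype=float)
    if k_eff.shape != k_d.shape:
        raise ValueError("profiles must have equal length")
    return np.array([padding_stiffness(e, d) for e, d in zip(k_eff, k_d)])


def padding_stiffness(k_eff: float, k_dorsum: float) -> float:
    """Padding stiffness achieving a target series stiffness over the dorsum:
    k_pHRI = k_eff * k_dorsum / (k_dorsum - k_eff).

    Requires ``0 < k_eff < k_dorsum``: the series stack is always softer
    than its softest member, so a target at or above the dorsum stiffness is
    unachievable by any positive padding.
    """
    if k_eff <= 0:
        raise ValueError("k_eff must be > 0")
    if k_eff >= k_dorsum:
        raise InfeasibleDesignError(
            f"target k_eff={k_eff:g} >= k_dorsum={k_dorsum:g}: the dorsum alone "
            "is too soft to reach this effective stiffness"
        )
    k = k_eff * k_dorsum / (k_dorsum - k_eff)
    assert abs(series_elastic(k, k_dorsum) - k_eff) <= 1e-9 * k_eff
    return k
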