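"""Piecewise-linear viscoelastic material laws and series-coupling algebra.

Soft-tissue stress-strain behaviour on the hand (skin in tension/shear,
skin plus subcutaneous tissue in compression) is well approximated by
piecewise-linear laws: an initially compliant toe region followed by sharply
stiffer segments as collagen fibres engage.  :class:`StiffnessCurve` encodes
such a law as ascending strain breakpoints with one non-negative slope per
segment, optionally blended at each knee by a quadratic smoothing zone so the
tangent stiffness is continuous.

The same class doubles as a lumped force-displacement spring law (slopes in
N/m over displacement breakpoints in m) via :meth:`StiffnessCurve.scaled`.
Two springs stacked in series combine exactly: compliances add segment-wise
in the force domain, which :func:`series_compose` evaluates in closed form so
the composed law is again piecewise linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "StiffnessCurve",
    "ViscoelasticElement",
    "evaluate_force",
    "tangent_stiffness",
    "series_elastic",
    "series_damping",
    "series_compose",
    "load_material_table",
    "default_material_table",
    "curves_from_table",
]


@dataclass
class StiffnessCurve:
    """Monotone piecewise-linear force law ``f(x) = integral of slope``.

    Parameters
    ----------
    breakpoints
        Strictly increasing abscissa values starting at 0.  ``slopes[i]``
        applies on ``[breakpoints[i], breakpoints[i+1])``; the final slope
        extends to infinity.
    slopes
        One non-negative slope per breakpoint.
    smoothing_halfwidth
        Half-width of the quadratic blending zone centred on each interior
        breakpoint.  ``0`` gives the exact piecewise-linear law.  Must not
        exceed half the smallest segment width.
    """

    breakpoints: np.ndarray
    slopes: np.ndarray
    smoothing_halfwidth: float = 0.0
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.breakpoints = np.atleast_1d(np.asarray(self.breakpoints, dtype=float))
        self.slopes = np.atleast_1d(np.asarray(self.slopes, dtype=float))
        if self.breakpoints.ndim != 1 or self.breakpoints.size == 0:
            raise ValueError("breakpoints must be a non-empty 1-D sequence")
        if self.breakpoints[0] != 0.0:
            raise ValueError("breakpoints must start at 0")
        if self.breakpoints.size > 1 and np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.slopes.shape != self.breakpoints.shape:
            raise ValueError("slopes must match breakpoints in length")
        if np.any(self.slopes < 0):
            raise ValueError("all slopes must be non-negative")
        if self.smoothing_halfwidth < 0:
            raise ValueError("smoothing_halfwidth must be >= 0")
        if self.smoothing_halfwidth > 0 and self.breakpoints.size > 1:
            min_gap = float(np.min(np.diff(self.breakpoints)))
            if self.smoothing_halfwidth > min_gap / 2 + 1e-15:
                raise ValueError(
                    "smoothing_halfwidth exceeds half the smallest segment "
                    f"width ({min_gap / 2:g})"
                )
        # cumulative force at each breakpoint of the unsmoothed backbone
        if self.breakpoints.size > 1:
            seg = self.slopes[:-1] * np.diff(self.breakpoints)
            self._cum = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self._cum = np.zeros(1)

    # -- evaluation ------------------------------------------------------

    def force(self, x):
        """Force at abscissa ``x`` (>= 0); scalar or array."""
        x_arr = np.asarray(x, dtype=float)
        if np.any(x_arr < 0):
            raise ValueError("strain/displacement must be non-negative")
        idx = np.searchsorted(self.breakpoints, x_arr, side="right") - 1
        f = self._cum[idx] + self.slopes[idx] * (x_arr - self.breakpoints[idx])
        h = self.smoothing_halfwidth
        if h > 0:
            for j in range(1, self.breakpoints.size):
                bj = self.breakpoints[j]
                ds = self.slopes[j] - self.slopes[j - 1]
                if ds == 0:
                    continue
                in_zone = np.abs(x_arr - bj) < h
                if np.any(in_zone):
                    xz = x_arr[in_zone] if x_arr.ndim else x_arr
                    corr = (
                        ds * (xz - bj + h) ** 2 / (4 * h)
                        - ds * np.maximum(0.0, xz - bj)
                    )
                    if x_arr.ndim:
                        f[in_zone] += corr
                    else:
                        f = f + corr
        return f if x_arr.ndim else float(f)

    def tangent(self, x):
        """Derivative of :meth:`force`; equals the segment slope outside
        smoothing zones."""
        x_arr = np.asarray(x, dtype=float)
        if np.any(x_arr < 0):
            raise ValueError("strain/displacement must be non-negative")
        idx = np.searchsorted(self.breakpoints, x_arr, side="right") - 1
        k = self.slopes[idx].astype(float).copy() if x_arr.ndim else float(self.slopes[idx])
        h = self.smoothing_halfwidth
        if h > 0:
            for j in range(1, self.breakpoints.size):
                bj = self.breakpoints[j]
                ds = self.slopes[j] - self.slopes[j - 1]
                if ds == 0:
                    continue
                in_zone = np.abs(x_arr - bj) < h
                if np.any(in_zone):
                    xz = x_arr[in_zone] if x_arr.ndim else x_arr
                    corr = ds * (xz - bj + h) / (2 * h) - ds * (xz > bj)
                    if x_arr.ndim:
                        k[in_zone] += corr
                    else:
                        k = k + corr
        return k

    # -- structure -------------------------------------------------------

    @property
    def max_force(self) -> float:
        """Largest force the law can transmit (inf unless a slope is 0)."""
        zero = np.nonzero(self.slopes == 0.0)[0]
        if zero.size:
            return float(self._cum[zero[0]])
        return np.inf

    def scaled(self, x_scale: float, f_scale: float) -> "StiffnessCurve":
        """Rescale abscissa by ``x_scale`` and ordinate by ``f_scale``.

        Turns a strain-domain stress law into a displacement-domain force law:
        ``x_scale`` = rest thickness (m), ``f_scale`` = stress-to-force factor
        (Pa-to-N, i.e. loaded area).
        """
        if x_scale <= 0 or f_scale < 0:
            raise ValueError("x_scale must be > 0 and f_scale >= 0")
        return StiffnessCurve(
            self.breakpoints * x_scale,
            self.slopes * (f_scale / x_scale),
            self.smoothing_halfwidth * x_scale,
        )

    def inverse(self, f: float) -> float:
        """Displacement at which the unsmoothed backbone reaches force ``f``."""
        if f < 0:
            raise ValueError("force must be non-negative")
        if f > self.max_force:
            raise ValueError("force exceeds the saturation force of this law")
        j = int(np.searchsorted(self._cum, f, side="right") - 1)
        j = min(j, self.slopes.size - 1)
        while self.slopes[j] == 0.0 and j > 0 and self._cum[j] >= f:
            j -= 1
        if self.slopes[j] == 0.0:
            return float(self.breakpoints[j])
        return float(self.breakpoints[j] + (f - self._cum[j]) / self.slopes[j])

    def stiffness_at_force(self, f: float) -> float:
        """Backbone segment slope at force level ``f``."""
        return float(self.tangent_backbone(self.inverse(f)))

    def tangent_backbone(self, x: float) -> float:
        idx = int(np.searchsorted(self.breakpoints, x, side="right") - 1)
        return float(self.slopes[idx])

    @classmethod
    def linear(cls, slope: float) -> "StiffnessCurve":
        return cls(np.array([0.0]), np.array([float(slope)]))

    @classmethod
    def zero(cls) -> "StiffnessCurve":
        return cls(np.array([0.0]), np.array([0.0]))


def evaluate_force(curve: StiffnessCurve, strain):
    """Force (or stress) carried by ``curve`` at the given strain.

    Strain is a magnitude; callers resolve sign and contact state.  Negative
    strain raises ``ValueError``.
    """
    return curve.force(strain)


def tangent_stiffness(curve: StiffnessCurve, strain):
    """Local derivative of :func:`evaluate_force` (slope of the active
    segment outside smoothing zones)."""
    return curve.tangent(strain)


def series_elastic(k1: float, k2: float) -> float:
    """Effective stiffness of two linear springs in series, k1*k2/(k1+k2).

    Both inputs must be strictly positive; the result is below min(k1, k2).
    Units are preserved (N/mm in, N/mm out).
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("series stiffness requires strictly positive inputs")
    return k1 * k2 / (k1 + k2)


def series_damping(r1: float, r2: float) -> float:
    """Series combination of two viscous coefficients (zero if either is 0)."""
    if r1 < 0 or r2 < 0:
        raise ValueError("damping coefficients must be >= 0")
    if r1 == 0 or r2 == 0:
        return 0.0
    return r1 * r2 / (r1 + r2)


def series_compose(
    a: StiffnessCurve, b: StiffnessCurve, smoothing_halfwidth: float | None = None
) -> StiffnessCurve:
    """Exact series composition of two displacement-domain spring laws.

    At common force ``F`` the displacements add, so the composed law is built
    in the force domain: at every force level the segment compliances
    ``1/k_a + 1/k_b`` add, with knots wherever either input law has a knee.
    A zero-slope segment (saturation) in either input caps the transmissible
    force of the composition.

    The returned curve's smoothing half-width defaults to the larger of the
    inputs', clamped to the composed geometry.
    """
    f_cap = min(a.max_force, b.max_force)
    if f_cap == 0.0:
        return StiffnessCurve.zero()

    knots = {0.0}
    for c in (a, b):
        for f in c._cum:
            if 0.0 < f < f_cap:
                knots.add(float(f))
    f_knots = np.array(sorted(knots))

    bps = [0.0]
    slopes = []
    d = 0.0
    for i, f_lo in enumerate(f_knots):
        f_hi = f_knots[i + 1] if i + 1 < f_knots.size else f_cap
        if np.isinf(f_hi):
            # beyond the last knot both laws are in their final segment
            f_mid = f_lo + (f_lo + 1.0) * 1e-6
        else:
            f_mid = 0.5 * (f_lo + f_hi)
        ka = a.stiffness_at_force(f_mid)
        kb = b.stiffness_at_force(f_mid)
        k_ser = series_elastic(ka, kb)
        slopes.append(k_ser)
        if np.isfinite(f_hi):
            d += (f_hi - f_lo) / k_ser
            bps.append(d)
    if np.isfinite(f_cap):
        slopes.append(0.0)

    bps_arr = np.array(bps)
    slopes_arr = np.array(slopes)
    if smoothing_halfwidth is None:
        smoothing_halfwidth = max(a.smoothing_halfwidth, b.smoothing_halfwidth)
    if bps_arr.size > 1:
        smoothing_halfwidth = min(
            smoothing_halfwidth, float(np.min(np.diff(bps_arr))) / 2
        )
    else:
        smoothing_halfwidth = 0.0
    return StiffnessCurve(bps_arr, slopes_arr, smoothing_halfwidth)


@dataclass
class ViscoelasticElement:
    """One viscoelastic layer of a contact stack (tissue or device padding).

    Elastic behaviour is split into an independent normal (compressive) and
    tangential (skin stretch / padding shear) direction, each with its own
    strain-domain :class:`StiffnessCurve` and viscous coefficient.

    ``force_scale`` converts the curve's force unit into newtons; for
    stress-strain curves in MPa it is ``loaded_area_m2 * 1e6``.
    """

    elastic_normal: StiffnessCurve
    elastic_tangential: StiffnessCurve
    damping_normal: float = 0.0
    damping_tangential: float = 0.0
    rest_thickness: float = 1.0e-3
    force_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.damping_normal < 0 or self.damping_tangential < 0:
            raise ValueError("damping coefficients must be >= 0")
        if self.rest_thickness <= 0:
            raise ValueError("rest_thickness must be > 0")
        if self.force_scale < 0:
            raise ValueError("force_scale must be >= 0")

    def normal_law(self) -> StiffnessCurve:
        """Displacement-domain (m -> N) normal force law."""
        return self.elastic_normal.scaled(self.rest_thickness, self.force_scale)

    def tangential_law(self) -> StiffnessCurve:
        """Displacement-domain (m -> N) tangential force law."""
        return self.elastic_tangential.scaled(self.rest_thickness, self.force_scale)

    @classmethod
    def zero(cls, rest_thickness: float = 1.0e-3) -> "ViscoelasticElement":
        """A null element: transmits no force (used for non-contacting
        network points whose viscoelastic values are set to zero)."""
        return cls(
            StiffnessCurve.zero(),
            StiffnessCurve.zero(),
            0.0,
            0.0,
            rest_thickness,
            0.0,
        )


# -- material parameter tables ------------------------------------------

_TABLE_COLUMNS = ["material", "direction", "breakpoint_strain", "slope", "units"]


def default_material_table() -> pd.DataFrame:
    """Built-in material parameter table.

    ``skin/tangential`` carries the literature piecewise-linear tensile law
    (0.1 MPa up to strain 0.4, then 18.8 MPa).  ``soft_tissue/normal`` is an
    editable PLACEHOLDER J-shaped compressive law for skin plus subcutaneous
    tissue: the literature establishes the shape but prints no digitised
    values, so these four segments are a stand-in to be replaced by measured
    data.  Padding rows describe a generic firm device foam.
    """
    rows = [
        ("skin", "tangential", 0.0, 0.1, "MPa"),
        ("skin", "tangential", 0.4, 18.8, "MPa"),
        ("soft_tissue", "normal", 0.0, 0.08, "MPa"),
        ("soft_tissue", "normal", 0.15, 0.2, "MPa"),
        ("soft_tissue", "normal", 0.30, 0.6, "MPa"),
        ("soft_tissue", "normal", 0.45, 5.0, "MPa"),
        ("padding", "normal", 0.0, 0.5, "MPa"),
        ("padding", "tangential", 0.0, 0.3, "MPa"),
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def load_material_table(path) -> pd.DataFrame:
    """Read a material parameter CSV (columns: material, direction,
    breakpoint_strain, slope, units)."""
    table = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"material table missing columns: {sorted(missing)}")
    return table


def curves_from_table(
    table: pd.DataFrame, smoothing_halfwidth: float = 0.02
) -> dict[tuple[str, str], StiffnessCurve]:
    """Build ``(material, direction) -> StiffnessCurve`` from a table.

    Rows of one material/direction are sorted by breakpoint strain; each
    row's slope applies from its breakpoint to the next.  The smoothing
    half-width is clamped per curve to half its smallest segment.
    """
    curves: dict[tuple[str, str], StiffnessCurve] = {}
    for (mat, direction), group in table.groupby(["material", "direction"]):
        g = group.sort_values("breakpoint_strain")
        bps = g["breakpoint_strain"].to_numpy(dtype=float)
        slopes = g["slope"].to_numpy(dtype=float)
        h = smoothing_halfwidth
        if bps.size > 1:
            h = min(h, float(np.min(np.diff(bps))) / 2)
        else:
            h = 0.0
        curves[(str(mat), str(direction))] = StiffnessCurve(bps, slopes, h)
    return curves
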