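import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from hurosim.materials import (
    StiffnessCurve,
    ViscoelasticElement,
    evaluate_force,
    series_compose,
    series_damping,
    series_elastic,
    tangent_stiffness,
    curves_from_table,
    default_material_table,
    load_material_table,
)


@st.composite
def curves(draw, max_segments=4):
    n = draw(st.integers(1, max_segments))
    gaps = draw(
        st.lists(st.floats(0.05, 0.5), min_size=max(0, n - 1), max_size=n - 1)
    )
    bps = np.concatenate([[0.0], np.cumsum(gaps)]) if n > 1 else np.array([0.0])
    slopes = np.array(draw(st.lists(st.floats(0.0, 20.0), min_size=n, max_size=n)))
    h = draw(st.floats(0.0, 0.02))
    if bps.size > 1:
        h = min(h, float(np.min(np.diff(bps))) / 2)
    else:
        h = 0.0
    return StiffnessCurve(bps, slopes, h)


class TestEvaluateForce:
    @pytest.mark.parametrize(
        "strain,expected",
        [
            (0.0, 0.0),  # zero strain, zero force
            (0.2, 0.02),  # within the 0.1 MPa toe segment
            (0.5, 0.1 * 0.4 + 18.8 * 0.1),  # hand integration across the knee
        ],
    )
    def test_skin_tangential_values(self, skin_tangential, strain, expected):
        assert evaluate_force(skin_tangential, strain) == pytest.approx(expected)

    def test_negative_strain_rejected(self, skin_tangential):
        with pytest.raises(ValueError):
            evaluate_force(skin_tangential, -0.1)

    @given(c=curves(), x=st.floats(0.0, 3.0))
    def test_monotone_nondecreasing(self, c, x):
        assert c.force(x + 0.01) >= c.force(x) - 1e-12

    @given(c=curves(), x=st.floats(1e-3, 3.0))
    def test_continuity(self, c, x):
        eps = 1e-7
        assert abs(c.force(x + eps) - c.force(x - eps)) < 1e-4 * (1 + c.force(x))

    @given(c=curves(), x=st.floats(0.0, 3.0))
    def test_smoothing_converges_to_piecewise_linear(self, c, x):
        sharp = StiffnessCurve(c.breakpoints, c.slopes, 0.0)
        prev = None
        for h in [0.02, 0.002, 0.0002]:
            hh = min(h, c.smoothing_halfwidth) if c.smoothing_halfwidth else 0.0
            smooth = StiffnessCurve(c.breakpoints, c.slopes, hh)
            err = abs(smooth.force(x) - sharp.force(x))
            if prev is not None:
                assert err <= prev + 1e-12
            prev = err
        assert prev <= 0.0002 * np.max(c.slopes) / 2 + 1e-12

    def test_force_zero_at_origin_with_smoothing(self, default_curves):
        for curve in default_curves.values():
            assert curve.force(0.0) == 0.0


class TestTangentStiffness:
    def test_single_segment_constant(self):
        c = StiffnessCurve([0.0], [1.2])
        for x in [0.0, 0.3, 2.5]:
            assert tangent_stiffness(c, x) == 1.2

    def test_skin_toe_slope(self, skin_tangential):
        assert tangent_stiffness(skin_tangential, 0.2) == pytest.approx(0.1)

    @given(c=curves(), x=st.floats(0.01, 2.0))
    def test_matches_central_difference(self, c, x):
        eps = 1e-7
        fd = (c.force(x + eps) - c.force(x - eps)) / (2 * eps)
        assert tangent_stiffness(c, x) == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_finite_difference_beyond_knee(self, skin_tangential):
        eps = 1e-7
        fd = (skin_tangential.force(0.5 + eps) - skin_tangential.force(0.5 - eps)) / (
            2 * eps
        )
        assert tangent_stiffness(skin_tangential, 0.5) == pytest.approx(fd, rel=1e-6)


class TestSeriesElastic:
    def test_equal_springs_halve(self):
        assert series_elastic(3.0, 3.0) == pytest.approx(1.5)

    def test_rigid_limit(self):
        assert series_elastic(1.0, 1e9) == pytest.approx(1.0, rel=1e-6)

    def test_dorsum_indenter_values(self):
        # mean dorsum stiffness against the instrument stiffness
        assert series_elastic(1.0876, 2.67) == pytest.approx(0.7728, abs=2e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            series_elastic(0.0, 1.0)
        with pytest.raises(ValueError):
            series_elastic(1.0, -2.0)

    @given(
        k1=st.floats(1e-3, 1e3),
        k2=st.floats(1e-3, 1e3),
        k3=st.floats(1e-3, 1e3),
    )
    def test_commutative_associative_bounded(self, k1, k2, k3):
        assert series_elastic(k1, k2) == pytest.approx(series_elastic(k2, k1))
        left = series_elastic(series_elastic(k1, k2), k3)
        right = series_elastic(k1, series_elastic(k2, k3))
        assert left == pytest.approx(right, rel=1e-12)
        assert series_elastic(k1, k2) < min(k1, k2)

    def test_series_damping_zero_shortcut(self):
        assert series_damping(0.0, 5.0) == 0.0
        assert series_damping(4.0, 4.0) == pytest.approx(2.0)


class TestSeriesCompose:
    @given(a=curves(max_segments=3), b=curves(max_segments=3),
           d=st.floats(1e-3, 2.0))
    def test_matches_partition_oracle(self, a, b, d):
        # the composed law must agree with explicitly solving the
        # force-equality partition delta1 + delta2 = d
        a = StiffnessCurve(a.breakpoints, np.maximum(a.slopes, 1e-3), 0.0)
        b = StiffnessCurve(b.breakpoints, np.maximum(b.slopes, 1e-3), 0.0)
        comp = series_compose(a, b)
        d1 = brentq(lambda u: a.force(u) - b.force(d - u), 0.0, d, xtol=1e-14)
        assert comp.force(d) == pytest.approx(a.force(d1), rel=1e-8, abs=1e-10)

    def test_zero_element_blocks_force(self):
        z = StiffnessCurve.zero()
        k = StiffnessCurve.linear(100.0)
        comp = series_compose(z, k)
        assert comp.force(0.5) == 0.0
        assert comp.max_force == 0.0

    def test_equal_linear_springs(self):
        k = StiffnessCurve.linear(10.0)
        comp = series_compose(k, k)
        assert comp.force(1.0) == pytest.approx(5.0)


class TestViscoelasticElement:
    def test_validation(self, skin_tangential):
        with pytest.raises(ValueError):
            ViscoelasticElement(skin_tangential, skin_tangential, -1.0, 0.0, 0.001)
        with pytest.raises(ValueError):
            ViscoelasticElement(skin_tangential, skin_tangential, 0.0, 0.0, 0.0)

    def test_displacement_law_scaling(self, skin_tangential):
        el = ViscoelasticElement(
            skin_tangential, skin_tangential, rest_thickness=0.004, force_scale=100.0
        )
        law = el.normal_law()
        # strain 0.2 = 0.8 mm compression; force = 100 * stress(0.2)
        assert law.force(0.0008) == pytest.approx(100.0 * 0.02)


class TestMaterialTable:
    def test_round_trip(self, tmp_path):
        table = default_material_table()
        path = tmp_path / "materials.csv"
        table.to_csv(path, index=False)
        loaded = load_material_table(path)
        curves = curves_from_table(loaded)
        assert ("skin", "tangential") in curves
        assert curves[("skin", "tangential")].force(0.5) == pytest.approx(1.92, rel=1e-2)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("material,slope\nskin,0.1\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_material_table(path)
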