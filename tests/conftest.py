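import pytest
from hypothesis import settings, HealthCheck

# deterministic property tests
settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def skin_tangential():
    """The literature tensile skin law: 0.1 MPa to strain 0.4, then 18.8 MPa."""
    from hurosim.materials import StiffnessCurve

    return StiffnessCurve([0.0, 0.4], [0.1, 18.8])


@pytest.fixture()
def default_curves():
    from hurosim.materials import curves_from_table, default_material_table

    return curves_from_table(default_material_table())


@pytest.fixture(scope="session")
def hand_system():
    """One default hand scenario system shared (read-only) per session."""
    from hurosim.hand import build_hand_system

    return build_hand_system()
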