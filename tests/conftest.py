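import pytest
from hypothesis import HealthCheck, settings

from anchalign import FixedScoring, AffineScoring, MemoryBackend, SQLiteBackend

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # scheme fixtures are frozen dataclasses, safe to share across inputs
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def fixed_scheme():
    return FixedScoring(1, -1, -2)


@pytest.fixture
def affine_scheme():
    return AffineScoring(1, -1, -3, -1)


@pytest.fixture(params=["memory", "sqlite"])
def backend_factory(request):
    """Both storage backends must behave identically."""
    if request.param == "memory":
        return MemoryBackend
    return lambda: SQLiteBackend(":memory:")
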