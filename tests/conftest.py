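import pytest
from hypothesis import HealthCheck, settings

from t2dproj.models import BaselineEstimate, baseline_state, make_model

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: England adult (18+) population, ONS mid-2015 estimate, millions.
ADULT_POPULATION = 42.9


@pytest.fixture(scope="session")
def documented_baseline() -> BaselineEstimate:
    """2015 starting point: diabetes 3.81M, IH 5.05M, NG the residual."""
    return BaselineEstimate(
        diabetes_total=3.81, ih_total=5.05, adult_population=ADULT_POPULATION
    )


@pytest.fixture(scope="session")
def baseline_vector(documented_baseline):
    return baseline_state(documented_baseline)


@pytest.fixture(scope="session", params=["model1", "model2", "model3"])
def builtin_spec(request):
    return make_model(request.param)
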