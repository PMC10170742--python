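import pytest
from hypothesis import HealthCheck, settings

from uwcager.regression import WoundModelFit

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: The published Moorea healing-curve coefficients, used as a reference fit.
REFERENCE_COEFFS = dict(a0=0.311, a1=0.053, b0=1.299, b1=0.037)


@pytest.fixture(scope="session")
def reference_fit() -> WoundModelFit:
    return WoundModelFit(
        **REFERENCE_COEFFS,
        var_id_area=0.0, var_id_perim=0.0,
        var_eps_area=0.0, var_eps_perim=0.0,
        n_individuals=16, n_observations=35,
    )


@pytest.fixture(scope="session")
def reference_scheme(reference_fit):
    from uwcager.classify import derive_scheme

    return derive_scheme(reference_fit)
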