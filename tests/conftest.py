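import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def graded_phantom():
    """Default radially graded phantom (core 4.5, rim 1.0, r=20 mm, 2 mm voxels)."""
    from metavol import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def homogeneous_phantom():
    """Homogeneous lesion, SUV 5, radius 10 mm (volume 4.19 mL)."""
    from metavol import PhantomSpec, generate_phantom

    spec = PhantomSpec(
        lesion_radii_mm=(10.0, 10.0, 10.0), suv_core=5.0, suv_rim=5.0
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def simulated_cohort():
    from metavol import CohortGenParams, generate_cohort

    return generate_cohort(CohortGenParams(n=300, seed=1))


@pytest.fixture(scope="session")
def reference_cohort():
    from metavol import reference_cohort

    return reference_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def null_cohort_params():
    """Factory for generator parameters with no marker-outcome effects."""
    from metavol import CohortGenParams

    def make(n, seed, p_death=0.3):
        b0 = float(np.log(p_death / (1 - p_death)))
        return CohortGenParams(
            n=n, seed=seed, beta0_death=b0, beta_suvliver=0.0, beta_hi2=0.0,
            beta_ldh=0.0, beta0_relapse=b0, beta_ldh_relapse=0.0,
            beta_suvliver_relapse=0.0, beta_hi2_relapse=0.0,
        )

    return make
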