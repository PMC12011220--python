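import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        max_examples=60,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass

from akdscreen.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort_5k():
    """One noisy default cohort shared by the slower cohort-level tests."""
    return generate_cohort(CohortConfig(n_patients=5000, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort_2k():
    """Noise-free cohort with pre-admission baselines always documented."""
    return generate_cohort(
        CohortConfig(
            n_patients=2000, seed=3, poc_cv=0.0, lab_cv=0.0, pre_admission_prob=1.0
        )
    )
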