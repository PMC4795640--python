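import numpy as np
import pytest

from mews_triage import CohortParams, default_bands, generate_cohort, reference_cohort
from mews_triage.scoring import score_frame


@pytest.fixture(scope="session")
def bands():
    return default_bands()


@pytest.fixture(scope="session")
def ref():
    """Deterministic reconstruction of the published study margins (n=452)."""
    return reference_cohort()


@pytest.fixture(scope="session")
def scored_50k():
    """One large default-parameter cohort, scored, shared across tests."""
    cohort = generate_cohort(CohortParams(n=50_000, seed=2024))
    return score_frame(cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A small scored cohort for brute-force oracles."""
    cohort = generate_cohort(CohortParams(n=48, seed=7))
    return score_frame(cohort)
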