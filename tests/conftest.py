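import numpy as np
import pytest

from myocat import SimulationConfig, generate_cohort

# Published internal/external validation counts used across tests:
# per-category decision counts (0,1,2,3) for the gold standard and each
# comparator, plus the diagonal agreement count and cohort size.
INTERNAL_GOLD = (1, 95, 5, 6)
EXTERNAL_GOLD = (15, 38, 0, 2)
PUBLISHED_AGREEMENT = {
    # name: (gold marginals, comparator marginals, agree, n, kappa, consistency_pct)
    "ai_internal": (INTERNAL_GOLD, (1, 96, 2, 8), 103, 107, 0.811, 96.26),
    "senior_internal": (INTERNAL_GOLD, (8, 87, 6, 6), 96, 107, 0.622, 89.72),
    "junior_internal": (INTERNAL_GOLD, (8, 87, 6, 6), 96, 107, 0.622, 89.72),
    "resident_internal": (INTERNAL_GOLD, (0, 91, 9, 7), 93, 107, 0.449, 86.92),
    "ai_external": (EXTERNAL_GOLD, (7, 44, 0, 4), 45, 55, 0.556, 81.82),
    "senior_external": (EXTERNAL_GOLD, (17, 33, 3, 2), 45, 55, 0.636, 81.82),
    "junior_external": (EXTERNAL_GOLD, (17, 33, 3, 2), 45, 55, 0.636, 81.82),
    "resident_external": (EXTERNAL_GOLD, (6, 43, 0, 6), 39, 55, 0.317, 70.91),
}


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort for pipeline-level tests."""
    return generate_cohort(SimulationConfig(n=150, seed=11))


@pytest.fixture(scope="session")
def large_calibrated_cohort():
    """10,000-eye cohort at the calibrated error scales, with one
    error-free rater, shared by the heavier distribution checks."""
    cfg = SimulationConfig(
        n=10_000,
        seed=20260928,
        sigma_pred=0.1955,
        rater_confusion={"perfect": np.eye(4)},
    )
    return generate_cohort(cfg)
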