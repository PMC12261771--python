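"""Session-scoped cohort fixtures shared across the suite.

Cohort sizes balance statistical power against the runtime of the
default test run: 60 drifted patients give ~120 test-set rows for the
effect-recovery checks, and 120 zero-drift patients give the null
calibration enough test patients that chance AUC concentrates well
inside [0.4, 0.6].
"""

import warnings

import pytest

from preshock.pipeline import run_all
from preshock.simulate import NULL_DRIFT, SimulationConfig

DRIFT_SEED = 20250923
NULL_SEED = 20250924
N_DRIFT = 60
N_NULL = 120


@pytest.fixture(scope="session")
def drift_run():
    """Full pipeline on a seeded cohort with the default pre-shock drift."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, result = run_all(SimulationConfig(n_patients=N_DRIFT, seed=DRIFT_SEED),
                                 n_boot=300)
    return cohort, result


@pytest.fixture(scope="session")
def null_run():
    """Full pipeline on a seeded zero-drift cohort (exchangeable windows)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, result = run_all(
            SimulationConfig(n_patients=N_NULL, seed=NULL_SEED, drift=NULL_DRIFT),
            n_boot=300)
    return cohort, result
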