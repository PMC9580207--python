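import numpy as np
import pytest

from mirsel import ExpressionCohort, SimulationConfig, SurvivalRecords, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast cohort: 62 samples × 40 features, strong planted structure."""
    return SimulationConfig(
        n_per_subtype=(16, 12, 10, 12, 12),
        n_features=40,
        informative_per_subtype=3,
        n_multisubtype_features=4,
        effect_size=2.0,
        noise_sd=1.0,
        n_prognostic=3,
        prognostic_beta=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = generate_cohort(small_config)
    return cohort, truth


def make_cohort(
    values: np.ndarray,
    labels: np.ndarray,
    time: np.ndarray | None = None,
    event: np.ndarray | None = None,
    log_scale: bool = True,
) -> ExpressionCohort:
    """Hand-built cohort with auto-generated IDs."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    survival = None
    if time is not None:
        survival = SurvivalRecords(time=np.asarray(time), event=np.asarray(event))
    return ExpressionCohort(
        sample_ids=[f"S{i}" for i in range(n)],
        feature_ids=[f"g{k}" for k in range(p)],
        values=values,
        labels=np.asarray(labels, dtype=int),
        survival=survival,
        log_scale=log_scale,
    )
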