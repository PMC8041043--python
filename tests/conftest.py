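import numpy as np
import pandas as pd
import pytest

from ebmflow import CohortTable, PipelineConfig, SyntheticConfig, generate_cohort
from ebmflow.simulate import default_recovery_config


def small_cohort_frame() -> pd.DataFrame:
    """Hand-written 6-subject cohort with two markers."""
    return pd.DataFrame({
        "subject_id": ["c1", "c2", "c3", "p1", "p2", "p3"],
        "group": ["control"] * 3 + ["patient"] * 3,
        "age": [60.0, 65.0, 70.0, 62.0, 68.0, 74.0],
        "gender": ["female", "male", "female", "male", "female", "male"],
        "education": [12.0, 16.0, 14.0, 12.0, 18.0, 10.0],
        "age_at_onset": [np.nan, np.nan, np.nan, 55.0, 70.1, 64.99],
        "rbdsq": [1, 4, 5, 9, 2, 3],
        "moca": [29.0, 28.0, 28.5, 27.0, 24.0, 25.5],
        "qsm_iron": [0.1, 0.2, 0.15, 0.6, 0.9, 0.7],
    })


@pytest.fixture
def small_cohort() -> CohortTable:
    return CohortTable(
        small_cohort_frame(),
        {"moca": "clinical_cognitive", "qsm_iron": "qsm"},
    )


@pytest.fixture
def small_config() -> PipelineConfig:
    return PipelineConfig(
        modality_of={"moca": "clinical_cognitive", "qsm_iron": "qsm"},
        excluded_markers=[],
    )


@pytest.fixture(scope="session")
def tiny_synthetic():
    """5-event strong-signal cohort with ground truth (session-cached)."""
    cfg = SyntheticConfig(
        events_per_modality={"clinical_cognitive": 3, "qsm": 2},
        n_controls=25, n_pdd_lr=25, n_pdd_hr=20,
        effect_size=4.0, missingness=0.0, seed=11,
    )
    cfg.true_sequence = np.random.default_rng(11).permutation(5)
    return generate_cohort(cfg, 11)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Default 20-event recovery cohort (133 subjects, d = 2)."""
    cfg = default_recovery_config(0)
    return generate_cohort(cfg, 0)


@pytest.fixture(scope="session")
def fitted_tiny(tiny_synthetic):
    """Full pipeline fit on the 5-event cohort, modest sampler settings."""
    from ebmflow import fit_pipeline

    table, truth = tiny_synthetic
    cfg = PipelineConfig(
        modality_of=table.modality_of, mcmc_iterations=5000,
        greedy_restarts=3, screened_modalities=[], excluded_markers=[],
    )
    return fit_pipeline(table, cfg, seed=5), truth, cfg
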