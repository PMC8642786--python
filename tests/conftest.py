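import numpy as np
import pandas as pd
import pytest

from mirstage import (
    CountMatrix,
    SampleAnnotation,
    SimulationConfig,
    nb_wald_test,
    prepare_counts,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_config():
    """A reduced twin-cohort configuration used by the faster tests."""
    return SimulationConfig(
        seed=11,
        n_samples_per_cohort=60,
        prevalence_stage1=0.35,
        n_mirna=300,
        n_mrna=200,
        n_planted_mirna=8,
        planted_fold_changes=(2.0, 2.2, 2.5, 3.0, 1.9, 2.8, 3.5, 2.1),
        n_planted_pairs=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, "discovery")


@pytest.fixture(scope="session")
def study_scale_cohorts():
    """Twin cohorts at study scale (127 samples, 1426 miRNAs, 19 planted)."""
    config = SimulationConfig(seed=23)
    return {
        "config": config,
        "discovery": simulate_cohort(config, "discovery"),
        "validation": simulate_cohort(config, "validation"),
    }


@pytest.fixture(scope="session")
def small_de(small_cohort):
    counts, _, annotation, _ = small_cohort
    filtered, sf = prepare_counts(counts)
    return nb_wald_test(filtered, annotation, sf, cohort_tag="discovery")


def make_counts(array, feature_ids=None, sample_ids=None) -> CountMatrix:
    array = np.asarray(array)
    feature_ids = feature_ids or [f"f{i}" for i in range(array.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(array.shape[1])]
    return CountMatrix(pd.DataFrame(array, index=feature_ids, columns=sample_ids))


def make_annotation(stages, sample_ids=None, cohort="c") -> SampleAnnotation:
    sample_ids = sample_ids or [f"s{j}" for j in range(len(stages))]
    return SampleAnnotation(
        pd.DataFrame(
            {"cohort": cohort, "stage": list(stages)},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
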