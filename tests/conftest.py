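import numpy as np
import pytest

from olfica import CohortSpec, canonical_hrf, generate_cohort


@pytest.fixture(scope="session")
def hrf10():
    return canonical_hrf(10.0, 2.0)


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale cohort: 6 subjects, reduced schedule, 5 task networks."""
    return CohortSpec(
        n_subjects=6,
        reps_per_run=2,
        n_components=5,
        n_task_components=5,
        base_hit_amplitudes=(1.0, 0.9, 0.9, 0.8, 0.8),
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, seed=11)


@pytest.fixture(scope="session")
def small_cohort_matrices(small_cohort):
    """Per-subject frames x mask-voxels matrices (unsmoothed)."""
    mask = small_cohort.ground_truth.analysis_mask
    return [
        np.vstack([b.data[mask].T for b in runs]) for runs in small_cohort.bold
    ], mask
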