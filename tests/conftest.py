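import numpy as np
import pytest

from restconn import preprocess, synth


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 4+4-subject cohort with 3 networks for unit tests."""
    cfg = synth.CohortConfig(n_per_group=4, grid=(12, 12, 6), n_volumes=90,
                             n_networks=3, effect_networks=(0,),
                             coupling_patients=np.array([[0.3, 0, 0.2],
                                                         [0, 0.3, 0],
                                                         [0, 0, 0.3]]),
                             coupling_controls=np.array([[0.3, 0, 0.5],
                                                         [0, 0.3, 0],
                                                         [0, 0, 0.3]]),
                             seed=7)
    runs, truth = synth.generate_cohort(cfg)
    return cfg, runs, truth


@pytest.fixture(scope="session")
def standardized_cohort(small_cohort):
    cfg, runs, truth = small_cohort
    std = [preprocess.standardize_timecourses(r) for r in runs]
    mask = np.logical_and.reduce([r.mask for r in std])
    std = [preprocess._replace_data(r, r.data, mask) for r in std]
    return cfg, std, truth, mask
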