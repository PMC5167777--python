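import numpy as np
import pytest

from netseg import (CohortSimConfig, default_sources, make_grid,
                    make_templates, simulate_cohort)


@pytest.fixture(scope="session")
def grid24():
    return make_grid()


@pytest.fixture(scope="session")
def templates24(grid24):
    return make_templates(grid24)


@pytest.fixture(scope="session")
def grid16():
    return make_grid((16, 18, 16))


@pytest.fixture(scope="session")
def small_cohort(grid16):
    """4 subjects, 3 clean sources, no noise/jitter: exact-recovery regime."""
    sources = default_sources(grid16, n_background=0)
    cfg = CohortSimConfig(n_subjects=4, n_timepoints=80, noise_sd=0.0,
                          jitter_sd_voxels=0.0, baseline=0.0,
                          tc_corr=(), seed=11)
    cohort, truth = simulate_cohort(grid16, sources, cfg)
    return cohort, truth


def matched_abs_corr(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Best one-to-one |Pearson r| assignment between two map sets."""
    from scipy.optimize import linear_sum_assignment

    rs = np.abs(np.corrcoef(maps_a, maps_b)[:len(maps_a), len(maps_a):])
    ri, ci = linear_sum_assignment(-rs)
    return rs[ri, ci]
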