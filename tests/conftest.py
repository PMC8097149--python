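"""Shared fixtures: fast small-grid configurations and rendered phantoms."""

import dataclasses

import numpy as np
import pytest

from vrsquant.cohort import CohortConfig, GroupParams, render_subject, sample_cohort
from vrsquant.pipeline import RunConfig


def make_small_config(
    n_sfs: int = 3,
    n_epi: int = 3,
    n_ctl: int = 3,
    count: tuple[float, float] = (40.0, 8.0),
    noise_sigma: float = 4.0,
) -> CohortConfig:
    """A shrunken phantom (128 x 128 x 24) for fast unit tests.

    Same spacing and tissue model as the study-scale default, smaller
    anatomy and burdens.
    """

    def mk(**kw) -> GroupParams:
        return GroupParams(
            count_mean=count[0],
            count_sd=count[1],
            volume_mean=count[0] * 14.0,
            volume_sd=count[0] * 1.5,
            bv_mean=228e3,
            bv_sd=12e3,
            wmv_mean=73e3,
            wmv_sd=5e3,
            age_mean=27.0,
            age_sd=12.0,
            ga_mean=39.3,
            ga_sd=1.2,
            male_frac=0.6,
            **kw,
        )

    groups = {
        "SFS": mk(
            n=n_sfs,
            duration_mean=2.54,
            duration_sd=1.45,
            course_mean=3.69,
            course_sd=1.38,
            r_duration_count=0.807,
            r_course_count=-0.964,
            r_duration_course=-0.78,
        ),
        "epilepsy": mk(
            n=n_epi,
            duration_mean=5.61,
            duration_sd=2.59,
            course_mean=3.42,
            course_sd=1.43,
            r_duration_count=0.766,
            r_course_count=-0.947,
            r_duration_course=-0.73,
        ),
        "control": mk(n=n_ctl),
    }
    return CohortConfig(
        groups=groups,
        grid_shape=(128, 128, 24),
        noise_sigma=noise_sigma,
        brain_axes_mm=(36.0, 42.0, 36.0),
        gm_axes_mm=(34.5, 40.5, 34.0),
        wm_axes_mm=(33.0, 39.0, 14.0),
        ventricle_axes_mm=(4.0, 9.0, 7.0),
        ventricle_offset_mm=(8.0, 0.0, -10.0),
    )


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return make_small_config()


@pytest.fixture(scope="session")
def small_run_config(small_config) -> RunConfig:
    return RunConfig(cohort=small_config, seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sample_cohort(small_config, seed=0)


@pytest.fixture(scope="session")
def rendered_subject(small_config, small_cohort):
    """One rendered SFS phantom (volume, ground-truth masks, tubules)."""
    record = small_cohort[0]
    vol, masks, tubules = render_subject(record, small_config, seed=(0, 0))
    return record, vol, masks, tubules


@pytest.fixture(scope="session")
def noisefree_subject(small_cohort, small_config):
    """Same subject rendered without noise."""
    cfg = dataclasses.replace(small_config, noise_sigma=0.0)
    record = small_cohort[0]
    vol, masks, tubules = render_subject(record, cfg, seed=(0, 0))
    return record, vol, masks, tubules


def tubule_mask(shape, tubules) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for t in tubules:
        mask[t.voxels[:, 0], t.voxels[:, 1], t.start[2]] = True
    return mask
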