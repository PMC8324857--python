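import numpy as np
import pytest

from icnsmap.synthetic import (
    make_template_heart,
    male_profile,
    female_profile,
    validation_profile,
    make_subject,
    sample_icns,
)


@pytest.fixture(scope="session")
def template():
    return make_template_heart()


@pytest.fixture(scope="session")
def small_markers(template):
    """A small fixed ICNS point cloud (validation profile, seed 11)."""
    markers, gt = sample_icns(template, validation_profile(), 11)
    return markers, gt


@pytest.fixture(scope="session")
def small_subject(template):
    """One complete synthetic subject with contours (seed 11)."""
    subject, gt = make_subject(template, validation_profile(), 11)
    return subject, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
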