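import numpy as np
import pytest

from wsilink import TissuePhantomParams, generate_cohort_manifest

# Small phantoms for unit tests; full-size cohorts (session-scoped, generated
# once) for the end-to-end trend checks.

SMALL_PARAMS = TissuePhantomParams(side=128)


@pytest.fixture(scope="session")
def small_params():
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def small_cohort():
    """8 patients x 3 slides at 128 px, for fast end-to-end unit tests."""
    return generate_cohort_manifest(8, 3, (3.0, 5.0), SMALL_PARAMS, seed=101)


@pytest.fixture(scope="session")
def block_cohort():
    """80 patients x 7 serial sections at 3-5 mm spacing (full scale)."""
    return generate_cohort_manifest(80, 7, (3.0, 5.0), seed=424242)


@pytest.fixture(scope="session")
def rescan_cohort():
    """28 patients, one slide each plus one rescan (different scanner)."""
    return generate_cohort_manifest(28, 1, (3.0, 5.0), seed=77, rescans_per_slide=1)


@pytest.fixture(scope="session")
def pair_cohort():
    """28 patients with directly consecutive section pairs."""
    return generate_cohort_manifest(28, 2, (3.0, 5.0), seed=78)
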