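import numpy as np
import pytest

from zfmorph.atlas import make_atlas
from zfmorph.simulate import CohortDesign, GroupSpec, make_cohort


@pytest.fixture(scope="session")
def atlas48():
    return make_atlas((48, 48, 48), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def atlas32():
    return make_atlas((32, 32, 32), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def small_effect_cohort(atlas32):
    """Tiny control-vs-crispant cohort on the 32^3 atlas (fast path for units)."""
    design = CohortDesign(
        groups=[GroupSpec("ctl", "b1", 5, 1.0), GroupSpec("xrcc", "b1", 5, 0.9)],
        shape=(32, 32, 32),
        truth_volumes=False,
        channels={"mcar": {"brain": 100.0}},
        seed=11,
    )
    return make_cohort(design, atlas32)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
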