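import numpy as np
import pytest

from digicms import synthetic, tripletmil


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-size study conditions for fast unit tests (not the acceptance runs)."""
    return synthetic.SyntheticSpec(
        n_patients_per_class=8, patches_per_bag=(6, 12), seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return synthetic.generate_cohort(small_spec, cohort_id="unit")


@pytest.fixture(scope="session")
def small_bags(small_cohort):
    return tripletmil.bags_from_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
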