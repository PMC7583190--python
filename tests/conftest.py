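import warnings

import pytest

from synpd.synthetic import (
    SyntheticSpec,
    generate_cycle_data,
    generate_growth_data,
    generate_protein_profiles,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def spec():
    """Default synthetic study conditions (fitted estimates as truth)."""
    return SyntheticSpec(seed=101)


@pytest.fixture(scope="session")
def growth_table_clean(spec):
    return generate_growth_data(spec, noise=False)


@pytest.fixture(scope="session")
def protein_profiles_clean(spec):
    return generate_protein_profiles(spec, noise=False)


@pytest.fixture(scope="session")
def cycle_table_clean(spec):
    return generate_cycle_data(spec, noise=False)
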