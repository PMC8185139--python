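import numpy as np
import pytest

import gazegraph as gg


@pytest.fixture(scope="session")
def group_specs():
    return gg.default_group_specs()


@pytest.fixture(scope="session")
def tiny_cohort(group_specs):
    """4 + 4 subjects with short (24 s) recordings: 6 segments each."""
    spec_a, spec_b = group_specs
    return gg.simulate_dataset(spec_a, spec_b, 4, 4, seed=11, duration_s=24.0)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return gg.extract_cohort_features(tiny_cohort)
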