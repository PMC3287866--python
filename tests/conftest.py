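import numpy as np
import pytest

from famqls import (
    Individual,
    Pedigree,
    Sex,
    compute_kinship,
    gaw17_like_scenario,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("F1", "A", sex=Sex.MALE),
            Individual("F1", "B", sex=Sex.FEMALE),
            Individual("F1", "C", "A", "B", Sex.MALE),
        ]
    )


@pytest.fixture(scope="session")
def bundle():
    """The canned 8-family scenario at its default seed, 200 replicates."""
    return gaw17_like_scenario(seed=0, n_replicates=200)


@pytest.fixture(scope="session")
def bundle_kinship(bundle):
    kin = compute_kinship(bundle.pedigree)
    kin.assert_positive_definite()
    return kin
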