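import pytest

import asymu


@pytest.fixture(scope="session")
def ex1_study():
    return asymu.load_fixture("thiamphenicol_milk")


@pytest.fixture(scope="session")
def ex2_study():
    return asymu.load_fixture("clopidol_egg")


@pytest.fixture(scope="session")
def ex1_results(ex1_study):
    """REML fit of the thiamphenicol-in-milk study (shared; fitting is deterministic)."""
    return asymu.UncertaintyModel(ex1_study).fit()


@pytest.fixture(scope="session")
def ex2_results(ex2_study):
    return asymu.UncertaintyModel(ex2_study).fit()


@pytest.fixture(scope="session")
def ex1_reference_profile():
    """Precision profile built from the published Example-1 variance components."""
    return asymu.PrecisionProfile(asymu.load_reference_components("thiamphenicol_milk"))


@pytest.fixture(scope="session")
def ex2_reference_profile():
    return asymu.PrecisionProfile(asymu.load_reference_components("clopidol_egg"))
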