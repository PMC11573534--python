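import warnings

import pytest
from hypothesis import HealthCheck, settings

import ptcquant as pq

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(autouse=True)
def _quiet_diagnostic_warnings():
    """Site-variant cleavage-pattern warnings are expected throughout."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*different cleavage patterns.*", category=UserWarning
        )
        yield


@pytest.fixture(scope="session")
def tga129_construct():
    return pq.p53_sbp_construct("TGA129")


@pytest.fixture(scope="session")
def tga129_site(tga129_construct):
    return tga129_construct.site("TGA129")


@pytest.fixture(scope="session")
def tga129_database(tga129_construct, tga129_site):
    """All-20 substitutions plus the stop-skip proteoform (21 records)."""
    subs = pq.enumerate_substitution_proteoforms(tga129_construct, tga129_site)
    skip = pq.enumerate_skip_proteoform(tga129_construct, tga129_site)
    return subs + [skip]


@pytest.fixture(scope="session")
def tga129_index(tga129_database):
    """Target+decoy peptide index at default search settings, built once."""
    config = pq.SearchConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        decoys = pq.make_decoys(tga129_database, mode=config.decoy_mode)
        return pq.PeptideIndex(tga129_database, decoys, config)
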