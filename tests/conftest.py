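import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fa_profiles():
    """Published FA profiles keyed by sample id (e.g. 'CA-7-16')."""
    from oilcascade import load_fixture_fatty_acids

    return {p.sample_id: p for p in load_fixture_fatty_acids()}


@pytest.fixture(scope="session")
def tpc_by_treatment():
    """Published TPC series keyed by treatment name."""
    from oilcascade import load_fixture_tpc

    return {s.treatment: s for s in load_fixture_tpc()}
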