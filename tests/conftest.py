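import pytest
from hypothesis import HealthCheck, settings

import splicelens as sl

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mshlike_gene() -> sl.GeneModel:
    return sl.make_toy_gene(sl.mshlike_spec(seed=17))


@pytest.fixture(scope="session")
def matrix() -> sl.ScoreMatrix:
    return sl.ScoreMatrix.default()


@pytest.fixture(scope="session")
def bundle() -> sl.FixtureBundle:
    return sl.make_clinical_fixtures(seed=17)


@pytest.fixture(scope="session")
def mshlike_report(mshlike_gene, bundle) -> dict:
    return sl.run_pipeline(
        mshlike_gene,
        "c.793-1G>A",
        construct=bundle.construct,
        clinical_inputs={
            "msi_calls": bundle.msi_calls,
            "ihc": bundle.ihc_patterns,
            "pedigree": bundle.pedigree,
        },
    )
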