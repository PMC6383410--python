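import pytest
from hypothesis import HealthCheck, settings

from litscape.corpus import Corpus, PublicationRecord
from litscape.geo import default_gazetteer
from litscape.synthetic import SyntheticSpec, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_record(pub_id, year=2000, affiliations=(), genes=(), countries=None,
                cities=None):
    return PublicationRecord(pub_id=str(pub_id), year=year,
                             affiliations=list(affiliations), genes=list(genes),
                             countries=countries, cities=cities)


def make_corpus(records):
    return Corpus(list(records))


@pytest.fixture(scope="session")
def gazetteer():
    return default_gazetteer()


@pytest.fixture(scope="session")
def synthetic_small():
    """A 120-record synthetic corpus with its ground truth (deterministic)."""
    return generate(SyntheticSpec(n_pubs=120, seed=7))


@pytest.fixture(scope="session")
def synthetic_annotated(gazetteer):
    """A geocoded 400-record synthetic corpus with a visible Finnish presence."""
    from litscape.geo import annotate_corpus

    spec = SyntheticSpec(n_pubs=400, seed=11)
    spec.country_weights = {"United States": 0.5, "Finland": 0.3, "Germany": 0.2}
    corpus, truth = generate(spec)
    annotate_corpus(corpus, default_gazetteer(), focal_country="Finland")
    return corpus, truth
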