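import pytest

from biocurate import demo, fixtures


@pytest.fixture
def demo_articles():
    return demo.demo_articles()


@pytest.fixture
def demo_diseases():
    return demo.demo_diseases()


@pytest.fixture
def demo_biomodels():
    return demo.demo_biomodels()


@pytest.fixture
def demo_cases():
    return demo.demo_cases()


@pytest.fixture
def pubmed_document(demo_articles):
    return fixtures.generate(
        fixtures.FixtureSpec(kind="pubmed-xml", records=tuple(demo_articles))
    )


@pytest.fixture
def malacards_document(demo_diseases):
    return fixtures.generate(
        fixtures.FixtureSpec(kind="malacards-html", records=tuple(demo_diseases))
    )


@pytest.fixture
def clinical_document(demo_cases):
    return fixtures.generate(
        fixtures.FixtureSpec(kind="aneurisk-csv", records=tuple(demo_cases))
    )


@pytest.fixture
def store_path(tmp_path):
    return str(tmp_path / "entities.db")
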