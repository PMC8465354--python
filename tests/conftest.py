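import pytest

from ethnoindex.data_model import (
    Community,
    DatasetLevel,
    Education,
    Gender,
    Informant,
    LifeForm,
    PlantPart,
    Preparation,
    Nativity,
    SurveyDataset,
    TaxonRecord,
    UseReport,
)
from ethnoindex.fixtures import load_fixture
from ethnoindex.synthetic import GeneratorConfig, KnowledgeModel, generate_survey


def make_taxon(taxon_id, family="Asteraceae", life_form=LifeForm.HERB,
               part=PlantPart.LEAF, preparation=Preparation.POWDER,
               nativity=Nativity.NATIVE, **kw):
    return TaxonRecord(
        taxon_id=taxon_id,
        botanical_name=kw.pop("botanical_name", taxon_id.replace("_", " ").title()),
        family=family, life_form=life_form, parts_used=frozenset({part}),
        preparation=preparation, nativity=nativity, **kw,
    )


def make_informant(informant_id, age=45, gender=Gender.M,
                   education=Education.MIDDLE, community=Community.KASHMIRI,
                   village="Alpha"):
    return Informant(informant_id=informant_id, age=age, gender=gender,
                     education=education, community=community, village=village)


@pytest.fixture(scope="session")
def fixture_bundle():
    return load_fixture()


@pytest.fixture(scope="session")
def paper_dataset(fixture_bundle):
    return fixture_bundle.dataset


@pytest.fixture
def tiny_dataset():
    """3 informants each reporting taxon A once for GAS."""
    taxa = (make_taxon("a"), make_taxon("b", family="Rosaceae"))
    informants = tuple(make_informant(f"i{k}") for k in range(1, 4))
    reports = tuple(
        UseReport(informant_id=f"i{k}", taxon_id="a", ailment="diarrhea",
                  category="GAS", village="Alpha")
        for k in range(1, 4)
    )
    return SurveyDataset(taxa=taxa, reports=reports, informants=informants,
                         level=DatasetLevel.INFORMANT_LEVEL)


@pytest.fixture(scope="session")
def synthetic_dataset():
    cfg = GeneratorConfig(seed=11, n_informants=50, n_taxa=30, n_families=8)
    return generate_survey(cfg)


@pytest.fixture(scope="session")
def synthetic_config():
    return GeneratorConfig(seed=11, n_informants=50, n_taxa=30, n_families=8)
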