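import os

import pytest
from hypothesis import given, settings, strategies as st

from ethnoindex.data_model import (
    Community,
    DatasetLevel,
    Education,
    Gender,
    Informant,
    LifeForm,
    Nativity,
    PlantPart,
    Preparation,
    ReferentialIntegrityError,
    Route,
    SchemaError,
    SurveyDataset,
    TaxonRecord,
    UniquenessError,
    UseReport,
    aggregate,
    parse_enum,
    read_survey,
    round_half_up,
    validate_consistency,
    write_survey,
)

from conftest import make_informant, make_taxon


class TestEnumParsing:
    @pytest.mark.parametrize("cls,token,expected", [
        (LifeForm, "H", LifeForm.HERB),
        (LifeForm, " herb ", LifeForm.HERB),
        (LifeForm, "TREE", LifeForm.TREE),
        (PlantPart, "Wp", PlantPart.WHOLE_PLANT),
        (PlantPart, "Lv", PlantPart.LEAF),
        (PlantPart, "St", PlantPart.SHOOT),
        (Preparation, "Juice/extract", Preparation.JUICE_EXTRACT),
        (Preparation, "Chew/Roasted", Preparation.CHEW),
        (Nativity, "N", Nativity.NATIVE),
        (Nativity, "e", Nativity.EXOTIC),
        (Education, "Senior Secondary", Education.SENIOR_SECONDARY),
        (Education, "Matriculation", Education.MATRIC),
        (Gender, "female", Gender.F),
        (Route, "smoke", Route.SMOKE_INHALATION),
    ])
    def test_accepts_table_dialects(self, cls, token, expected):
        assert parse_enum(cls, token) is expected

    def test_unknown_token_rejected(self):
        with pytest.raises(SchemaError, match="LifeForm"):
            parse_enum(LifeForm, "cactus")

    def test_education_is_ordered(self):
        assert Education.ILLITERATE < Education.PRIMARY < Education.POSTGRADUATE


class TestValidation:
    def test_age_bounds(self):
        with pytest.raises(SchemaError, match="age"):
            make_informant("x", age=12)
        make_informant("x", age=21)  # survey range is fine

    def test_duplicate_informants_rejected(self):
        with pytest.raises(UniquenessError, match="informant_id"):
            SurveyDataset(taxa=(), reports=(),
                          informants=(make_informant("i1"), make_informant("i1")))

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(UniquenessError, match="taxon_id"):
            SurveyDataset(taxa=(make_taxon("a"), make_taxon("a")), reports=())

    def test_dangling_taxon_lists_rows(self):
        with pytest.raises(ReferentialIntegrityError, match=r"\(1, 'tX'\)"):
            SurveyDataset(
                taxa=(make_taxon("a"),),
                reports=(UseReport(informant_id="i1", taxon_id="tX"),),
                informants=(make_informant("i1"),),
            )

    def test_informant_level_requires_count_one(self):
        with pytest.raises(SchemaError, match="count=1"):
            SurveyDataset(
                taxa=(make_taxon("a"),),
                reports=(UseReport(informant_id="i1", taxon_id="a", count=2),),
                informants=(make_informant("i1"),),
            )

    def test_aggregate_requires_n_informants(self):
        with pytest.raises(SchemaError, match="n_informants"):
            SurveyDataset(taxa=(make_taxon("a"),), reports=(),
                          level=DatasetLevel.AGGREGATE)

    def test_empty_parts_rejected(self):
        with pytest.raises(SchemaError, match="parts_used"):
            TaxonRecord(taxon_id="a", botanical_name="A", family="F",
                        life_form=LifeForm.HERB, parts_used=frozenset(),
                        preparation=Preparation.POWDER)

    def test_bad_category_code_rejected(self):
        with pytest.raises(SchemaError, match="category"):
            UseReport(taxon_id="a", category="XXX")


class TestAggregate:
    def test_three_informants_one_row(self, tiny_dataset):
        agg = aggregate(tiny_dataset)
        assert agg.level is DatasetLevel.AGGREGATE
        rows = [r for r in agg.reports if r.taxon_id == "a"]
        assert len(rows) == 1
        assert rows[0].count == 3
        assert rows[0].category == "GAS"
        assert agg.n_informants == 3

    def test_total_conserved_on_synthetic(self, synthetic_dataset):
        agg = aggregate(synthetic_dataset)
        # oracle: brute-force recount of informant-level rows
        assert agg.total_use_reports == len(synthetic_dataset.reports)

    def test_village_stratification_matches_recount(self, synthetic_dataset):
        agg = aggregate(synthetic_dataset)
        for village in {r.village for r in synthetic_dataset.reports}:
            brute = sum(1 for r in synthetic_dataset.reports
                        if r.village == village)
            got = sum(r.count for r in agg.reports if r.village == village)
            assert got == brute

    def test_idempotent(self, synthetic_dataset):
        once = aggregate(synthetic_dataset)
        twice = aggregate(once)
        assert once.reports == twice.reports
        assert once.n_informants == twice.n_informants


# --- read/write round-trip property -----------------------------------------

_informants = st.builds(
    Informant,
    informant_id=st.uuids().map(lambda u: f"i{u.hex[:8]}"),
    age=st.integers(21, 80),
    gender=st.sampled_from(Gender),
    education=st.sampled_from(Education),
    community=st.sampled_from(Community),
    village=st.sampled_from(["Alpha", "Beta", "Gam ma", 'Qu"ote']),
)

_taxa = st.builds(
    TaxonRecord,
    taxon_id=st.uuids().map(lambda u: f"t{u.hex[:8]}"),
    # readers whitespace-trim field values, so quantify over trimmed names
    botanical_name=st.text(
        st.characters(whitelist_categories=("L", "N"), whitelist_characters=" ,"),
        min_size=1, max_size=20).map(str.strip).filter(bool),
    family=st.sampled_from(["Rosaceae", "Poaceae", "Lamiaceae"]),
    life_form=st.sampled_from(LifeForm),
    parts_used=st.frozensets(st.sampled_from(PlantPart), min_size=1, max_size=3),
    preparation=st.sampled_from(Preparation),
    route=st.none() | st.sampled_from(Route),
    nativity=st.sampled_from(Nativity),
    voucher=st.text(st.characters(whitelist_categories=("L", "N")), max_size=8),
)


@st.composite
def _datasets(draw):
    informants = draw(st.lists(_informants, min_size=1, max_size=5,
                               unique_by=lambda i: i.informant_id))
    taxa = draw(st.lists(_taxa, min_size=1, max_size=5,
                         unique_by=lambda t: t.taxon_id))
    n_reports = draw(st.integers(0, 8))
    reports = []
    for _ in range(n_reports):
        informant = draw(st.sampled_from(informants))
        taxon = draw(st.sampled_from(taxa))
        reports.append(UseReport(
            informant_id=informant.informant_id, taxon_id=taxon.taxon_id,
            ailment=draw(st.sampled_from(["diarrhea", "asthma", "x, y", ""])),
            category=draw(st.none() | st.sampled_from(["GAS", "RES"])),
            village=informant.village,
        ))
    return SurveyDataset(taxa=tuple(taxa), reports=tuple(reports),
                         informants=tuple(informants))


class TestRoundTrip:
    @settings(max_examples=40, deadline=None)
    @given(ds=_datasets())
    def test_write_read_identity(self, ds, tmp_path_factory):
        d = tmp_path_factory.mktemp("rt")
        paths = [str(d / f) for f in
                 ("informants.csv", "taxa.csv", "use_reports.csv")]
        write_survey(ds, *paths)
        back = read_survey(*paths, level=ds.level)
        assert back.informants == ds.informants
        assert back.taxa == ds.taxa
        assert back.reports == ds.reports
        assert back.total_use_reports == ds.total_use_reports


class TestReadSurveyErrors:
    def test_missing_column_named(self, tmp_path):
        (tmp_path / "taxa.csv").write_text("taxon_id,botanical_name\n")
        (tmp_path / "reports.csv").write_text(
            "informant_id,taxon_id,ailment,category,village,count\n")
        with pytest.raises(SchemaError, match="family"):
            read_survey(None, str(tmp_path / "taxa.csv"),
                        str(tmp_path / "reports.csv"),
                        level=DatasetLevel.AGGREGATE, n_informants=5)

    def test_empty_reports_ok(self, tmp_path):
        (tmp_path / "taxa.csv").write_text(
            "taxon_id,botanical_name,family,life_form,parts_used,"
            "preparation,route,nativity,voucher\n"
            "a,Aa,Rosaceae,H,Lv,Powder,,N,V1\n")
        (tmp_path / "reports.csv").write_text(
            "informant_id,taxon_id,ailment,category,village,count\n")
        ds = read_survey(None, str(tmp_path / "taxa.csv"),
                         str(tmp_path / "reports.csv"),
                         level=DatasetLevel.AGGREGATE, n_informants=5)
        assert ds.total_use_reports == 0

    def test_tab_delimiter_autodetected(self, tmp_path):
        (tmp_path / "taxa.csv").write_text(
            "taxon_id\tbotanical_name\tfamily\tlife_form\tparts_used\t"
            "preparation\troute\tnativity\tvoucher\n"
            "a\tAa\tRosaceae\tH\tLv;Rt\tPowder\t\tN\tV1\n")
        (tmp_path / "reports.csv").write_text(
            "informant_id,taxon_id,ailment,category,village,count\n"
            ",a,diarrhea,GAS,,4\n")
        ds = read_survey(None, str(tmp_path / "taxa.csv"),
                         str(tmp_path / "reports.csv"),
                         level=DatasetLevel.AGGREGATE, n_informants=9)
        assert ds.taxa[0].parts_used == frozenset({PlantPart.LEAF, PlantPart.ROOT})
        assert ds.taxa[0].primary_part is PlantPart.LEAF
        assert ds.total_use_reports == 4


class TestValidateConsistency:
    def test_consistent_row_silent(self, paper_dataset):
        out = validate_consistency(
            paper_dataset, {"valeriana_jatamansi": {"urs": 47, "fq": 46.08}})
        assert out == []

    def test_inconsistent_row_flagged(self, paper_dataset):
        out = validate_consistency(
            paper_dataset, {"zizyphus_mauritiama": {"urs": 24, "fq": 20.59}})
        assert len(out) == 1
        assert out[0].recomputed == pytest.approx(23.53)

    def test_empty_table(self, paper_dataset):
        assert validate_consistency(paper_dataset, {}) == []


def test_round_half_up_at_boundary():
    assert round_half_up(0.005) == 0.01
    assert round_half_up(2.675) == 2.68
    assert round_half_up(71.96261682, 2) == 71.96
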