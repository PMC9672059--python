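import pytest

from backbonekit import (
    Checklist,
    Rank,
    SimConfig,
    TaxonomicStatus,
    TaxonRecord,
    build_backbone,
    degrade_backbone,
    generate_checklist,
    generate_occurrences,
)


def acacia_records():
    """A tiny hand-built checklist: one genus, two accepted species, one
    synonym, one unplaced name, one variety."""
    return [
        TaxonRecord("g1", family="Fabaceae", genus="Acacia", scientific_name="Acacia",
                    scientific_name_authorship="Mill.", taxon_rank=Rank.GENUS),
        TaxonRecord("s1", family="Fabaceae", genus="Acacia", specific_epithet="mearnsii",
                    scientific_name="Acacia mearnsii", scientific_name_authorship="De Wild.",
                    taxon_rank=Rank.SPECIES, parent_name_usage_id="g1"),
        TaxonRecord("s2", family="Fabaceae", genus="Acacia", specific_epithet="dealbata",
                    scientific_name="Acacia dealbata", scientific_name_authorship="Link",
                    taxon_rank=Rank.SPECIES, parent_name_usage_id="g1"),
        TaxonRecord("y1", family="Fabaceae", genus="Acacia", specific_epithet="decurrens",
                    scientific_name="Acacia decurrens", scientific_name_authorship="Willd.",
                    taxon_rank=Rank.SPECIES, taxonomic_status=TaxonomicStatus.SYNONYM,
                    accepted_name_usage_id="s1", parent_name_usage_id="g1"),
        TaxonRecord("u1", family="Fabaceae", genus="Acacia", specific_epithet="dubia",
                    scientific_name="Acacia dubia", scientific_name_authorship="Hort.",
                    taxon_rank=Rank.SPECIES, taxonomic_status=TaxonomicStatus.UNPLACED),
        TaxonRecord("v1", family="Fabaceae", genus="Acacia", specific_epithet="mearnsii",
                    infraspecific_epithet="pallida",
                    scientific_name="Acacia mearnsii var. pallida",
                    scientific_name_authorship="Benth.",
                    taxon_rank=Rank.VARIETY, parent_name_usage_id="s1"),
    ]


@pytest.fixture
def acacia_checklist():
    return Checklist(records=acacia_records(), metadata={"title": "Acacia demo"})


@pytest.fixture
def acacia_backbone(acacia_checklist):
    return build_backbone(acacia_checklist)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_genera=8, species_per_genus=(8.0, 1.2),
                     synonyms_per_accepted=1.5, n_ambiguity_traps=2)


@pytest.fixture(scope="session")
def small_checklist(small_config):
    return generate_checklist(small_config)


@pytest.fixture(scope="session")
def study_conditions():
    """The default study conditions: a ~5,000-name checklist, an old
    backbone missing 10% of species-group names, and a 5,000-record
    stream with the default corruption mix."""
    config = SimConfig(seed=20210601 % (2**31))
    checklist = generate_checklist(config)
    old, manifest = degrade_backbone(checklist, config)
    occurrences, truth = generate_occurrences(checklist, 5000, config, old)
    return {
        "config": config,
        "checklist": checklist,
        "old": old,
        "manifest": manifest,
        "occurrences": occurrences,
        "truth": truth,
    }
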