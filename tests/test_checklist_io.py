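"""Darwin Core Archive and working-table I/O contracts."""

import textwrap
import zipfile

import pytest

from backbonekit import (
    Checklist,
    FormatError,
    Rank,
    SimConfig,
    TaxonomicStatus,
    TaxonRecord,
    ValidationError,
    generate_checklist,
    read_dwca,
    read_working_table,
    working_to_dwca,
    write_dwca,
)
from backbonekit.records import WORKING_FIELDS

META = """<?xml version="1.0" encoding="UTF-8"?>
<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core encoding="UTF-8" fieldsTerminatedBy="\\t" linesTerminatedBy="\\n" ignoreHeaderLines="1" rowType="http://rs.tdwg.org/dwc/terms/Taxon">
    <files><location>taxon.txt</location></files>
    <id index="0"/>
    <field index="1" term="http://rs.tdwg.org/dwc/terms/family"/>
    <field index="2" term="http://rs.tdwg.org/dwc/terms/genus"/>
    <field index="3" term="http://rs.tdwg.org/dwc/terms/specificEpithet"/>
    <field index="4" term="http://rs.tdwg.org/dwc/terms/infraspecificEpithet"/>
    <field index="5" term="http://rs.tdwg.org/dwc/terms/scientificName"/>
    <field index="6" term="http://rs.tdwg.org/dwc/terms/scientificNameAuthorship"/>
    <field index="7" term="http://rs.tdwg.org/dwc/terms/taxonRank"/>
    <field index="8" term="http://rs.tdwg.org/dwc/terms/taxonomicStatus"/>
    <field index="9" term="http://rs.tdwg.org/dwc/terms/acceptedNameUsageID"/>
  </core>
</archive>
"""

HEADER = "taxonID\tfamily\tgenus\tspecificEpithet\tinfraspecificEpithet\tscientificName\tscientificNameAuthorship\ttaxonRank\ttaxonomicStatus\tacceptedNameUsageID\n"


def make_archive(tmp_path, rows, meta=META, name="arch"):
    d = tmp_path / name
    d.mkdir()
    (d / "meta.xml").write_text(meta, encoding="utf-8")
    (d / "taxon.txt").write_text(HEADER + "".join(r + "\n" for r in rows), encoding="utf-8")
    return d


def test_minimal_archive_reads_three_statuses(tmp_path):
    rows = [
        "t1\tFabaceae\tAcacia\t\t\tAcacia\tMill.\tgenus\tAccepted\t",
        "t2\tFabaceae\tAcacia\talba\t\tAcacia alba\tL.\tspecies\tSynonym\tt1",
        "t3\tFabaceae\tAcacia\tdubia\t\tAcacia dubia\t\tspecies\tUnplaced\t",
    ]
    checklist = read_dwca(make_archive(tmp_path, rows))
    assert len(checklist) == 3
    syn = checklist.records[1]
    assert syn.taxonomic_status is TaxonomicStatus.SYNONYM
    assert syn.accepted_name_usage_id == "t1"
    assert checklist.records[2].taxonomic_status is TaxonomicStatus.UNPLACED


def test_missing_meta_is_format_error(tmp_path):
    d = tmp_path / "broken"
    d.mkdir()
    (d / "taxon.txt").write_text("x", encoding="utf-8")
    with pytest.raises(FormatError, match="meta.xml"):
        read_dwca(d)


def test_duplicate_id_is_validation_error(tmp_path):
    rows = [
        "t1\tFabaceae\tAcacia\t\t\tAcacia\t\tgenus\tAccepted\t",
        "t1\tFabaceae\tVicia\t\t\tVicia\t\tgenus\tAccepted\t",
    ]
    with pytest.raises(ValidationError, match="t1"):
        read_dwca(make_archive(tmp_path, rows))


def test_unknown_status_token_names_row_and_token(tmp_path):
    rows = ["t1\tFabaceae\tAcacia\t\t\tAcacia\t\tgenus\tDoubtful\t"]
    with pytest.raises(ValidationError, match="Doubtful"):
        read_dwca(make_archive(tmp_path, rows))


def test_unknown_extra_columns_survive_in_extras(tmp_path):
    meta = META.replace(
        "  </core>",
        '    <field index="10" term="http://rs.tdwg.org/dwc/terms/references"/>\n  </core>',
    )
    d = tmp_path / "extra"
    d.mkdir()
    (d / "meta.xml").write_text(meta, encoding="utf-8")
    (d / "taxon.txt").write_text(
        HEADER.rstrip("\n") + "\treferences\n"
        "t1\tFabaceae\tAcacia\t\t\tAcacia\t\tgenus\tAccepted\t\thttp://example.org\n",
        encoding="utf-8",
    )
    checklist = read_dwca(d)
    assert checklist.records[0].extras == {"references": "http://example.org"}


def test_empty_checklist_writes_header_only_core(tmp_path):
    out = write_dwca(Checklist(), tmp_path / "empty")
    core = (out / "taxon.txt").read_text(encoding="utf-8")
    assert core.count("\n") == 1 and core.startswith("taxonID\t")


def test_core_fields_written_in_index_order(tmp_path):
    recs = [
        TaxonRecord("a", family="Fabaceae", genus="Vicia", specific_epithet="faba",
                    scientific_name="Vicia faba", scientific_name_authorship="L.",
                    taxon_rank=Rank.SPECIES),
    ]
    out = write_dwca(Checklist(records=recs), tmp_path / "ordered")
    line = (out / "taxon.txt").read_text(encoding="utf-8").splitlines()[1].split("\t")
    assert len(line) == 15
    assert line[0] == "a" and line[5] == "Vicia faba" and line[6] == "L." and line[8] == "Accepted"


def test_write_refuses_invalid_checklist(tmp_path):
    bad = Checklist(records=[
        TaxonRecord("a", scientific_name="X y", taxon_rank=Rank.SPECIES,
                    taxonomic_status=TaxonomicStatus.SYNONYM)  # pointer missing
    ])
    with pytest.raises(ValidationError, match="accepted name pointer"):
        write_dwca(bad, tmp_path / "bad")


def test_round_trip_identity_on_synthetic_checklist(tmp_path):
    checklist = generate_checklist(SimConfig(seed=5, n_genera=30, species_per_genus=(30.0, 1.2)))
    assert len(checklist) >= 1000
    first = write_dwca(checklist, tmp_path / "a.zip")
    again = write_dwca(read_dwca(first), tmp_path / "b.zip")
    assert read_dwca(again).records == checklist.records
    # writing is byte-deterministic, so the round trip is too
    assert first.read_bytes() == again.read_bytes()


def test_row_conservation_zip_and_directory(tmp_path, small_checklist):
    for target in ("arch.zip", "archdir"):
        out = write_dwca(small_checklist, tmp_path / target)
        assert len(read_dwca(out)) == len(small_checklist)


# ---------------------------------------------------------------------------
# working table

WORKING_HEADER = ",".join(
    f if f != "tribe_clade" else "tribe/clade" for f in WORKING_FIELDS
)


def working_row(**kw):
    base = {f: "" for f in WORKING_FIELDS}
    base.update(kw)
    return ",".join(base[f] for f in WORKING_FIELDS)


def test_working_table_header_only_is_empty(tmp_path):
    p = tmp_path / "wt.csv"
    p.write_text(WORKING_HEADER + "\n", encoding="utf-8")
    assert read_working_table(p) == []


def test_working_table_missing_column_is_format_error(tmp_path):
    p = tmp_path / "wt.csv"
    p.write_text("plant_name_id,taxon_name\n1,Acacia\n", encoding="utf-8")
    with pytest.raises(FormatError, match="sort_name"):
        read_working_table(p)


def test_working_table_accepted_row_without_pointer_parses(tmp_path):
    p = tmp_path / "wt.csv"
    p.write_text(
        WORKING_HEADER + "\n" + working_row(
            plant_name_id="7", taxon_name="Acacia mearnsii De Wild.",
            rank="Species", taxon_status="Accepted",
        ) + "\n",
        encoding="utf-8",
    )
    [rec] = read_working_table(p)
    assert rec.plant_name_id == "7" and rec.accepted_plant_name_id == ""


def test_working_to_dwca_maps_status_and_pointer():
    from backbonekit.records import WcvpWorkingRecord

    rows = [
        WcvpWorkingRecord(plant_name_id="1", taxon_name="Acacia Mill.", rank="Genus",
                          taxon_status="Accepted", family="Fabaceae"),
        WcvpWorkingRecord(plant_name_id="2", taxon_name="Acacia alba L.", rank="Species",
                          taxon_status="Synonym", accepted_plant_name_id="X",
                          family="Fabaceae"),
        WcvpWorkingRecord(plant_name_id="3", taxon_name="Acacia varia Benth.", rank="Species",
                          taxon_status="Orthographic", accepted_plant_name_id="1",
                          family="Fabaceae"),
    ]
    checklist = working_to_dwca(rows)
    assert checklist.records[1].taxonomic_status is TaxonomicStatus.SYNONYM
    assert checklist.records[1].accepted_name_usage_id == "X"
    # the short spelling maps onto the same vocabulary entry
    assert checklist.records[2].taxonomic_status is TaxonomicStatus.ORTHOGRAPHIC_VARIANT
    # names are stored without authorship
    assert checklist.records[1].scientific_name == "Acacia alba"
    assert checklist.records[1].scientific_name_authorship == "L."


def test_working_to_dwca_fifty_rows_pass_invariants():
    from backbonekit.records import WcvpWorkingRecord

    rows = [WcvpWorkingRecord(plant_name_id="g0", taxon_name="Acacia Mill.",
                              rank="Genus", taxon_status="Accepted", family="Fabaceae")]
    for i in range(49):
        accepted = i % 3 != 2
        rows.append(
            WcvpWorkingRecord(
                plant_name_id=f"r{i}",
                taxon_name=f"Acacia epitheton{i} L.",
                rank="Species",
                taxon_status="Accepted" if accepted else "Synonym",
                accepted_plant_name_id="" if accepted else f"r{i - 2}",
                family="Fabaceae",
            )
        )
    checklist = working_to_dwca(rows)
    assert len(checklist) == 50
    assert checklist.validate() == []
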