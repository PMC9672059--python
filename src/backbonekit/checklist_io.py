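"""Checklist I/O: Darwin Core Archives and the 19-field working table.

A Darwin Core Archive is a zip (or unpacked directory) holding a
tab-delimited taxon core file, a ``meta.xml`` descriptor mapping column
indices onto Darwin Core terms, and an ``eml.xml`` metadata document.
The dialect read and written here uses the fifteen taxon terms at fixed
indices 0–14; extra columns survive a round trip through an ``extras``
map on each record.

The working table is the 19-column spreadsheet format used during expert
curation, consumed as a UTF-8 CSV/TSV export.
"""

from __future__ import annotations

import csv
import io
import os
import zipfile
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .name_parser import parse_name, NameParseError
from .records import (
    Checklist,
    FormatError,
    Rank,
    TaxonomicStatus,
    TaxonRecord,
    ValidationError,
    WcvpWorkingRecord,
    WORKING_FIELDS,
    parse_rank,
    parse_status,
)

DWC_NS = "http://rs.tdwg.org/dwc/text/"
TERM_BASE = "http://rs.tdwg.org/dwc/terms/"

#: the fifteen core terms, in field-index order 0-14.
CORE_TERMS = (
    "taxonID",
    "family",
    "genus",
    "specificEpithet",
    "infraspecificEpithet",
    "scientificName",
    "scientificNameAuthorship",
    "taxonRank",
    "taxonomicStatus",
    "acceptedNameUsageID",
    "parentNameUsageID",
    "originalNameUsageID",
    "namePublishedIn",
    "scientificNameID",
    "wfoID",
)

_TERM_TO_ATTR = {
    "taxonID": "taxon_id",
    "family": "family",
    "genus": "genus",
    "specificEpithet": "specific_epithet",
    "infraspecificEpithet": "infraspecific_epithet",
    "scientificName": "scientific_name",
    "scientificNameAuthorship": "scientific_name_authorship",
    "acceptedNameUsageID": "accepted_name_usage_id",
    "parentNameUsageID": "parent_name_usage_id",
    "originalNameUsageID": "original_name_usage_id",
    "namePublishedIn": "name_published_in",
    "scientificNameID": "scientific_name_id",
    "wfoID": "wfo_id",
}

_STATUS_OUT = {
    TaxonomicStatus.ACCEPTED: "Accepted",
    TaxonomicStatus.ARTIFICIAL_HYBRID: "Artificial hybrid",
    TaxonomicStatus.ILLEGITIMATE: "Illegitimate",
    TaxonomicStatus.INCOMPLETE: "Incomplete",
    TaxonomicStatus.INVALID: "Invalid",
    TaxonomicStatus.MISAPPLIED: "Misapplied",
    TaxonomicStatus.ORTHOGRAPHIC_VARIANT: "Orthographic variant",
    TaxonomicStatus.SYNONYM: "Synonym",
    TaxonomicStatus.UNPLACED: "Unplaced",
}


# ---------------------------------------------------------------------------
# Darwin Core Archive reading


def _read_archive_member(path: Path, name: str) -> bytes:
    if path.is_dir():
        member = path / name
        if not member.exists():
            raise FormatError(f"archive {path} has no {name}")
        return member.read_bytes()
    with zipfile.ZipFile(path) as zf:
        names = {os.path.basename(n): n for n in zf.namelist()}
        if name not in names:
            raise FormatError(f"archive {path} has no {name}")
        return zf.read(names[name])


def _parse_meta(meta_bytes: bytes) -> tuple[str, dict[int, str], int, str]:
    """Return (core file name, index->term map, ignored header lines,
    delimiter)."""
    root = etree.fromstring(meta_bytes)
    core = root.find(f"{{{DWC_NS}}}core")
    if core is None:
        core = root.find("core")  # tolerate namespaceless descriptors
    if core is None:
        raise FormatError("meta.xml has no <core> element")
    loc = core.findtext(f"{{{DWC_NS}}}files/{{{DWC_NS}}}location") or core.findtext(
        "files/location"
    )
    if not loc:
        raise FormatError("meta.xml core declares no file location")
    header = int(core.get("ignoreHeaderLines", "0"))
    delim = core.get("fieldsTerminatedBy", "\\t")
    delim = delim.replace("\\t", "\t")
    canon = {t.lower(): t for t in CORE_TERMS}
    fields: dict[int, str] = {}
    for el in core.iter():
        tag = etree.QName(el).localname
        if tag == "id":
            fields[int(el.get("index"))] = "taxonID"
        elif tag == "field":
            term = el.get("term", "").rsplit("/", 1)[-1]
            # capitalisation of e.g. infraspecificEpithet varies in the wild
            fields[int(el.get("index"))] = canon.get(term.lower(), term)
    return loc, fields, header, delim


def _decode_lines(data: bytes) -> list[str]:
    text = data.decode("utf-8")
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    return [ln for ln in text.split("\n") if ln != ""]


def read_dwca(path: str | Path) -> Checklist:
    """Read a Darwin Core Archive (zip or unpacked directory).

    Raises :class:`FormatError` on a missing descriptor and
    :class:`ValidationError` on duplicate identifiers or unknown status
    tokens; dangling pointers are *not* fatal — they are surfaced by
    :meth:`Checklist.validate`.
    """
    path = Path(path)
    meta = _read_archive_member(path, "meta.xml")
    core_name, fields, skip, delim = _parse_meta(meta)
    data = _read_archive_member(path, core_name)
    lines = _decode_lines(data)[skip:]

    known_idx = {i: t for i, t in fields.items() if t in _TERM_TO_ATTR or t in ("taxonRank", "taxonomicStatus")}
    records: list[TaxonRecord] = []
    for lineno, line in enumerate(lines, start=skip + 1):
        cols = line.split(delim)
        rec = TaxonRecord(taxon_id="")
        for i, term in fields.items():
            value = cols[i] if i < len(cols) else ""
            if term == "taxonRank":
                rec.taxon_rank = parse_rank(value, row=lineno)
            elif term == "taxonomicStatus":
                rec.taxonomic_status = parse_status(value, row=lineno)
            elif term in _TERM_TO_ATTR:
                setattr(rec, _TERM_TO_ATTR[term], value)
            else:
                rec.extras[term] = value
        records.append(rec)

    checklist = Checklist(records=records, metadata=_read_eml(path))
    dups = checklist.duplicate_ids()
    if dups:
        raise ValidationError(
            "duplicate taxon_id values: " + ", ".join(sorted(set(dups)))
        )
    return checklist


def _read_eml(path: Path) -> dict:
    try:
        eml = _read_archive_member(path, "eml.xml")
    except FormatError:
        return {}
    try:
        root = etree.fromstring(eml)
    except etree.XMLSyntaxError:
        return {}
    meta: dict = {}
    for key in ("title", "pubDate", "citation"):
        el = root.find(f".//{key}")
        if el is not None and el.text:
            meta[{"pubDate": "version"}.get(key, key)] = el.text.strip()
    return meta


# ---------------------------------------------------------------------------
# Darwin Core Archive writing

_META_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core encoding="UTF-8" fieldsTerminatedBy="\\t" linesTerminatedBy="\\n" fieldsEnclosedBy="" ignoreHeaderLines="1" rowType="http://rs.tdwg.org/dwc/terms/Taxon">
    <files>
      <location>taxon.txt</location>
    </files>
    <id index="0"/>
{fields}
  </core>
</archive>
"""

_EML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<eml:eml xmlns:eml="eml://ecoinformatics.org/eml-2.1.1" packageId="{package_id}" system="backbonekit">
  <dataset>
    <title>{title}</title>
    <pubDate>{version}</pubDate>
  </dataset>
  <additionalMetadata>
    <metadata>
      <citation>{citation}</citation>
    </metadata>
  </additionalMetadata>
</eml:eml>
"""


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")
    )


def _record_row(rec: TaxonRecord) -> list[str]:
    return [
        rec.taxon_id,
        rec.family,
        rec.genus,
        rec.specific_epithet,
        rec.infraspecific_epithet,
        rec.scientific_name,
        rec.scientific_name_authorship,
        rec.taxon_rank.value,
        _STATUS_OUT[rec.taxonomic_status],
        rec.accepted_name_usage_id,
        rec.parent_name_usage_id,
        rec.original_name_usage_id,
        rec.name_published_in,
        rec.scientific_name_id,
        rec.wfo_id,
    ]


def write_dwca(checklist: Checklist, path: str | Path) -> Path:
    """Write ``checklist`` as a Darwin Core Archive.

    ``path`` ending in ``.zip`` produces a zip, anything else an unpacked
    directory.  Output bytes are deterministic for a fixed checklist.
    Refuses to write when per-record invariants fail, reporting all
    violations at once.
    """
    problems = [v for rec in checklist.records for v in rec.violations()]
    dups = checklist.duplicate_ids()
    problems += [f"duplicate taxon_id {d}" for d in dups]
    if problems:
        raise ValidationError("refusing to write invalid checklist:\n" + "\n".join(problems))

    field_lines = "\n".join(
        f'    <field index="{i}" term="{TERM_BASE}{term}"/>'
        for i, term in enumerate(CORE_TERMS)
        if i > 0
    )
    meta_xml = _META_TEMPLATE.format(fields=field_lines)
    md = checklist.metadata
    eml_xml = _EML_TEMPLATE.format(
        package_id=_xml_escape(md.get("package_id", "backbonekit-checklist")),
        title=_xml_escape(md.get("title", "Checklist")),
        version=_xml_escape(md.get("version", "")),
        citation=_xml_escape(md.get("citation", "")),
    )
    buf = io.StringIO()
    buf.write("\t".join(CORE_TERMS) + "\n")
    for rec in checklist.records:
        row = _record_row(rec)
        for v in row:
            if "\t" in v or "\n" in v:
                raise ValidationError(f"{rec.taxon_id}: field contains delimiter: {v!r}")
        buf.write("\t".join(row) + "\n")
    core_bytes = buf.getvalue().encode("utf-8")

    path = Path(path)
    members = {
        "meta.xml": meta_xml.encode("utf-8"),
        "eml.xml": eml_xml.encode("utf-8"),
        "taxon.txt": core_bytes,
    }
    if path.suffix == ".zip":
        path.parent.mkdir(parents=True, exist_ok=True)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, data in sorted(members.items()):
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, data, zipfile.ZIP_DEFLATED)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, data in members.items():
            (path / name).write_bytes(data)
    return path


# ---------------------------------------------------------------------------
# Working table

_HEADER_ALIASES = {
    "tribe/clade": "tribe_clade",
    "tribe clade": "tribe_clade",
}


def read_working_table(path: str | Path) -> list[WcvpWorkingRecord]:
    """Read the 19-field working table from a UTF-8 CSV/TSV export.

    Header order is irrelevant; a missing mandatory column raises
    :class:`FormatError` naming it.  ``verified`` and ``comments`` are
    preserved verbatim.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    canon = [_HEADER_ALIASES.get(h.strip().lower(), h.strip().lower()) for h in header]
    missing = [f for f in WORKING_FIELDS if f not in canon]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    idx = {f: canon.index(f) for f in WORKING_FIELDS}
    out: list[WcvpWorkingRecord] = []
    for row in reader:
        if not row or all(c == "" for c in row):
            continue
        kwargs = {f: (row[i] if i < len(row) else "") for f, i in idx.items()}
        out.append(WcvpWorkingRecord(**kwargs))
    return out


def working_to_dwca(
    records: Sequence[WcvpWorkingRecord], metadata: dict | None = None
) -> Checklist:
    """Convert working-table rows to a Darwin Core checklist.

    ``plant_name_id`` becomes the taxon identifier; ``taxon_name`` (which
    carries authorship inline) is split into canonical parts and
    authorship; accepted rows get an empty accepted pointer even when
    they self-reference.
    """
    out: list[TaxonRecord] = []
    for rowno, wr in enumerate(records, start=1):
        status = parse_status(wr.taxon_status, row=rowno)
        try:
            parsed = parse_name(wr.taxon_name)
        except NameParseError as exc:
            raise ValidationError(f"row {rowno}: unparseable taxon_name: {exc}") from exc
        rank = parse_rank(wr.rank, row=rowno)
        if rank is Rank.OTHER:
            # fall back on the structure of the name itself
            rank = {
                "genus": Rank.GENUS,
                "species": Rank.SPECIES,
                "infraspecific": Rank.SUBSPECIES,
            }[parsed.implied_rank.value]
        accepted = wr.accepted_plant_name_id
        if status is TaxonomicStatus.ACCEPTED or status is TaxonomicStatus.UNPLACED:
            accepted = ""
        out.append(
            TaxonRecord(
                taxon_id=wr.plant_name_id,
                family=wr.family,
                genus=parsed.genus if rank is not Rank.FAMILY else "",
                specific_epithet=parsed.specific_epithet or "",
                infraspecific_epithet=parsed.infraspecific_epithet or "",
                scientific_name=parsed.canonical,
                scientific_name_authorship=parsed.authorship or "",
                taxon_rank=rank,
                taxonomic_status=status,
                accepted_name_usage_id=accepted,
                name_published_in=wr.place_of_publication,
                scientific_name_id=wr.ipni_id,
            )
        )
    return Checklist(records=out, metadata=metadata or {})


def read_occurrences(path: str | Path):
    """Read a flat occurrence TSV with columns occurrenceID,
    scientificName and optionally scientificNameAuthorship."""
    from .impact import OccurrenceRecord

    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "occurrenceID" not in reader.fieldnames:
            raise FormatError(f"{path}: missing occurrenceID column")
        if "scientificName" not in reader.fieldnames:
            raise FormatError(f"{path}: missing scientificName column")
        out = []
        for row in reader:
            out.append(
                OccurrenceRecord(
                    occurrence_id=row["occurrenceID"],
                    verbatim_name=row["scientificName"],
                    verbatim_authorship=row.get("scientificNameAuthorship") or None,
                )
            )
    return out
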