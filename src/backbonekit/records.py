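"""Core record types: taxon rows, working-table rows, checklists.

A checklist is an ordered collection of taxon rows in the Darwin Core
dialect: each row carries an identifier, the parts of the scientific name,
a rank, a taxonomic status drawn from a closed nine-value vocabulary, and
pointers to the accepted name and the parent taxon.  Statuses other than
``accepted`` and ``unplaced`` must point at an accepted name identifier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator


class Rank(str, enum.Enum):
    FAMILY = "family"
    GENUS = "genus"
    SPECIES = "species"
    SUBSPECIES = "subspecies"
    VARIETY = "variety"
    FORM = "form"
    OTHER = "other"


#: ordering used for "coarser / finer" comparisons; infraspecific ranks pool
#: at the same depth.
RANK_DEPTH = {
    Rank.FAMILY: 0,
    Rank.OTHER: 0,
    Rank.GENUS: 1,
    Rank.SPECIES: 2,
    Rank.SUBSPECIES: 3,
    Rank.VARIETY: 3,
    Rank.FORM: 3,
}

#: pooled rank categories used by the impact accounting.
RANK_CATEGORY = {
    Rank.FAMILY: "family",
    Rank.OTHER: "family",
    Rank.GENUS: "genus",
    Rank.SPECIES: "species",
    Rank.SUBSPECIES: "infraspecific",
    Rank.VARIETY: "infraspecific",
    Rank.FORM: "infraspecific",
}

RANK_CATEGORY_ORDER = ("family", "genus", "species", "infraspecific")


class TaxonomicStatus(str, enum.Enum):
    ACCEPTED = "accepted"
    ARTIFICIAL_HYBRID = "artificial_hybrid"
    ILLEGITIMATE = "illegitimate"
    INCOMPLETE = "incomplete"
    INVALID = "invalid"
    MISAPPLIED = "misapplied"
    ORTHOGRAPHIC_VARIANT = "orthographic_variant"
    SYNONYM = "synonym"
    UNPLACED = "unplaced"


#: statuses that must carry an accepted-name pointer.
POINTED_STATUSES = frozenset(TaxonomicStatus) - {
    TaxonomicStatus.ACCEPTED,
    TaxonomicStatus.UNPLACED,
}

_STATUS_TOKENS = {
    "accepted": TaxonomicStatus.ACCEPTED,
    "artificial hybrid": TaxonomicStatus.ARTIFICIAL_HYBRID,
    "artificial_hybrid": TaxonomicStatus.ARTIFICIAL_HYBRID,
    "illegitimate": TaxonomicStatus.ILLEGITIMATE,
    "incomplete": TaxonomicStatus.INCOMPLETE,
    "invalid": TaxonomicStatus.INVALID,
    "misapplied": TaxonomicStatus.MISAPPLIED,
    # both spellings occur in the wild
    "orthographic": TaxonomicStatus.ORTHOGRAPHIC_VARIANT,
    "orthographic variant": TaxonomicStatus.ORTHOGRAPHIC_VARIANT,
    "orthographic_variant": TaxonomicStatus.ORTHOGRAPHIC_VARIANT,
    "synonym": TaxonomicStatus.SYNONYM,
    "unplaced": TaxonomicStatus.UNPLACED,
}

_RANK_TOKENS = {
    "family": Rank.FAMILY,
    "genus": Rank.GENUS,
    "species": Rank.SPECIES,
    "subspecies": Rank.SUBSPECIES,
    "subsp.": Rank.SUBSPECIES,
    "variety": Rank.VARIETY,
    "var.": Rank.VARIETY,
    "form": Rank.FORM,
    "forma": Rank.FORM,
    "f.": Rank.FORM,
}


class ChecklistError(Exception):
    """Base error for checklist parsing and validation."""


class FormatError(ChecklistError):
    """Structurally malformed input (missing descriptor, missing column)."""


class ValidationError(ChecklistError):
    """Well-formed input violating a checklist invariant."""


def parse_status(token: str, *, row: object = None) -> TaxonomicStatus:
    """Map a status token onto the nine-value vocabulary.

    Matching is case-insensitive after trimming; underscores and internal
    whitespace runs are equivalent.  An unknown token raises
    :class:`ValidationError` naming the row and the token.
    """
    key = " ".join(token.strip().lower().replace("_", " ").split())
    try:
        return _STATUS_TOKENS[key]
    except KeyError:
        where = f" (row {row})" if row is not None else ""
        raise ValidationError(f"unknown taxonomic status token {token!r}{where}") from None


def parse_rank(token: str, *, row: object = None) -> Rank:
    key = token.strip().lower()
    try:
        return _RANK_TOKENS[key]
    except KeyError:
        return Rank.OTHER


@dataclass(slots=True)
class TaxonRecord:
    """One checklist row in the Darwin Core taxon dialect.

    ``scientific_name`` is the canonical name *without* authorship; the
    authorship lives only in ``scientific_name_authorship``.
    """

    taxon_id: str
    family: str = ""
    genus: str = ""
    specific_epithet: str = ""
    infraspecific_epithet: str = ""
    scientific_name: str = ""
    scientific_name_authorship: str = ""
    taxon_rank: Rank = Rank.OTHER
    taxonomic_status: TaxonomicStatus = TaxonomicStatus.ACCEPTED
    accepted_name_usage_id: str = ""
    parent_name_usage_id: str = ""
    original_name_usage_id: str = ""
    name_published_in: str = ""
    scientific_name_id: str = ""
    wfo_id: str = ""
    extras: dict = field(default_factory=dict)

    def violations(self) -> list[str]:
        """Per-record invariant violations (empty list when clean)."""
        out = []
        if not self.taxon_id:
            out.append("empty taxon_id")
        if self.taxonomic_status in POINTED_STATUSES and not self.accepted_name_usage_id:
            out.append(
                f"{self.taxon_id}: status {self.taxonomic_status.value} "
                "requires an accepted name pointer"
            )
        return out

    @property
    def is_accepted(self) -> bool:
        return self.taxonomic_status is TaxonomicStatus.ACCEPTED

    @property
    def rank_depth(self) -> int:
        return RANK_DEPTH[self.taxon_rank]


@dataclass(slots=True)
class WcvpWorkingRecord:
    """One row of the 19-field working spreadsheet format.

    All fields are verbatim strings; only ``plant_name_id`` and
    ``taxon_name`` are mandatory.  ``taxon_name`` carries the authorship
    inline.  A non-empty ``verified`` marks an expert-checked record.
    """

    sort_name: str = ""
    plant_name_id: str = ""
    ipni_id: str = ""
    family: str = ""
    subfamily: str = ""
    tribe_clade: str = ""
    rank: str = ""
    taxon_status: str = ""
    taxon_name: str = ""
    place_of_publication: str = ""
    volume_and_page: str = ""
    first_published: str = ""
    geographic_area: str = ""
    nomenclatural_remarks: str = ""
    accepted_plant_name_id: str = ""
    acc_ipni_id: str = ""
    accepted_name: str = ""
    comments: str = ""
    verified: str = ""


WORKING_FIELDS = tuple(WcvpWorkingRecord.__dataclass_fields__)  # 19 fields


@dataclass
class Checklist:
    """An ordered taxon-record collection plus archive-level metadata."""

    records: list[TaxonRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self.records)

    def by_id(self) -> dict[str, TaxonRecord]:
        return {r.taxon_id: r for r in self.records}

    def duplicate_ids(self) -> list[str]:
        seen: set[str] = set()
        dups: list[str] = []
        for r in self.records:
            if r.taxon_id in seen:
                dups.append(r.taxon_id)
            seen.add(r.taxon_id)
        return dups

    def validate(self) -> list[str]:
        """All checklist-level violations: duplicates, dangling pointers,
        per-record invariant failures.  Dangling pointers are reported, not
        fatal — aggregated checklists contain them and a pipeline has to
        diagnose rather than crash."""
        problems: list[str] = []
        dups = self.duplicate_ids()
        problems += [f"duplicate taxon_id {d}" for d in dups]
        ids = {r.taxon_id for r in self.records}
        for r in self.records:
            problems += r.violations()
            if r.accepted_name_usage_id and r.accepted_name_usage_id not in ids:
                problems.append(
                    f"{r.taxon_id}: dangling accepted pointer {r.accepted_name_usage_id}"
                )
            if r.parent_name_usage_id and r.parent_name_usage_id not in ids:
                problems.append(
                    f"{r.taxon_id}: dangling parent pointer {r.parent_name_usage_id}"
                )
        return problems


def require_unique_ids(records: Iterable[TaxonRecord]) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for r in records:
        if r.taxon_id in seen:
            dups.append(r.taxon_id)
        seen.add(r.taxon_id)
    if dups:
        raise ValidationError("duplicate taxon_id values: " + ", ".join(sorted(set(dups))))
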