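"""Checklist summaries, two-version diffs, and backbone name overlap.

Three bookkeeping operations underpin the comparisons a checklist
curation effort reports: (1) a rank-by-status summary of a single
checklist (accepted genera / species / subspecies / varieties / forms,
synonyms in the broad sense, unplaced names counted apart); (2) the
category-wise absolute difference between two such summaries, whose sum
is the headline "number of differences recorded"; and (3) set arithmetic
over canonical-plus-authorship name strings between an older backbone and
a newer checklist — names in both, names the checklist adds, names only
the other sources carry.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from .backbone import Backbone
from .name_parser import normalize_authorship, parse_name, NameParseError
from .records import (
    Checklist,
    POINTED_STATUSES,
    Rank,
    TaxonomicStatus,
    TaxonRecord,
    WcvpWorkingRecord,
)

#: summary categories, in report order
CATEGORIES = ("genera", "species", "subspecies", "varieties", "forms", "synonyms")

_RANK_TO_CATEGORY = {
    Rank.GENUS: "genera",
    Rank.SPECIES: "species",
    Rank.SUBSPECIES: "subspecies",
    Rank.VARIETY: "varieties",
    Rank.FORM: "forms",
}


@dataclass(frozen=True)
class RankStatusSummary:
    accepted_by_rank: dict[str, int]
    synonym_count: int
    unplaced_count: int
    suprageneric_count: int
    total_records: int

    def category_counts(self) -> dict[str, int]:
        out = {c: self.accepted_by_rank.get(c, 0) for c in CATEGORIES[:-1]}
        out["synonyms"] = self.synonym_count
        return out


@dataclass(frozen=True)
class DiffReport:
    per_category_difference: dict[str, int]
    signed_difference: dict[str, int]
    total_difference: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "absolute": self.per_category_difference,
                "signed": self.signed_difference,
                "total": self.total_difference,
            },
            indent=2,
        )


@dataclass(frozen=True)
class OverlapReport:
    in_both: int
    added_from_checklist: int
    other_sources_only: int
    added_by_genus: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for v in (self.in_both, self.added_from_checklist, self.other_sources_only):
            if v < 0:
                raise ValueError("overlap counts must be non-negative")


def summarize(checklist: Checklist) -> RankStatusSummary:
    """Rank-by-status summary; unplaced names are counted apart and never
    enter the accepted or synonym buckets."""
    accepted = Counter()
    synonyms = 0
    unplaced = 0
    suprageneric = 0
    for rec in checklist:
        if rec.taxonomic_status is TaxonomicStatus.UNPLACED:
            unplaced += 1
        elif rec.taxonomic_status in POINTED_STATUSES:
            synonyms += 1
        else:  # accepted
            cat = _RANK_TO_CATEGORY.get(rec.taxon_rank)
            if cat is None:
                suprageneric += 1
            else:
                accepted[cat] += 1
    summary = RankStatusSummary(
        accepted_by_rank=dict(accepted),
        synonym_count=synonyms,
        unplaced_count=unplaced,
        suprageneric_count=suprageneric,
        total_records=len(checklist),
    )
    assert (
        sum(summary.accepted_by_rank.values())
        + summary.synonym_count
        + summary.unplaced_count
        + summary.suprageneric_count
        == summary.total_records
    )
    return summary


def diff_summaries(a: RankStatusSummary, b: RankStatusSummary) -> DiffReport:
    """Category-wise absolute differences and their sum.

    The headline "difference" is absolute — a category that shrank counts
    as many differences as one that grew; signed deltas (b minus a) are
    carried alongside for transparency.
    """
    ca, cb = a.category_counts(), b.category_counts()
    absolute = {c: abs(cb[c] - ca[c]) for c in CATEGORIES}
    signed = {c: cb[c] - ca[c] for c in CATEGORIES}
    return DiffReport(
        per_category_difference=absolute,
        signed_difference=signed,
        total_difference=sum(absolute.values()),
    )


def verification_coverage(
    working_records: list[WcvpWorkingRecord],
) -> dict[str, dict[str, int]]:
    """Per-subfamily genus counts and percentage of genera verified.

    Genera are the genus-rank rows excluding unplaced ones; a genus
    counts as verified when any record under it carries a non-empty
    ``verified`` entry.  Percentages are rounded to integers.
    """
    genus_rows: dict[str, set[str]] = {}
    verified_genera: set[str] = set()
    for wr in working_records:
        try:
            genus = parse_name(wr.taxon_name).genus
        except NameParseError:
            continue
        if wr.verified.strip():
            verified_genera.add(genus)
        if wr.rank.strip().lower() == "genus":
            if wr.taxon_status.strip().lower() == "unplaced":
                continue
            genus_rows.setdefault(wr.subfamily, set()).add(genus)
    out: dict[str, dict[str, int]] = {}
    for subfamily, genera in sorted(genus_rows.items()):
        n = len(genera)
        v = sum(1 for g in genera if g in verified_genera)
        out[subfamily] = {"n_genera": n, "pct_verified": round(100 * v / n) if n else 0}
    return out


def name_key(record: TaxonRecord) -> str:
    """Identity used for cross-system name comparison: canonical name plus
    normalised authorship (identifiers are not comparable across
    independently keyed systems)."""
    return f"{record.scientific_name}|{normalize_authorship(record.scientific_name_authorship)}"


def name_overlap(old_backbone: Backbone, checklist: Checklist) -> OverlapReport:
    """Set arithmetic over name strings between an older backbone and a
    checklist.  The two conservation identities
    ``in_both + added = |checklist names|`` and
    ``in_both + other_only = |backbone names|`` are asserted on every
    call."""
    old_names = {name_key(r) for r in old_backbone.records.values()}
    new_names: dict[str, TaxonRecord] = {}
    for rec in checklist:
        new_names.setdefault(name_key(rec), rec)
    in_both = sum(1 for k in new_names if k in old_names)
    added_keys = [k for k in new_names if k not in old_names]
    other_only = sum(1 for k in old_names if k not in new_names)
    added_by_genus = Counter()
    for k in added_keys:
        rec = new_names[k]
        genus = rec.genus or (rec.scientific_name if rec.taxon_rank is Rank.GENUS else "")
        if genus:
            added_by_genus[genus] += 1
    report = OverlapReport(
        in_both=in_both,
        added_from_checklist=len(added_keys),
        other_sources_only=other_only,
        added_by_genus=dict(added_by_genus),
    )
    assert report.in_both + report.added_from_checklist == len(new_names)
    assert report.in_both + report.other_sources_only == len(old_names)
    return report


def per_genus_new_names(report: OverlapReport, threshold: int) -> dict[str, int]:
    """Genera contributing more than ``threshold`` newly added names,
    descending by count (ties alphabetical)."""
    items = [(g, n) for g, n in report.added_by_genus.items() if n > threshold]
    items.sort(key=lambda t: (-t[1], t[0]))
    return dict(items)
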