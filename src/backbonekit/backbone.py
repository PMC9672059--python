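"""Turn a checklist into a validated, indexed taxonomic backbone.

The backbone is what an aggregator matches verbatim occurrence names
against: a record store keyed by identifier, a canonical-name index for
(fuzzy) lookups, a genus index for hierarchical fallback, and a family
root that guarantees every interpretation chain has somewhere to land.
Construction never fails on messy pointers — it produces a validation
report enumerating dangling pointers, over-long synonym chains, cycles
and rank inversions, so that real aggregated checklists can be diagnosed
rather than rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .records import (
    Checklist,
    ChecklistError,
    POINTED_STATUSES,
    Rank,
    RANK_DEPTH,
    TaxonomicStatus,
    TaxonRecord,
)

FAMILY_ROOT_ID = "FAMILY-ROOT"


class LookupError_(ChecklistError):
    """Unknown taxon identifier."""


@dataclass
class ValidationReport:
    dangling_accepted: list[str] = field(default_factory=list)
    dangling_parent: list[str] = field(default_factory=list)
    long_chains: list[str] = field(default_factory=list)
    cycles: list[str] = field(default_factory=list)
    rank_inversions: list[str] = field(default_factory=list)
    missing_pointer: list[str] = field(default_factory=list)

    _CLASSES = (
        "dangling_accepted",
        "dangling_parent",
        "long_chains",
        "cycles",
        "rank_inversions",
        "missing_pointer",
    )

    def counts(self) -> dict[str, int]:
        return {c: len(getattr(self, c)) for c in self._CLASSES}

    def is_clean(self) -> bool:
        return not any(getattr(self, c) for c in self._CLASSES)

    def flagged_ids(self) -> set[str]:
        return {i for c in self._CLASSES for i in getattr(self, c)}

    def to_json(self) -> str:
        return json.dumps(
            {c: {"count": len(getattr(self, c)), "ids": sorted(getattr(self, c))} for c in self._CLASSES},
            indent=2,
        )

    def to_text(self) -> str:
        lines = ["validation report"]
        for c in self._CLASSES:
            ids = getattr(self, c)
            lines.append(f"  {c}: {len(ids)}")
            for i in sorted(ids)[:20]:
                lines.append(f"    - {i}")
        return "\n".join(lines)


@dataclass(frozen=True, slots=True)
class Resolution:
    """Outcome of following a record to its accepted name.

    ``terminal_status`` is the status of the record the lookup started
    from, so consumers can e.g. exclude misapplied names even though they
    resolve like synonyms.  ``accepted_id`` is absent for unplaced names
    and for pointed records whose chain is broken.
    """

    accepted_id: Optional[str]
    terminal_status: TaxonomicStatus


@dataclass
class Backbone:
    records: dict[str, TaxonRecord]
    canonical_index: dict[str, set[str]]
    genus_index: dict[str, str]
    family_id: str
    report: ValidationReport
    #: canonical names grouped per genus token, for candidate blocking
    genus_blocks: dict[str, list[str]]
    order: list[str]

    def __len__(self) -> int:
        return len(self.records)

    def record(self, taxon_id: str) -> TaxonRecord:
        try:
            return self.records[taxon_id]
        except KeyError:
            raise LookupError_(f"unknown taxon_id {taxon_id!r}") from None


def build_backbone(checklist: Checklist) -> Backbone:
    """Index a checklist; the validation report rides on the backbone.

    An empty checklist is the only fatal input.  When no family-rank
    record exists, a family root is synthesised (named after the records'
    family field) so that family-level fallback always has a target.
    """
    if len(checklist) == 0:
        raise ChecklistError("cannot build a backbone from an empty checklist")

    records: dict[str, TaxonRecord] = {}
    report = ValidationReport()
    for rec in checklist.records:
        if rec.taxon_id in records:
            report.cycles.append(rec.taxon_id)  # duplicate ids caught upstream
            continue
        records[rec.taxon_id] = rec

    family_id = next(
        (r.taxon_id for r in checklist.records if r.taxon_rank is Rank.FAMILY), None
    )
    if family_id is None:
        family_name = next((r.family for r in checklist.records if r.family), "Fabaceae")
        root = TaxonRecord(
            taxon_id=FAMILY_ROOT_ID,
            family=family_name,
            scientific_name=family_name,
            taxon_rank=Rank.FAMILY,
            taxonomic_status=TaxonomicStatus.ACCEPTED,
        )
        records[root.taxon_id] = root
        family_id = root.taxon_id

    canonical_index: dict[str, set[str]] = {}
    genus_index: dict[str, str] = {}
    genus_blocks: dict[str, list[str]] = {}
    for rec in records.values():
        canon = rec.scientific_name
        if canon:
            canonical_index.setdefault(canon, set()).add(rec.taxon_id)
        if rec.taxon_rank is Rank.GENUS and rec.is_accepted and rec.scientific_name:
            genus_index.setdefault(rec.scientific_name, rec.taxon_id)
        genus_token = rec.genus or (
            rec.scientific_name if rec.taxon_rank is Rank.GENUS else ""
        )
        if genus_token and canon:
            genus_blocks.setdefault(genus_token, []).append(canon)
    for block in genus_blocks.values():
        block.sort()

    # --- pointer validation -------------------------------------------------
    for rec in records.values():
        if rec.taxonomic_status in POINTED_STATUSES:
            tgt = rec.accepted_name_usage_id
            if not tgt:
                report.missing_pointer.append(rec.taxon_id)
            elif tgt not in records:
                report.dangling_accepted.append(rec.taxon_id)
            else:
                target = records[tgt]
                if not target.is_accepted:
                    # chain longer than the one hop the data contract allows
                    report.long_chains.append(rec.taxon_id)
        if rec.parent_name_usage_id and rec.parent_name_usage_id not in records:
            report.dangling_parent.append(rec.taxon_id)

    # --- parent inference & hierarchy validation ----------------------------
    for rec in records.values():
        if rec.taxon_id == family_id:
            continue
        if not rec.parent_name_usage_id or rec.parent_name_usage_id not in records:
            if rec.taxon_rank is Rank.GENUS:
                rec.parent_name_usage_id = family_id
            elif rec.genus and rec.genus in genus_index:
                rec.parent_name_usage_id = genus_index[rec.genus]
            else:
                rec.parent_name_usage_id = family_id

    for rec in records.values():
        seen = {rec.taxon_id}
        cur = rec
        while cur.parent_name_usage_id:
            nxt = records.get(cur.parent_name_usage_id)
            if nxt is None:
                break
            if nxt.taxon_id in seen:
                report.cycles.append(rec.taxon_id)
                break
            if RANK_DEPTH[nxt.taxon_rank] >= RANK_DEPTH[cur.taxon_rank] and cur.taxon_id == rec.taxon_id:
                # only report at the offending record, once
                report.rank_inversions.append(rec.taxon_id)
            seen.add(nxt.taxon_id)
            cur = nxt

    return Backbone(
        records=records,
        canonical_index=canonical_index,
        genus_index=genus_index,
        family_id=family_id,
        report=report,
        genus_blocks=genus_blocks,
        order=[r.taxon_id for r in checklist.records],
    )


def resolve_accepted(backbone: Backbone, taxon_id: str) -> Resolution:
    """Follow a record to its accepted name.

    Accepted records resolve to themselves; unplaced records resolve to
    nothing; every other status follows its accepted pointer (chains
    longer than one hop are followed to their terminus — they are already
    flagged in the validation report).
    """
    rec = backbone.record(taxon_id)
    status = rec.taxonomic_status
    if status is TaxonomicStatus.ACCEPTED:
        return Resolution(accepted_id=taxon_id, terminal_status=status)
    if status is TaxonomicStatus.UNPLACED:
        return Resolution(accepted_id=None, terminal_status=status)
    seen = {taxon_id}
    cur = rec
    while True:
        tgt = cur.accepted_name_usage_id
        if not tgt or tgt not in backbone.records or tgt in seen:
            return Resolution(accepted_id=None, terminal_status=status)
        cur = backbone.records[tgt]
        seen.add(cur.taxon_id)
        if cur.is_accepted:
            return Resolution(accepted_id=cur.taxon_id, terminal_status=status)
        if cur.taxonomic_status is TaxonomicStatus.UNPLACED:
            return Resolution(accepted_id=None, terminal_status=status)


def parent_at_rank(backbone: Backbone, taxon_id: str, rank: Rank) -> Optional[str]:
    """Walk parent pointers to the first record at ``rank``.

    Returns ``None`` when the chain is broken or never reaches the rank.
    """
    rec = backbone.record(taxon_id)
    target_depth = RANK_DEPTH[rank]
    seen = {taxon_id}
    cur = rec
    while cur.parent_name_usage_id:
        nxt = backbone.records.get(cur.parent_name_usage_id)
        if nxt is None or nxt.taxon_id in seen:
            return None
        if nxt.taxon_rank is rank or (
            rank is not Rank.FAMILY and RANK_DEPTH[nxt.taxon_rank] == target_depth
        ):
            return nxt.taxon_id
        seen.add(nxt.taxon_id)
        cur = nxt
    return backbone.family_id if rank is Rank.FAMILY and rec.taxon_id != backbone.family_id else None
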