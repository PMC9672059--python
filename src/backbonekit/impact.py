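"""Occurrence re-interpretation impact: the two-backbone comparison.

Each occurrence record carries a verbatim name.  Interpreting the same
name stream against an older and a newer backbone and comparing the
ranks of the two interpretations quantifies what a checklist update
bought: a rank-transition matrix over {family, genus, species,
infraspecific}, the number of occurrences whose interpretation became
strictly finer ("improved"), per-genus improvement counts, and a
partition of the records still interpreted coarser than their verbatim
name implies, by cause.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .backbone import Backbone
from .matcher import DEFAULT_CONFIG, MatchConfig, MatchResult, match_name
from .name_parser import ImpliedRank, NameParseError, ParsedName, parse_name
from .records import RANK_CATEGORY, RANK_CATEGORY_ORDER

_CATEGORY_DEPTH = {c: i for i, c in enumerate(RANK_CATEGORY_ORDER)}
_IMPLIED_DEPTH = {
    ImpliedRank.GENUS: 1,
    ImpliedRank.SPECIES: 2,
    ImpliedRank.INFRASPECIFIC: 3,
}


@dataclass(frozen=True, slots=True)
class OccurrenceRecord:
    occurrence_id: str
    verbatim_name: str
    verbatim_authorship: Optional[str] = None


@dataclass(frozen=True, slots=True)
class OccurrenceAudit:
    """Per-occurrence trail: what each backbone made of the name."""

    occurrence_id: str
    implied_rank: str
    old_rank: str
    new_rank: str
    old_match_type: str
    new_match_type: str
    new_genus: str
    reassigned: bool


@dataclass
class ImpactReport:
    transition_matrix: dict[tuple[str, str], int]
    improved_total: int
    reassigned_total: int
    per_genus_improved: dict[str, int]
    still_higher_rank: int
    parse_failures: list[tuple[str, str]]
    audit: list[OccurrenceAudit] = field(repr=False, default_factory=list)

    def matrix_table(self) -> list[list[int]]:
        return [
            [self.transition_matrix.get((o, n), 0) for n in RANK_CATEGORY_ORDER]
            for o in RANK_CATEGORY_ORDER
        ]


def _interpret(
    parsed: ParsedName, backbone: Backbone, config: MatchConfig
) -> tuple[str, MatchResult]:
    result = match_name(parsed, backbone, config)
    rank = RANK_CATEGORY[result.interpreted_rank]
    return rank, result


def evaluate_impact(
    occurrences: Sequence[OccurrenceRecord],
    old_backbone: Backbone,
    new_backbone: Backbone,
    config: MatchConfig = DEFAULT_CONFIG,
) -> ImpactReport:
    """Re-interpret a name stream under both backbones and tally rank
    transitions.

    "Improved" means a strictly finer interpreted rank under the new
    backbone; a different taxon at the same rank counts as "reassigned",
    not improved.  Unparseable names are collected, never silently
    dropped.
    """
    matrix: Counter = Counter()
    per_genus: Counter = Counter()
    improved = 0
    reassigned = 0
    still_higher = 0
    failures: list[tuple[str, str]] = []
    audit: list[OccurrenceAudit] = []

    for occ in occurrences:
        try:
            parsed = parse_name(occ.verbatim_name)
        except NameParseError as exc:
            failures.append((occ.occurrence_id, str(exc)))
            continue
        if occ.verbatim_authorship and not parsed.authorship:
            parsed = ParsedName(
                genus=parsed.genus,
                specific_epithet=parsed.specific_epithet,
                infraspecific_epithet=parsed.infraspecific_epithet,
                rank_marker=parsed.rank_marker,
                authorship=occ.verbatim_authorship,
                is_hybrid=parsed.is_hybrid,
            )
        old_rank, old_res = _interpret(parsed, old_backbone, config)
        new_rank, new_res = _interpret(parsed, new_backbone, config)
        matrix[(old_rank, new_rank)] += 1

        new_rec = new_backbone.records[new_res.interpreted_id]
        genus = new_rec.genus or (
            new_rec.scientific_name if new_rec.taxon_rank.value == "genus" else ""
        )
        finer = _CATEGORY_DEPTH[new_rank] > _CATEGORY_DEPTH[old_rank]
        is_reassigned = (
            not finer
            and new_rank == old_rank
            and new_backbone.records[new_res.interpreted_id].scientific_name
            != old_backbone.records[old_res.interpreted_id].scientific_name
        )
        if finer:
            improved += 1
            if genus:
                per_genus[genus] += 1
        elif is_reassigned:
            reassigned += 1
        if _CATEGORY_DEPTH[new_rank] < _CATEGORY_DEPTH["species"]:
            still_higher += 1
        audit.append(
            OccurrenceAudit(
                occurrence_id=occ.occurrence_id,
                implied_rank=parsed.implied_rank.value,
                old_rank=old_rank,
                new_rank=new_rank,
                old_match_type=old_res.match_type.value,
                new_match_type=new_res.match_type.value,
                new_genus=genus,
                reassigned=is_reassigned,
            )
        )

    report = ImpactReport(
        transition_matrix=dict(matrix),
        improved_total=improved,
        reassigned_total=reassigned,
        per_genus_improved=dict(per_genus),
        still_higher_rank=still_higher,
        parse_failures=failures,
        audit=audit,
    )
    assert sum(report.transition_matrix.values()) == len(occurrences) - len(failures)
    assert report.improved_total == sum(
        c
        for (o, n), c in report.transition_matrix.items()
        if _CATEGORY_DEPTH[n] > _CATEGORY_DEPTH[o]
    )
    return report


def per_genus_improvements(report: ImpactReport, threshold: int) -> dict[str, int]:
    """Genera with more than ``threshold`` improved occurrences,
    descending by count (ties alphabetical)."""
    items = [(g, n) for g, n in report.per_genus_improved.items() if n > threshold]
    items.sort(key=lambda t: (-t[1], t[0]))
    return dict(items)


def classify_residual(report: ImpactReport) -> dict[str, int]:
    """Partition occurrences still interpreted coarser than their
    verbatim name implies, under the *new* backbone, by cause:

    - ``infraspecific_to_species``: the name implied an infraspecific
      rank but interpretation landed at species (missing infraspecific
      name in the backbone);
    - ``species_level_unmatched``: the name implied species (or finer)
      but interpretation landed above species;
    - ``genus_only_inputs``: the provider supplied only a genus name, so
      species-level interpretation is impossible at source.
    """
    out = {
        "infraspecific_to_species": 0,
        "species_level_unmatched": 0,
        "genus_only_inputs": 0,
    }
    for row in report.audit:
        implied = {"genus": 1, "species": 2, "infraspecific": 3}[row.implied_rank]
        new_depth = _CATEGORY_DEPTH[row.new_rank]
        if row.implied_rank == "genus":
            out["genus_only_inputs"] += 1
        elif new_depth >= implied:
            continue
        elif row.implied_rank == "infraspecific" and row.new_rank == "species":
            out["infraspecific_to_species"] += 1
        else:
            out["species_level_unmatched"] += 1
    return out
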