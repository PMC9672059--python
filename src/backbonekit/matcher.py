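"""The verbatim-name interpretation cascade.

An aggregator interprets each incoming verbatim name against its
backbone in stages: exact canonical-plus-authorship match, exact
canonical match, approximate (Damerau–Levenshtein) match, synonym
resolution to the accepted name, and — on no match, on ambiguity between
equally good candidates, or on an unplaced best candidate — fallback to
the next higher rank.  An infraspecific name whose terminal epithet is
unknown falls back to its species; an unknown species epithet falls back
to the genus; an unknown genus falls back to the family, which always
exists, so interpretation is total.

Thresholds are length-scaled: names of at most 8 characters tolerate one
edit, longer names two; genus tokens tolerate one edit and must keep
their initial letter, which guards against cross-genus epithet
collisions.  Authorship never filters candidates, it only breaks ties.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .backbone import Backbone, Resolution, resolve_accepted
from .distance import bounded_distance
from .name_parser import ImpliedRank, ParsedName, normalize_authorship
from .records import ChecklistError, Rank, TaxonomicStatus


class MatchType(str, enum.Enum):
    EXACT = "exact"
    EXACT_CANONICAL = "exact_canonical"
    FUZZY = "fuzzy"
    HIGHER_RANK_NO_MATCH = "higher_rank_no_match"
    HIGHER_RANK_AMBIGUOUS = "higher_rank_ambiguous"
    HIGHER_RANK_UNPLACED = "higher_rank_unplaced"
    NONE = "none"


@dataclass(frozen=True, slots=True)
class MatchConfig:
    #: maximum edit distance for canonical names of <= 8 characters
    max_edit_distance_short: int = 1
    #: maximum edit distance for longer canonical names
    max_edit_distance_long: int = 2
    #: maximum edit distance for the genus token (initial letter must agree)
    genus_max_distance: int = 1
    use_authorship_tiebreak: bool = True

    def __post_init__(self) -> None:
        if min(self.max_edit_distance_short, self.max_edit_distance_long, self.genus_max_distance) < 0:
            raise ValueError("edit distances must be >= 0")
        if self.max_edit_distance_short > self.max_edit_distance_long:
            raise ValueError("short-name threshold must not exceed long-name threshold")

    def threshold(self, canonical: str) -> int:
        return (
            self.max_edit_distance_short
            if len(canonical) <= 8
            else self.max_edit_distance_long
        )


DEFAULT_CONFIG = MatchConfig()


@dataclass(frozen=True, slots=True)
class MatchResult:
    query: ParsedName
    matched_id: Optional[str]
    interpreted_id: str
    interpreted_rank: Rank
    match_type: MatchType
    candidates_considered: int = 0


def _auth_agrees(query: ParsedName, rec_auth: str) -> bool:
    if not query.authorship or not rec_auth:
        return False
    return normalize_authorship(query.authorship) == normalize_authorship(rec_auth)


def _genus_candidates(backbone: Backbone, genus: str, config: MatchConfig) -> list[str]:
    """Genus tokens reachable from ``genus``: exact, or within
    ``genus_max_distance`` with the same initial letter."""
    out = []
    g0 = genus[:1].lower()
    for token in backbone.genus_blocks:
        if token == genus:
            out.append(token)
        elif token[:1].lower() == g0 and bounded_distance(
            token.lower(), genus.lower(), config.genus_max_distance
        ) <= config.genus_max_distance:
            out.append(token)
    return sorted(out)


def _fuzzy_scan(
    backbone: Backbone,
    query: ParsedName,
    config: MatchConfig,
) -> tuple[list[tuple[int, str]], int]:
    """All (distance, taxon_id) candidates within threshold, plus the
    number of name comparisons performed."""
    canonical = query.canonical
    k = config.threshold(canonical)
    lowered = canonical.lower()
    considered = 0
    hits: list[tuple[int, str]] = []
    if query.implied_rank is ImpliedRank.GENUS:
        for token in _genus_candidates(backbone, query.genus, config):
            for tid in backbone.canonical_index.get(token, ()):
                if backbone.records[tid].taxon_rank is Rank.GENUS:
                    considered += 1
                    d = bounded_distance(lowered, token.lower(), k)
                    if d <= k:
                        hits.append((d, tid))
        return hits, considered
    for token in _genus_candidates(backbone, query.genus, config):
        for cand in backbone.genus_blocks.get(token, ()):
            if " " not in cand:
                continue  # genus-rank record inside its own block
            considered += 1
            d = bounded_distance(lowered, cand.lower(), k)
            if d <= k:
                for tid in backbone.canonical_index.get(cand, ()):
                    hits.append((d, tid))
    return hits, considered


def _rank_candidates(
    backbone: Backbone,
    query: ParsedName,
    hits: Sequence[tuple[int, str]],
    config: MatchConfig,
) -> list[tuple[tuple[int, int], str]]:
    """Attach the tie-break key (distance, authorship disagreement)."""
    keyed = []
    for d, tid in hits:
        agree = _auth_agrees(query, backbone.records[tid].scientific_name_authorship)
        penalty = 0 if (config.use_authorship_tiebreak and agree) else 1
        keyed.append(((d, penalty), tid))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return keyed


def _strip_level(query: ParsedName) -> Optional[ParsedName]:
    """The query one rank coarser: drop the terminal epithet."""
    if query.infraspecific_epithet:
        return ParsedName(
            genus=query.genus,
            specific_epithet=query.specific_epithet,
            authorship=None,
        )
    if query.specific_epithet:
        return ParsedName(genus=query.genus, authorship=None)
    return None


def _shared_genus_interpretation(
    backbone: Backbone, tids: Iterable[str]
) -> Optional[str]:
    genera = set()
    for tid in tids:
        rec = backbone.records[tid]
        genera.add(rec.genus or (rec.scientific_name if rec.taxon_rank is Rank.GENUS else ""))
    if len(genera) == 1:
        g = genera.pop()
        if g and g in backbone.genus_index:
            return backbone.genus_index[g]
    return None


def match_name(
    query: ParsedName, backbone: Backbone, config: MatchConfig = DEFAULT_CONFIG
) -> MatchResult:
    """Interpret one parsed verbatim name against a backbone."""
    if len(backbone) == 0:
        raise ChecklistError("cannot match against an empty backbone")

    considered = 0
    fallback_reason: Optional[MatchType] = None
    level: Optional[ParsedName] = query

    while level is not None:
        canonical = level.canonical
        exact_ids = sorted(backbone.canonical_index.get(canonical, ()))

        # stage 1: exact canonical + authorship
        if exact_ids and level.authorship and config.use_authorship_tiebreak:
            agreeing = [
                tid
                for tid in exact_ids
                if _auth_agrees(level, backbone.records[tid].scientific_name_authorship)
            ]
            if len(agreeing) == 1:
                out = _finalize(
                    backbone, query, agreeing[0], MatchType.EXACT, fallback_reason, considered
                )
                if out is not None:
                    return out
                fallback_reason = fallback_reason or MatchType.HIGHER_RANK_UNPLACED
                level = _strip_level(level)
                continue

        # stage 2: exact canonical, unique
        if len(exact_ids) == 1:
            out = _finalize(
                backbone, query, exact_ids[0], MatchType.EXACT_CANONICAL, fallback_reason, considered
            )
            if out is not None:
                return out
            fallback_reason = fallback_reason or MatchType.HIGHER_RANK_UNPLACED
            level = _strip_level(level)
            continue

        # stage 3: fuzzy scan (includes any exact ties at distance 0)
        hits, n = _fuzzy_scan(backbone, level, config)
        considered += n
        if hits:
            keyed = _rank_candidates(backbone, level, hits, config)
            best_key = keyed[0][0]
            best = [tid for key, tid in keyed if key == best_key]
            if len(set(best)) == 1:
                mt = MatchType.FUZZY if best_key[0] > 0 else (
                    MatchType.EXACT
                    if best_key[1] == 0 and level.authorship
                    else MatchType.EXACT_CANONICAL
                )
                out = _finalize(backbone, query, best[0], mt, fallback_reason, considered)
                if out is not None:
                    return out
                fallback_reason = fallback_reason or MatchType.HIGHER_RANK_UNPLACED
                level = _strip_level(level)
                continue
            # stage 7: equally best candidates survive every tie-break
            fallback_reason = fallback_reason or MatchType.HIGHER_RANK_AMBIGUOUS
            shared = _shared_genus_interpretation(backbone, set(best))
            if shared is not None and _finer_than_query(backbone, shared, query):
                rec = backbone.records[shared]
                return MatchResult(
                    query=query,
                    matched_id=None,
                    interpreted_id=shared,
                    interpreted_rank=rec.taxon_rank,
                    match_type=fallback_reason,
                    candidates_considered=considered,
                )
            root = backbone.records[backbone.family_id]
            return MatchResult(
                query=query,
                matched_id=None,
                interpreted_id=root.taxon_id,
                interpreted_rank=root.taxon_rank,
                match_type=fallback_reason,
                candidates_considered=considered,
            )

        # stage 6: nothing at this level — strip the terminal epithet
        fallback_reason = fallback_reason or MatchType.HIGHER_RANK_NO_MATCH
        level = _strip_level(level)

    root = backbone.records[backbone.family_id]
    return MatchResult(
        query=query,
        matched_id=None,
        interpreted_id=root.taxon_id,
        interpreted_rank=root.taxon_rank,
        match_type=fallback_reason or MatchType.HIGHER_RANK_NO_MATCH,
        candidates_considered=considered,
    )


def _finer_than_query(backbone: Backbone, tid: str, query: ParsedName) -> bool:
    # the ambiguity fallback must interpret strictly coarser than the query
    from .records import RANK_DEPTH

    depth = RANK_DEPTH[backbone.records[tid].taxon_rank]
    implied = {"genus": 1, "species": 2, "infraspecific": 3}[query.implied_rank.value]
    return depth < implied


def _finalize(
    backbone: Backbone,
    query: ParsedName,
    matched_id: str,
    match_type: MatchType,
    fallback_reason: Optional[MatchType],
    considered: int,
) -> Optional[MatchResult]:
    """Resolve a matched record to its accepted form.

    Returns ``None`` when the matched record is unplaced (or its chain is
    broken), signalling the caller to fall back to the next higher rank
    (stage 5).
    """
    res: Resolution = resolve_accepted(backbone, matched_id)
    if res.accepted_id is None:
        return None
    rec = backbone.records[res.accepted_id]
    return MatchResult(
        query=query,
        matched_id=matched_id,
        interpreted_id=res.accepted_id,
        interpreted_rank=rec.taxon_rank,
        match_type=fallback_reason if fallback_reason is not None else match_type,
        candidates_considered=considered,
    )


@dataclass
class BatchOutcome:
    results: list[Optional[MatchResult]] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)


def match_batch(
    queries: Iterable[ParsedName],
    backbone: Backbone,
    config: MatchConfig = DEFAULT_CONFIG,
) -> list[MatchResult]:
    """Order-preserving batch driver, identical to element-wise
    :func:`match_name`."""
    return [match_name(q, backbone, config) for q in queries]


def match_batch_collecting(
    queries: Iterable[ParsedName],
    backbone: Backbone,
    config: MatchConfig = DEFAULT_CONFIG,
) -> BatchOutcome:
    """Like :func:`match_batch` but collects per-item errors instead of
    raising; failed slots hold ``None``."""
    out = BatchOutcome()
    for i, q in enumerate(queries):
        try:
            out.results.append(match_name(q, backbone, config))
        except ChecklistError as exc:
            out.results.append(None)
            out.errors.append((i, str(exc)))
    return out
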