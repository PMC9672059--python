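"""The interpretation cascade: exact, fuzzy, synonym, fallback, ambiguity."""

import numpy as np
import pytest

from backbonekit import (
    Checklist,
    MatchConfig,
    MatchType,
    Rank,
    SimConfig,
    TaxonomicStatus,
    TaxonRecord,
    build_backbone,
    generate_checklist,
    generate_occurrences,
    match_batch,
    match_name,
    parse_name,
)
from backbonekit.matcher import _fuzzy_scan
from backbonekit.records import RANK_DEPTH

from _oracles import brute_force_candidates


def test_unknown_epithet_interprets_at_genus_with_no_species(acacia_backbone):
    """A binomial whose genus is known but whose epithet is not must be
    interpreted at the genus, with no species inferred."""
    r = match_name(parse_name("Acacia xyz"), acacia_backbone)
    assert r.interpreted_id == "g1"
    assert r.interpreted_rank is Rank.GENUS
    assert r.match_type is MatchType.HIGHER_RANK_NO_MATCH


def test_exact_with_authorship(acacia_backbone):
    r = match_name(parse_name("Acacia mearnsii De Wild."), acacia_backbone)
    assert r.interpreted_id == "s1" and r.match_type is MatchType.EXACT


def test_exact_canonical_without_authorship(acacia_backbone):
    r = match_name(parse_name("Acacia dealbata"), acacia_backbone)
    assert r.interpreted_id == "s2" and r.match_type is MatchType.EXACT_CANONICAL


def test_synonym_resolves_to_accepted(acacia_backbone):
    r = match_name(parse_name("Acacia decurrens"), acacia_backbone)
    assert r.matched_id == "y1" and r.interpreted_id == "s1"


def test_fuzzy_single_candidate(acacia_backbone):
    r = match_name(parse_name("Acacia mearnsi"), acacia_backbone)
    assert r.interpreted_id == "s1" and r.match_type is MatchType.FUZZY


def test_unplaced_match_falls_back_to_genus(acacia_backbone):
    r = match_name(parse_name("Acacia dubia"), acacia_backbone)
    assert r.interpreted_id == "g1"
    assert r.match_type is MatchType.HIGHER_RANK_UNPLACED
    assert r.interpreted_rank is Rank.GENUS


def test_unknown_genus_interprets_at_family(acacia_backbone):
    r = match_name(parse_name("Vicia faba"), acacia_backbone)
    assert r.interpreted_id == acacia_backbone.family_id
    assert r.match_type is MatchType.HIGHER_RANK_NO_MATCH


def test_unknown_infraspecific_falls_back_to_species(acacia_backbone):
    """An infraspecific name whose terminal epithet is unknown but whose
    binomial is known interprets at species rank."""
    r = match_name(parse_name("Acacia mearnsii subsp. nonexistens"), acacia_backbone)
    assert r.interpreted_id == "s1" and r.interpreted_rank is Rank.SPECIES
    assert r.match_type is MatchType.HIGHER_RANK_NO_MATCH


def _two_sibling_backbone():
    recs = [
        TaxonRecord("g", genus="Vicia", scientific_name="Vicia", taxon_rank=Rank.GENUS),
        TaxonRecord("a", genus="Vicia", specific_epithet="palabra",
                    scientific_name="Vicia palabra", scientific_name_authorship="L.",
                    taxon_rank=Rank.SPECIES),
        TaxonRecord("b", genus="Vicia", specific_epithet="palabla",
                    scientific_name="Vicia palabla", scientific_name_authorship="DC.",
                    taxon_rank=Rank.SPECIES),
    ]
    return build_backbone(Checklist(records=recs))


def test_ambiguous_tie_interprets_at_shared_genus():
    bb = _two_sibling_backbone()
    # "palabca" is one substitution from each sibling
    r = match_name(parse_name("Vicia palabca"), bb)
    assert r.interpreted_id == "g"
    assert r.match_type is MatchType.HIGHER_RANK_AMBIGUOUS
    assert r.interpreted_rank is Rank.GENUS


def test_authorship_breaks_the_tie():
    bb = _two_sibling_backbone()
    r = match_name(parse_name("Vicia palabca DC."), bb)
    assert r.interpreted_id == "b" and r.match_type is MatchType.FUZZY
    # with the tie-break disabled the same query stays ambiguous
    r2 = match_name(parse_name("Vicia palabca DC."), bb, MatchConfig(use_authorship_tiebreak=False))
    assert r2.match_type is MatchType.HIGHER_RANK_AMBIGUOUS


def test_determinism(small_checklist):
    bb = build_backbone(small_checklist)
    queries = [parse_name(r.scientific_name) for r in small_checklist.records[:50] if r.scientific_name]
    assert match_batch(queries, bb) == match_batch(queries, bb)


def test_batch_equals_elementwise_map(study_conditions):
    bb = build_backbone(study_conditions["checklist"])
    queries = [parse_name(o.verbatim_name) for o in study_conditions["occurrences"][:2000]]
    assert match_batch(queries, bb) == [match_name(q, bb) for q in queries]


def test_deleting_matched_record_never_yields_finer_interpretation(small_checklist):
    """Monotonicity: removing the record a query matched can only keep or
    coarsen the interpretation."""
    bb = build_backbone(small_checklist)
    config = MatchConfig()
    rng = np.random.default_rng(3)
    species = [r for r in small_checklist if r.taxon_rank is Rank.SPECIES][:30]
    for rec in species:
        q = parse_name(rec.scientific_name)
        before = match_name(q, bb, config)
        if before.matched_id is None:
            continue
        pruned = Checklist(
            records=[r for r in small_checklist.records if r.taxon_id != before.matched_id]
        )
        after = match_name(q, build_backbone(pruned), config)
        assert RANK_DEPTH[after.interpreted_rank] <= RANK_DEPTH[before.interpreted_rank]


def test_fuzzy_stage_equals_brute_force_on_small_backbones():
    """On small random backbones the fuzzy stage's candidate set must
    equal an independent all-pairs edit-distance scan."""
    config = MatchConfig()
    rng = np.random.default_rng(17)
    for trial in range(8):
        sim = SimConfig(
            seed=100 + trial,
            n_genera=5,
            species_per_genus=(10.0, 1.2),
            synonyms_per_accepted=1.0,
            n_ambiguity_traps=1,
        )
        checklist = generate_checklist(sim)
        bb = build_backbone(checklist)
        occurrences, _ = generate_occurrences(checklist, 25, sim)
        for occ in occurrences:
            q = parse_name(occ.verbatim_name)
            hits, _ = _fuzzy_scan(bb, q, config)
            assert set(hits) == brute_force_candidates(bb, q, config), occ.verbatim_name
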