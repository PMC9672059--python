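"""Checklist summaries, version diffs and backbone name overlap."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from backbonekit import (
    Checklist,
    build_backbone,
    degrade_backbone,
    diff_summaries,
    name_overlap,
    per_genus_new_names,
    summarize,
    verification_coverage,
)
from backbonekit.metrics import CATEGORIES, RankStatusSummary
from backbonekit.records import Rank, TaxonomicStatus, TaxonRecord, WcvpWorkingRecord


def test_summarize_tiny_checklist(acacia_checklist):
    s = summarize(acacia_checklist)
    assert s.accepted_by_rank == {"genera": 1, "species": 2, "varieties": 1}
    assert s.synonym_count == 1
    assert s.unplaced_count == 1
    assert s.total_records == 6


def test_summarize_is_permutation_invariant(small_checklist):
    shuffled = list(small_checklist.records)
    random.Random(5).shuffle(shuffled)
    assert summarize(Checklist(records=shuffled)) == summarize(small_checklist)


def test_unplaced_never_counted_as_accepted_or_synonym():
    recs = [
        TaxonRecord("u", genus="Vicia", specific_epithet="dubia",
                    scientific_name="Vicia dubia", taxon_rank=Rank.SPECIES,
                    taxonomic_status=TaxonomicStatus.UNPLACED),
    ]
    s = summarize(Checklist(records=recs))
    assert s.accepted_by_rank == {} and s.synonym_count == 0 and s.unplaced_count == 1


def test_all_pointed_statuses_pool_into_the_synonym_bucket():
    pointed = [
        TaxonomicStatus.SYNONYM,
        TaxonomicStatus.ILLEGITIMATE,
        TaxonomicStatus.INVALID,
        TaxonomicStatus.INCOMPLETE,
        TaxonomicStatus.MISAPPLIED,
        TaxonomicStatus.ORTHOGRAPHIC_VARIANT,
        TaxonomicStatus.ARTIFICIAL_HYBRID,
    ]
    recs = [
        TaxonRecord(f"p{i}", genus="Vicia", specific_epithet=f"ep{i}",
                    scientific_name=f"Vicia ep{i}", taxon_rank=Rank.SPECIES,
                    taxonomic_status=status, accepted_name_usage_id="a")
        for i, status in enumerate(pointed)
    ] + [TaxonRecord("a", genus="Vicia", specific_epithet="faba",
                     scientific_name="Vicia faba", taxon_rank=Rank.SPECIES)]
    assert summarize(Checklist(records=recs)).synonym_count == len(pointed)


_summary = st.fixed_dictionaries({c: st.integers(0, 10_000) for c in CATEGORIES})


def _mk(counts):
    return RankStatusSummary(
        accepted_by_rank={c: counts[c] for c in CATEGORIES[:-1]},
        synonym_count=counts["synonyms"],
        unplaced_count=0,
        suprageneric_count=0,
        total_records=sum(counts.values()),
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(a=_summary, b=_summary)
def test_diff_total_matches_independent_recomputation(a, b):
    report = diff_summaries(_mk(a), _mk(b))
    assert report.total_difference == sum(abs(a[c] - b[c]) for c in CATEGORIES)
    assert report.total_difference == sum(report.per_category_difference.values())


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=_summary, b=_summary)
def test_diff_is_symmetric_and_zero_on_self(a, b):
    assert diff_summaries(_mk(a), _mk(a)).total_difference == 0
    assert (
        diff_summaries(_mk(a), _mk(b)).per_category_difference
        == diff_summaries(_mk(b), _mk(a)).per_category_difference
    )


def test_verification_coverage_counts_and_rounds():
    rows = [
        WcvpWorkingRecord(plant_name_id="1", taxon_name="Acacia Mill.", rank="Genus",
                          taxon_status="Accepted", subfamily="Caesalpinioideae"),
        WcvpWorkingRecord(plant_name_id="2", taxon_name="Senna Mill.", rank="Genus",
                          taxon_status="Accepted", subfamily="Caesalpinioideae"),
        # verification recorded on a species row still marks its genus
        WcvpWorkingRecord(plant_name_id="3", taxon_name="Acacia alba L.", rank="Species",
                          taxon_status="Accepted", subfamily="Caesalpinioideae",
                          verified="A. Expert"),
        # unplaced genera are excluded from the denominator
        WcvpWorkingRecord(plant_name_id="4", taxon_name="Dubiosa Hort.", rank="Genus",
                          taxon_status="Unplaced", subfamily="Caesalpinioideae"),
    ]
    cov = verification_coverage(rows)
    assert cov == {"Caesalpinioideae": {"n_genera": 2, "pct_verified": 50}}


def _name_only_checklist(names):
    recs = []
    for i, (genus, epithet) in enumerate(names):
        recs.append(
            TaxonRecord(f"n{i}", genus=genus, specific_epithet=epithet,
                        scientific_name=f"{genus} {epithet}", taxon_rank=Rank.SPECIES)
        )
    return Checklist(records=recs)


def test_overlap_disjoint_and_subset_cases():
    a = _name_only_checklist([("Vicia", "faba"), ("Vicia", "sativa")])
    b = _name_only_checklist([("Lens", "culinaris")])
    bb = build_backbone(a)
    assert name_overlap(bb, b).in_both == 0
    sub = Checklist(records=a.records[:1])
    r = name_overlap(bb, sub)
    assert r.added_from_checklist == 0 and r.in_both == 1


def test_overlap_conservation_on_degraded_pair(small_config, small_checklist):
    old, manifest = degrade_backbone(small_checklist, small_config)
    report = name_overlap(build_backbone(old), small_checklist)
    # construction oracle: the deletion manifest is exactly the added set
    assert report.added_from_checklist == len(manifest)
    assert report.other_sources_only == 0
    assert report.in_both == len(old)


def test_per_genus_new_names_threshold():
    base = [("Vicia", f"ep{i}") for i in range(10)]
    injected = [("Lens", f"nov{i}") for i in range(300)]
    old = build_backbone(_name_only_checklist(base))
    new = _name_only_checklist(base + injected)
    report = name_overlap(old, new)
    assert per_genus_new_names(report, 250) == {"Lens": 300}
    assert per_genus_new_names(report, 0) == {"Lens": 300}
    assert per_genus_new_names(report, 1000) == {}
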