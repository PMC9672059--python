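"""Synthetic checklists, degraded backbone pairs and corrupted name streams.

The generator emulates the input structure the three impact comparisons
assume: a family → genus → species → infraspecific checklist with
synonym groups and the nine-status vocabulary; an "old backbone" formed
by deleting a controlled fraction of species-group names; and an
occurrence stream whose verbatim names are corrupted in parameterised
ways (exact copies, synonym use, one- and two-edit typos, unknown
epithets, genus-only names, engineered ambiguity).

Every stream row carries ground truth: the intended taxon and the rank
at which the documented matching contract must interpret the name under
each backbone.  To make those expectations *exact* rather than
statistical, names are laid out so corruption classes cannot collide:

- distinct names within a genus keep pairwise Damerau–Levenshtein
  distance >= 3, so a deleted name has no fuzzy neighbour and must fall
  back a rank;
- genus names sharing an initial letter keep distance >= 3, so typos in
  epithets can never jump genus;
- typo strings are rejection-sampled until their unique nearest real
  name is their source;
- ambiguity comes only from dedicated "trap" sibling pairs exactly two
  edits apart, which are exempt from the spacing rule, never degraded,
  and never used by any other corruption class.

All randomness flows from one integer seed; output is byte-identical
across runs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distance import bounded_distance
from .impact import OccurrenceRecord
from .records import Checklist, ChecklistError, Rank, TaxonomicStatus, TaxonRecord

CORRUPTION_CLASSES = (
    "exact",
    "synonym_use",
    "typo1",
    "typo2",
    "unknown_epithet",
    "genus_only",
    "ambiguous",
)

#: minimum edit distance kept between distinct names in a genus (and
#: between same-initial genus names); one more than the widest fuzzy
#: threshold, so absence of a name can never be papered over by a
#: neighbour.
NAME_MARGIN = 3

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"

_AUTHORS = (
    "L.",
    "DC.",
    "Benth.",
    "Harv.",
    "Willd.",
    "Lam.",
    "Taub.",
    "Vogel",
    "Mill.",
    "(L.) DC.",
    "(Benth.) Harv.",
    "(Willd.) Lam.",
)

_MINOR_POINTED = (
    TaxonomicStatus.ILLEGITIMATE,
    TaxonomicStatus.INVALID,
    TaxonomicStatus.INCOMPLETE,
    TaxonomicStatus.MISAPPLIED,
    TaxonomicStatus.ORTHOGRAPHIC_VARIANT,
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    ``species_per_genus`` is (mean, dispersion): counts are
    1 + NegativeBinomial with that mean and shape, giving the long right
    tail real genus sizes show.  ``corruption_mix`` must sum to one.
    """

    n_genera: int = 50
    species_per_genus: tuple[float, float] = (35.0, 1.2)
    synonyms_per_accepted: float = 2.0
    infraspecific_fraction: float = 0.15
    unplaced_fraction: float = 0.02
    degrade_fraction: float = 0.10
    n_ambiguity_traps: int = 5
    corruption_mix: dict = field(
        default_factory=lambda: {
            "exact": 0.40,
            "synonym_use": 0.20,
            "typo1": 0.15,
            "typo2": 0.00,
            "unknown_epithet": 0.10,
            "genus_only": 0.10,
            "ambiguous": 0.05,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1:
            raise ChecklistError("degenerate config: need at least one genus")
        for p in (
            self.infraspecific_fraction,
            self.unplaced_fraction,
            self.degrade_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ChecklistError(f"probability out of range: {p}")
        unknown = set(self.corruption_mix) - set(CORRUPTION_CLASSES)
        if unknown:
            raise ChecklistError(f"unknown corruption classes: {sorted(unknown)}")
        total = sum(self.corruption_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ChecklistError(f"corruption_mix sums to {total}, not 1")


@dataclass(frozen=True, slots=True)
class GroundTruthRow:
    occurrence_id: str
    true_taxon_id: str
    corruption_class: str
    expected_new_rank: str
    expected_old_rank: str
    expected_interpreted_id: str


def expected_transition_matrix(truth: Sequence[GroundTruthRow]) -> dict[tuple[str, str], int]:
    """The (old rank, new rank) cell counts the impact pipeline must
    reproduce on the matching stream."""
    return dict(Counter((t.expected_old_rank, t.expected_new_rank) for t in truth))


# ---------------------------------------------------------------------------
# name sampling


def _syllable(rng: np.random.Generator) -> str:
    return _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


def _far_from_all(candidate: str, existing: Sequence[str], margin: int = NAME_MARGIN) -> bool:
    k = margin - 1
    for other in existing:
        if abs(len(candidate) - len(other)) > k:
            continue
        if bounded_distance(candidate, other, k) <= k:
            return False
    return True


class _NamePool:
    """Margin-respecting name sampler over one seeded generator."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.genus_names: list[str] = []
        #: per-genus suffixes (canonical minus the "Genus " prefix);
        #: identical prefixes preserve edit distance, so spacing suffixes
        #: spaces the canonicals.
        self.suffixes: dict[str, list[str]] = defaultdict(list)
        self.canonicals: set[str] = set()

    def new_genus(self) -> str:
        for _ in range(10_000):
            name = _word(self.rng, int(self.rng.integers(3, 5))).capitalize()
            same_initial = [g.lower() for g in self.genus_names if g[0] == name[0]]
            if name not in self.genus_names and _far_from_all(name.lower(), same_initial):
                self.genus_names.append(name)
                return name
        raise ChecklistError("exhausted genus name space")

    def new_epithet(self, genus: str) -> str:
        block = self.suffixes[genus]
        for _ in range(10_000):
            ep = _word(self.rng, int(self.rng.integers(3, 5)))
            if _far_from_all(ep, block):
                return ep
        raise ChecklistError(f"exhausted epithet space in {genus}")

    def register(self, genus: str, suffix: str) -> str:
        canonical = f"{genus} {suffix}"
        if canonical in self.canonicals:
            raise ChecklistError(f"duplicate canonical {canonical}")
        self.canonicals.add(canonical)
        self.suffixes[genus].append(suffix)
        return canonical


# ---------------------------------------------------------------------------
# checklist generation


def generate_checklist(config: SimConfig) -> Checklist:
    """A hierarchical checklist satisfying every checklist invariant.

    Deterministic: a fixed config (including seed) reproduces the same
    records byte for byte.
    """
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    pool = _NamePool(rng)
    mean, shape = config.species_per_genus
    base = max(mean - 1.0, 1e-9)
    p = shape / (shape + base)

    records: list[TaxonRecord] = []
    family = "Fabaceae"
    records.append(
        TaxonRecord(
            taxon_id="FAM1",
            family=family,
            scientific_name=family,
            scientific_name_authorship="Lindl.",
            taxon_rank=Rank.FAMILY,
            taxonomic_status=TaxonomicStatus.ACCEPTED,
        )
    )

    sp_counter = inf_counter = syn_counter = unp_counter = 0
    genus_ids: dict[str, str] = {}
    accepted_species: list[TaxonRecord] = []

    def _author() -> str:
        return _AUTHORS[rng.integers(len(_AUTHORS))]

    for gi in range(config.n_genera):
        gname = pool.new_genus()
        gid = f"GEN{gi + 1:03d}"
        genus_ids[gname] = gid
        records.append(
            TaxonRecord(
                taxon_id=gid,
                family=family,
                genus=gname,
                scientific_name=gname,
                scientific_name_authorship=_author(),
                taxon_rank=Rank.GENUS,
                taxonomic_status=TaxonomicStatus.ACCEPTED,
                parent_name_usage_id="FAM1",
            )
        )
        n_species = 1 + int(rng.negative_binomial(shape, p))
        for _ in range(n_species):
            ep = pool.new_epithet(gname)
            canonical = pool.register(gname, ep)
            sp_counter += 1
            sid = f"SP{sp_counter:05d}"
            sp = TaxonRecord(
                taxon_id=sid,
                family=family,
                genus=gname,
                specific_epithet=ep,
                scientific_name=canonical,
                scientific_name_authorship=_author(),
                taxon_rank=Rank.SPECIES,
                taxonomic_status=TaxonomicStatus.ACCEPTED,
                parent_name_usage_id=gid,
            )
            records.append(sp)
            accepted_species.append(sp)

            if rng.random() < config.infraspecific_fraction:
                marker, rank = (
                    ("subsp.", Rank.SUBSPECIES),
                    ("var.", Rank.VARIETY),
                    ("f.", Rank.FORM),
                )[rng.integers(3)]
                iep = pool.new_epithet(gname)
                icanon = pool.register(gname, f"{ep} {marker} {iep}")
                inf_counter += 1
                records.append(
                    TaxonRecord(
                        taxon_id=f"INF{inf_counter:05d}",
                        family=family,
                        genus=gname,
                        specific_epithet=ep,
                        infraspecific_epithet=iep,
                        scientific_name=icanon,
                        scientific_name_authorship=_author(),
                        taxon_rank=rank,
                        taxonomic_status=TaxonomicStatus.ACCEPTED,
                        parent_name_usage_id=sid,
                    )
                )

            for _ in range(int(rng.poisson(config.synonyms_per_accepted))):
                sep = pool.new_epithet(gname)
                scanon = pool.register(gname, sep)
                syn_counter += 1
                status = (
                    TaxonomicStatus.SYNONYM
                    if rng.random() < 0.85
                    else _MINOR_POINTED[rng.integers(len(_MINOR_POINTED))]
                )
                records.append(
                    TaxonRecord(
                        taxon_id=f"SYN{syn_counter:05d}",
                        family=family,
                        genus=gname,
                        specific_epithet=sep,
                        scientific_name=scanon,
                        scientific_name_authorship=_author(),
                        taxon_rank=Rank.SPECIES,
                        taxonomic_status=status,
                        accepted_name_usage_id=sid,
                        parent_name_usage_id=gid,
                    )
                )

    # unplaced names: species-group rows with no accepted pointer
    n_unplaced = int(round(config.unplaced_fraction * len(accepted_species)))
    gnames = list(genus_ids)
    for _ in range(n_unplaced):
        gname = gnames[rng.integers(len(gnames))]
        ep = pool.new_epithet(gname)
        canonical = pool.register(gname, ep)
        unp_counter += 1
        records.append(
            TaxonRecord(
                taxon_id=f"UNP{unp_counter:04d}",
                family=family,
                genus=gname,
                specific_epithet=ep,
                scientific_name=canonical,
                scientific_name_authorship=_author(),
                taxon_rank=Rank.SPECIES,
                taxonomic_status=TaxonomicStatus.UNPLACED,
                parent_name_usage_id=genus_ids[gname],
            )
        )

    # ambiguity traps: sibling pairs exactly two edits apart
    for _ in range(config.n_ambiguity_traps):
        gname = gnames[rng.integers(len(gnames))]
        e1, e2 = _trap_epithets(rng, pool, gname)
        for ep in (e1, e2):
            canonical = pool.register(gname, ep)
            sp_counter += 1
            sp = TaxonRecord(
                taxon_id=f"SP{sp_counter:05d}",
                family=family,
                genus=gname,
                specific_epithet=ep,
                scientific_name=canonical,
                scientific_name_authorship=_author(),
                taxon_rank=Rank.SPECIES,
                taxonomic_status=TaxonomicStatus.ACCEPTED,
                parent_name_usage_id=genus_ids[gname],
            )
            records.append(sp)

    checklist = Checklist(
        records=records,
        metadata={
            "title": "Synthetic hierarchical checklist",
            "version": "1",
            "citation": f"backbonekit synthetic generator, seed {config.seed}",
        },
    )
    return checklist


def _trap_epithets(rng: np.random.Generator, pool: _NamePool, genus: str) -> tuple[str, str]:
    """Two epithets differing at exactly two non-adjacent positions, each
    margin-spaced from the rest of the genus (but not from each other)."""
    letters = "abcdefghijklmnopqrstuvz"
    for _ in range(10_000):
        e1 = pool.new_epithet(genus)
        positions = sorted(rng.choice(len(e1), size=2, replace=False))
        if positions[1] - positions[0] < 2:
            continue
        chars = list(e1)
        for pos in positions:
            choices = [c for c in letters if c != e1[pos]]
            chars[pos] = choices[rng.integers(len(choices))]
        e2 = "".join(chars)
        if not _far_from_all(e2, pool.suffixes[genus]):
            continue
        if bounded_distance(e1, e2, 2) == 2:
            return e1, e2
    raise ChecklistError("could not build an ambiguity trap")


def find_trap_pairs(checklist: Checklist) -> list[tuple[str, str, str]]:
    """Recover trap pairs from a generated checklist: accepted species in
    the same genus within two edits of each other (everything else keeps
    a wider margin by construction).  Returns (genus, id1, id2)."""
    by_genus: dict[str, list[TaxonRecord]] = defaultdict(list)
    for rec in checklist:
        if rec.taxon_rank is Rank.SPECIES and rec.is_accepted:
            by_genus[rec.genus].append(rec)
    traps = []
    for genus, recs in sorted(by_genus.items()):
        for i, a in enumerate(recs):
            for b in recs[i + 1 :]:
                if (
                    abs(len(a.specific_epithet) - len(b.specific_epithet)) <= 2
                    and bounded_distance(a.specific_epithet, b.specific_epithet, 2) <= 2
                ):
                    traps.append((genus, a.taxon_id, b.taxon_id))
    return traps


# ---------------------------------------------------------------------------
# degradation


def degrade_backbone(
    checklist: Checklist, config: SimConfig
) -> tuple[Checklist, list[str]]:
    """Delete ``degrade_fraction`` of species-group names to form the
    "old" backbone; the genus/family scaffold and the ambiguity traps
    are never touched.  Deleting an accepted name deletes everything
    pointing at it, so the result is a valid checklist.  The returned
    manifest of deleted identifiers is the oracle for the overlap and
    impact accounting."""
    rng = np.random.default_rng(np.random.PCG64(config.seed + 1))
    trap_ids = {tid for _, a, b in find_trap_pairs(checklist) for tid in (a, b)}
    pointed_by_target: dict[str, list[str]] = defaultdict(list)
    children_by_parent: dict[str, list[str]] = defaultdict(list)
    for rec in checklist:
        if rec.accepted_name_usage_id:
            pointed_by_target[rec.accepted_name_usage_id].append(rec.taxon_id)
        if rec.parent_name_usage_id:
            children_by_parent[rec.parent_name_usage_id].append(rec.taxon_id)

    deleted: set[str] = set()
    p = config.degrade_fraction
    for rec in checklist:
        if rec.taxon_id in deleted or rec.taxon_id in trap_ids:
            continue
        if rec.taxon_rank in (Rank.FAMILY, Rank.GENUS, Rank.OTHER):
            continue
        if rng.random() < p:
            deleted.add(rec.taxon_id)
            if rec.is_accepted:
                # closure: infraspecific children and all pointed records
                stack = [rec.taxon_id]
                while stack:
                    cur = stack.pop()
                    for cid in children_by_parent.get(cur, ()):
                        if cid not in deleted:
                            deleted.add(cid)
                            stack.append(cid)
                    for pid in pointed_by_target.get(cur, ()):
                        deleted.add(pid)

    old = Checklist(
        records=[r for r in checklist.records if r.taxon_id not in deleted],
        metadata=dict(checklist.metadata, title="Synthetic degraded backbone"),
    )
    return old, sorted(deleted)


# ---------------------------------------------------------------------------
# occurrence streams


def generate_occurrences(
    checklist: Checklist,
    n: int,
    config: SimConfig,
    old_checklist: Optional[Checklist] = None,
) -> tuple[list[OccurrenceRecord], list[GroundTruthRow]]:
    """A corrupted occurrence stream with per-row ground truth.

    ``old_checklist`` (typically from :func:`degrade_backbone`) is needed
    to state the rank the matching contract must produce under the old
    backbone; without it the old expectations equal the new ones.
    """
    if n == 0:
        return [], []
    rng = np.random.default_rng(np.random.PCG64(config.seed + 2))
    classes = [c for c in CORRUPTION_CLASSES if config.corruption_mix.get(c, 0.0) > 0]
    probs = np.array([config.corruption_mix[c] for c in classes])
    probs = probs / probs.sum()

    by_id = checklist.by_id()
    old_names = {
        r.scientific_name for r in (old_checklist or checklist).records
    }
    trap_pairs = find_trap_pairs(checklist)
    trap_ids = {tid for _, a, b in trap_pairs for tid in (a, b)}
    genus_ids = {
        r.scientific_name: r.taxon_id
        for r in checklist
        if r.taxon_rank is Rank.GENUS and r.is_accepted
    }
    gnames = sorted(genus_ids)
    species = [
        r
        for r in checklist
        if r.taxon_rank is Rank.SPECIES and r.is_accepted and r.taxon_id not in trap_ids
    ]
    infras = [r for r in checklist if r.taxon_rank in (Rank.SUBSPECIES, Rank.VARIETY, Rank.FORM)]
    synonyms = [r for r in checklist if r.taxonomic_status is TaxonomicStatus.SYNONYM]
    exact_pool = species + infras
    suffix_blocks: dict[str, list[str]] = defaultdict(list)
    for rec in checklist:
        if rec.genus and " " in rec.scientific_name:
            suffix_blocks[rec.genus].append(rec.scientific_name[len(rec.genus) + 1 :])
    all_canonicals = {r.scientific_name for r in checklist}

    if "synonym_use" in classes and not synonyms:
        raise ChecklistError("corruption mix asks for synonym_use but no synonyms exist")
    if "ambiguous" in classes and not trap_pairs:
        raise ChecklistError("corruption mix asks for ambiguity but no trap pairs exist")

    occurrences: list[OccurrenceRecord] = []
    truth: list[GroundTruthRow] = []

    def _old_rank_for(rec: TaxonRecord) -> str:
        """Rank the contract yields for rec's verbatim canonical under
        the old backbone."""
        if rec.scientific_name in old_names:
            return _category(rec.taxon_rank)
        if rec.infraspecific_epithet:
            binomial = f"{rec.genus} {rec.specific_epithet}"
            return "species" if binomial in old_names else "genus"
        return "genus"

    for i in range(n):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        oid = f"OCC{i + 1:05d}"
        if cls == "exact":
            rec = exact_pool[rng.integers(len(exact_pool))]
            verbatim = f"{rec.scientific_name} {rec.scientific_name_authorship}"
            truth.append(
                GroundTruthRow(
                    oid, rec.taxon_id, cls,
                    _category(rec.taxon_rank), _old_rank_for(rec), rec.taxon_id,
                )
            )
        elif cls == "synonym_use":
            syn = synonyms[rng.integers(len(synonyms))]
            acc = by_id[syn.accepted_name_usage_id]
            verbatim = f"{syn.scientific_name} {syn.scientific_name_authorship}"
            old = (
                _category(acc.taxon_rank)
                if syn.scientific_name in old_names
                else "genus"
            )
            truth.append(
                GroundTruthRow(
                    oid, acc.taxon_id, cls, _category(acc.taxon_rank), old, acc.taxon_id
                )
            )
        elif cls in ("typo1", "typo2"):
            n_edits = 1 if cls == "typo1" else 2
            rec, verbatim = _typo_name(
                rng, species, suffix_blocks, all_canonicals, n_edits
            )
            truth.append(
                GroundTruthRow(
                    oid, rec.taxon_id, cls, "species", _old_rank_for(rec), rec.taxon_id
                )
            )
        elif cls == "unknown_epithet":
            gname = gnames[rng.integers(len(gnames))]
            ep = _unknown_epithet(rng, suffix_blocks[gname])
            verbatim = f"{gname} {ep}"
            gid = genus_ids[gname]
            truth.append(GroundTruthRow(oid, gid, cls, "genus", "genus", gid))
        elif cls == "genus_only":
            gname = gnames[rng.integers(len(gnames))]
            verbatim = gname
            gid = genus_ids[gname]
            truth.append(GroundTruthRow(oid, gid, cls, "genus", "genus", gid))
        else:  # ambiguous
            gname, a, b = trap_pairs[rng.integers(len(trap_pairs))]
            verbatim = f"{gname} {_trap_query(by_id[a].specific_epithet, by_id[b].specific_epithet)}"
            gid = genus_ids[gname]
            truth.append(GroundTruthRow(oid, gid, cls, "genus", "genus", gid))
        occurrences.append(OccurrenceRecord(occurrence_id=oid, verbatim_name=verbatim))

    return occurrences, truth


def _category(rank: Rank) -> str:
    from .records import RANK_CATEGORY

    return RANK_CATEGORY[rank]


def _trap_query(e1: str, e2: str) -> str:
    """The engineered query exactly one edit from each trap member."""
    diffs = [i for i, (x, y) in enumerate(zip(e1, e2)) if x != y]
    assert len(diffs) == 2 and len(e1) == len(e2)
    chars = list(e1)
    chars[diffs[1]] = e2[diffs[1]]
    q = "".join(chars)
    assert bounded_distance(q, e1, 2) == 1 and bounded_distance(q, e2, 2) == 1
    return q


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _mutate_epithet(rng: np.random.Generator, ep: str, n_edits: int) -> str:
    chars = list(ep)
    for _ in range(n_edits):
        op = rng.integers(4)
        if op == 0 and len(chars) > 4:  # deletion
            del chars[rng.integers(len(chars))]
        elif op == 1:  # insertion
            pos = rng.integers(len(chars) + 1)
            chars.insert(pos, _LETTERS[rng.integers(26)])
        elif op == 2 and len(chars) >= 2:  # adjacent transposition
            pos = rng.integers(len(chars) - 1)
            if chars[pos] != chars[pos + 1]:
                chars[pos], chars[pos + 1] = chars[pos + 1], chars[pos]
            else:
                chars[pos] = _LETTERS[rng.integers(26)]
        else:  # substitution
            pos = rng.integers(len(chars))
            old = chars[pos]
            choices = [c for c in _LETTERS if c != old]
            chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _typo_name(
    rng: np.random.Generator,
    species: list[TaxonRecord],
    suffix_blocks: dict[str, list[str]],
    all_canonicals: set[str],
    n_edits: int,
) -> tuple[TaxonRecord, str]:
    """A corrupted binomial whose unique nearest backbone name is its
    source, at distance between 1 and ``n_edits``."""
    for _ in range(1_000):
        rec = species[rng.integers(len(species))]
        corrupted = _mutate_epithet(rng, rec.specific_epithet, n_edits)
        if corrupted == rec.specific_epithet:
            continue
        candidate = f"{rec.genus} {corrupted}"
        if candidate in all_canonicals or len(candidate) <= 8:
            continue
        d_src = bounded_distance(corrupted, rec.specific_epithet, 2)
        if d_src > 2:
            continue
        # no *other* real name may sit within the widest fuzzy threshold,
        # so that when the source is deleted the query falls back a rank
        # instead of drifting to a neighbour
        ok = True
        for other in suffix_blocks[rec.genus]:
            if other == rec.specific_epithet:
                continue
            if abs(len(corrupted) - len(other)) <= 2 and bounded_distance(
                corrupted, other, 2
            ) <= 2:
                ok = False
                break
        if ok:
            return rec, candidate
    raise ChecklistError("could not corrupt an epithet cleanly")


def _unknown_epithet(rng: np.random.Generator, block: list[str]) -> str:
    for _ in range(10_000):
        ep = _word(rng, int(rng.integers(3, 5)))
        if _far_from_all(ep, block):
            return ep
    raise ChecklistError("exhausted unknown-epithet space")
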