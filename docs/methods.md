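# Methods

## The problem

Biodiversity aggregators interpret every incoming occurrence record —
a specimen or observation arriving with a free-text *verbatim* name —
against a *taxonomic backbone*: an indexed checklist of accepted names,
their synonyms and their higher classification. The quality of that
backbone decides how finely occurrences can be indexed: a missing
species epithet demotes an occurrence to genus level, a missing genus to
family level. `backbonekit` implements the data structures and
accounting needed to study this: checklist I/O in the Darwin Core
Archive dialect, backbone construction and validation, the
name-interpretation cascade, checklist version diffs, backbone name
overlap, and the two-backbone occurrence impact comparison — plus a
synthetic-data generator that produces all of these inputs with known
ground truth.

## Checklist model

A checklist row carries an opaque identifier, the parts of the
scientific name (genus, specific epithet, infraspecific epithet), the
canonical name *without* authorship, the authorship separately, a rank,
and a taxonomic status from a closed nine-value vocabulary: accepted,
artificial hybrid, illegitimate, incomplete, invalid, misapplied,
orthographic variant, synonym, unplaced. Every status other than
accepted and unplaced must point at an accepted name identifier;
unplaced marks a name an expert could not confirm or link. Status
tokens are matched case-insensitively after trimming, and the short
spelling "orthographic" maps to the same vocabulary entry as
"orthographic variant", because both circulate in exported data.

Dangling accepted/parent pointers are a *reported* condition, not a
read failure: aggregated checklists contain them in practice and a
pipeline must diagnose rather than crash. Duplicate identifiers and
unknown status tokens, by contrast, abort a read — silently coalescing
rows would falsify every downstream count.

Archives are UTF-8, tab-delimited without quoting, field indices 0–14
fixed (taxonID, family, genus, specificEpithet, infraspecificEpithet,
scientificName, scientificNameAuthorship, taxonRank, taxonomicStatus,
acceptedNameUsageID, parentNameUsageID, originalNameUsageID,
namePublishedIn, scientificNameID, wfoID). Line endings are normalised
on read and LF on write; writing is byte-deterministic so archives can
be diffed and the write∘read round trip is the identity. The 19-field
curation working table is consumed as a CSV/TSV export (the spreadsheet
container is an exchange convenience; a spreadsheet ingester can wrap
this reader).

## Name parsing

Verbatim names are decomposed with a deliberately small heuristic: the
genus is the leading capitalised token; epithets are the following
lower-case tokens; the infraspecific markers subsp./ssp., var. and f.
(with or without the dot) are lifted out of the epithet stream;
everything from the first token starting with an uppercase letter or
"(" onward is authorship; a leading hybrid sign ("×" or "x ") is
stripped and flagged. "f." counts as the forma marker only after an
epithet — before one it is far more likely *filius* inside an
authorship ("Baker f."). Any other rank designation is left inside the
epithet stream. This is not ICN-grade parsing (no cultivars, named
hybrids or autonym logic) — it only has to serve verbatim occurrence
names, because checklist rows already carry their parts separately.

## The interpretation cascade

One verbatim name is interpreted against a backbone in ordered stages:

1. exact canonical + authorship match;
2. exact canonical match, if unique;
3. approximate match: candidates within a length-scaled
   Damerau–Levenshtein threshold of the canonical, ranked by
   (distance, authorship agreement);
4. the best candidate's *accepted* form becomes the interpretation
   (synonym resolution; one pointer hop by contract, longer chains are
   followed but flagged);
5. a best candidate that is unplaced forces fallback to the next higher
   rank;
6. no candidate at all: the terminal epithet is stripped and matching
   recurses one rank up — infraspecific → species → genus → family;
7. two or more equally best candidates after all tie-breaks: the name
   is interpreted at the finest rank they all share (their common
   genus, else the family).

The family root always exists (synthesised when the checklist has no
family-rank row), so interpretation is total.

Tunable parameters (`MatchConfig`), all in edit-distance units:

| parameter | default | meaning |
|---|---|---|
| `max_edit_distance_short` | 1 | threshold for canonicals ≤ 8 characters |
| `max_edit_distance_long` | 2 | threshold for longer canonicals |
| `genus_max_distance` | 1 | genus-token tolerance; the initial letter must also agree |
| `use_authorship_tiebreak` | on | authorship breaks ties, never filters |

Length-scaled thresholds are the conventional choice for scientific
names; requiring the genus initial to survive guards against
cross-genus epithet collisions. Authorship is never a hard filter
because real occurrence data cites authorities inconsistently; whether
"equally best" should consult authorship at all is genuinely open, so
it is a switch rather than a guess. The distance is the optimal
string alignment variant (adjacent transpositions count one edit),
computed with a banded dynamic program cut off at the threshold; the
test suite checks it against an independent full-matrix implementation.

The hybrid sign is ignored for matching. Misapplied names resolve
through their pointer exactly like synonyms, but the resolution carries
their status so a consumer can exclude them: the vocabulary lists
misapplied without fixing interpretation semantics, and this keeps the
choice downstream.

## Checklist metrics

`summarize` counts accepted names per rank (genera, species,
subspecies, varieties, forms); every non-accepted, non-unplaced status
pools into one synonyms bucket (the headline tables have a single
synonym row while the vocabulary has seven pointed statuses); unplaced
names are counted apart and never enter either bucket. `diff_summaries`
reports per-category *absolute* differences plus their sum — a category
that shrank counts as many differences as one that grew — with signed
deltas carried alongside for transparency. `name_overlap` compares
canonical + normalised authorship strings, not identifiers, because the
two systems being compared are keyed independently; its two
conservation identities (in-both + added = checklist names, in-both +
other-only = backbone names) are asserted on every call.
`verification_coverage` counts genus-rank rows per subfamily, excluding
unplaced genera, and marks a genus verified when any record under it
carries a non-empty verifier entry; percentages are rounded to
integers.

## Impact accounting

`evaluate_impact` re-interprets an occurrence stream under an old and a
new backbone and tallies a transition matrix over the pooled rank
categories family < genus < species < infraspecific (subspecies,
varieties and forms pool as "infraspecific"). "Improved" means a
strictly finer interpreted rank; a different taxon at the same rank is
counted separately as "reassigned". Per-genus improvement counts
attribute the genus from the *new* interpretation. `classify_residual`
partitions occurrences still interpreted coarser than their verbatim
name implies: infraspecific names landing at species, species-level
names landing above species, and genus-only inputs that can never reach
species without source curation. Occurrence identity is the occurrence
identifier (each distinct identifier counts once). Unparseable names
are collected and reported, never dropped.

## The synthetic generator

`generate_checklist` builds a family → genus → species → infraspecific
checklist with pronounceable pseudo-Latin names from a seeded syllable
sampler. Genus sizes are 1 + negative binomial (default mean 35,
shape 1.2), long-tailed so per-genus threshold tables have
non-degenerate output. Defaults: 50 genera (≈ 5,000–6,000 names
total), 2.0 synonym-group members per accepted species (85% status
synonym, the rest spread over the other pointed statuses), 15% of
species with one infraspecific child, 2% unplaced names.
`degrade_backbone` deletes 10% of species-group names (never the
genus/family scaffold), removing everything that points at a deleted
accepted name so the result stays valid; the deletion manifest is the
oracle for the overlap and impact accounting. `generate_occurrences`
draws 5,000 records from the corruption mix exact .40 / synonym-use .20
/ one-edit typo .15 / unknown epithet .10 / genus-only .10 / engineered
ambiguity .05 (a two-edit typo class exists with default weight 0).

The generator's expectations are exact, not statistical, by
construction:

- distinct names within a genus keep pairwise distance ≥ 3 (one more
  than the widest fuzzy threshold), so a deleted name has no fuzzy
  neighbour and its queries must fall back a rank;
- genus names sharing an initial keep distance ≥ 3, so typo'd epithets
  cannot jump genus;
- typo strings are rejection-sampled until no real name other than the
  source lies within the fuzzy threshold;
- ambiguity comes only from dedicated sibling "trap" pairs exactly two
  edits apart (queries one edit from each member), exempt from the
  spacing rule, excluded from degradation and from every other class's
  target pool. Trap pairs are recoverable from the checklist itself
  (they are the only accepted siblings within two edits), so no side
  channel is needed.

Because the expected old-backbone rank depends on which names were
deleted, `generate_occurrences` optionally takes the degraded checklist
and states both expectations per row.

What the generator does *not* emulate — and therefore what passing
tests do not show about real data: realistic typo distributions (real
misspellings cluster on specific letters and latinate endings, and real
names are not spaced three edits apart, so real fuzzy matching faces
genuine near-collisions and homonyms); authorship variability and
abbreviation conventions; nomenclatural structure (basionyms, autonyms,
nothotaxa); dirty pointers and duplicate identifiers (exercised by
hand-built fixtures instead); and the absolute scale of production
backbones. The pipeline's *accounting* is validated exactly; its
real-world match accuracy is not a claim these tests can support.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at ~5,000–6,000
checklist names and 5,000 occurrences — large enough that every
corruption class, rank transition and threshold table is populated,
small enough to iterate on freely — and check the fuzzy stage against a
brute-force scan on 100 backbones of ≤ 500 names with 50 queries each.
All randomness flows from one integer seed per run; derived seeds stay
below 2³¹. Ties are broken deterministically everywhere (sorted
identifiers, alphabetical order within equal counts), so identical
inputs give identical outputs bit for bit. Degenerate inputs are
defined rather than accidental: an empty checklist cannot become a
backbone, an empty occurrence stream yields an empty report, a
zero-degrade run yields an identical pair and an empty manifest.

## Known limitations

- The cascade is a documented reconstruction of how aggregator matching
  behaves, not a bit-for-bit reproduction of any production matcher,
  whose full algorithm (candidate scoring, authorship similarity,
  epithet gender-ending normalisation) is not public in comparable
  detail. Gender-ending normalisation (-us/-a/-um) is future work.
- Multi-source backbone merging with priority ordering is out of scope;
  the package compares exactly two backbones.
- The name parser is intentionally minimal (see above).
- Working-table ingestion reads delimited exports only.
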