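"""Independent brute-force implementations used only as test oracles.

These deliberately avoid the package's banded dynamic program and the
backbone's candidate-blocking indices: the distance is a full-matrix
optimal-string-alignment computation, and the candidate scan walks every
record of the backbone applying the documented matching rules directly.
"""

from backbonekit.name_parser import ImpliedRank
from backbonekit.records import Rank


def naive_osa(a: str, b: str) -> int:
    """Full-matrix Damerau-Levenshtein (optimal string alignment)."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[la][lb]


def brute_force_candidates(backbone, query, config):
    """Every (distance, taxon_id) the fuzzy stage must consider: all-pairs
    scan over the backbone under the documented rules — length-scaled
    threshold on the whole canonical, genus token within
    ``genus_max_distance`` sharing its initial letter."""
    k = config.threshold(query.canonical)
    q = query.canonical.lower()
    hits = set()
    for tid, rec in backbone.records.items():
        cand = rec.scientific_name
        if not cand:
            continue
        if query.implied_rank is ImpliedRank.GENUS:
            if rec.taxon_rank is not Rank.GENUS:
                continue
            token = cand
        else:
            if " " not in cand:
                continue
            token = rec.genus
            if not token:
                continue
        if token != query.genus:
            if token[:1].lower() != query.genus[:1].lower():
                continue
            if naive_osa(token.lower(), query.genus.lower()) > config.genus_max_distance:
                continue
        if abs(len(cand) - len(q)) > k:
            continue
        d = naive_osa(q, cand.lower())
        if d <= k:
            hits.add((d, tid))
    return hits
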