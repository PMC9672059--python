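"""Bounded Damerau–Levenshtein distance (optimal string alignment).

The matcher only ever needs to know whether two canonical names are within
a small threshold k (1 or 2), so the dynamic program is banded: cells more
than k off the diagonal cannot contribute and are skipped, and a row whose
minimum exceeds k aborts early.  Adjacent transpositions count as one
edit, which is the conventional treatment of the commonest typo class in
scientific names.
"""

from __future__ import annotations


def bounded_distance(a: str, b: str, k: int) -> int:
    """Damerau–Levenshtein (OSA) distance between ``a`` and ``b``, cut off
    at ``k``: returns the exact distance when it is <= k, else ``k + 1``.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la > lb:
        a, b, la, lb = b, a, lb, la
    if lb - la > k:
        return k + 1
    if k <= 0:
        return k + 1
    big = k + 1
    # rows over a (shorter), columns over b; banded at |i - j| <= k
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        lo = max(1, i - k)
        hi = min(lb, i + k)
        cur = [big] * (lb + 1)
        cur[lo - 1] = i if lo == 1 else big
        ca = a[i - 1]
        row_min = big
        for j in range(lo, hi + 1):
            cost = 0 if ca == b[j - 1] else 1
            best = prev[j - 1] + cost
            d = prev[j] + 1
            if d < best:
                best = d
            d = cur[j - 1] + 1
            if d < best:
                best = d
            if (
                cost
                and i > 1
                and j > 1
                and ca == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = prev2[j - 2] + 1
                if d < best:
                    best = d
            cur[j] = best
            if best < row_min:
                row_min = best
        if row_min > k:
            return big
        prev2, prev = prev, cur
    return prev[lb] if prev[lb] <= k else big
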