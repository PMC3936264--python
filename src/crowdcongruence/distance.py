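"""Levenshtein (unit-cost) edit distance.

This is the similarity primitive behind dictionary-based hospital-name
normalization: surface forms seen in forum messages (acronyms,
abbreviations, misspellings) are resolved to canonical registry names by
minimum edit distance against an alias dictionary.
"""

from __future__ import annotations

__all__ = ["levenshtein", "char_count_lower_bound"]


def levenshtein(a: str, b: str, limit: int | None = None) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions converting ``a`` into ``b``.

    Parameters
    ----------
    a, b : str
        Strings to compare.
    limit : int, optional
        Early-abandon threshold.  When given, the return value equals the
        true distance whenever that distance is ``<= limit``; otherwise
        ``limit + 1`` is returned (the exact value above the limit is not
        computed).

    Returns
    -------
    int
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb if limit is None else min(lb, limit + 1)
    if lb == 0:
        return la if limit is None else min(la, limit + 1)
    if limit is not None and abs(la - lb) > limit:
        return limit + 1
    # keep the inner loop over the shorter string
    if lb > la:
        a, b = b, a
        la, lb = lb, la
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        ca = a[i - 1]
        cur = [i] + [0] * lb
        row_min = i
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            v = prev[j] + 1
            w = cur[j - 1] + 1
            if w < v:
                v = w
            w = prev[j - 1] + cost
            if w < v:
                v = w
            cur[j] = v
            if v < row_min:
                row_min = v
        # row minimum is a lower bound on the final distance
        if limit is not None and row_min > limit:
            return limit + 1
        prev = cur
    d = prev[lb]
    if limit is not None and d > limit:
        return limit + 1
    return d


def char_count_lower_bound(counts_a: dict[str, int], counts_b: dict[str, int]) -> int:
    """Cheap lower bound on the edit distance from character multisets.

    Every substitution changes the counts of at most two characters by one
    each, and every indel changes one; hence half the total absolute count
    difference (rounded up) never exceeds the edit distance.  Used to prune
    fuzzy dictionary scans before running the dynamic program.
    """
    diff = 0
    for c in counts_a.keys() | counts_b.keys():
        diff += abs(counts_a.get(c, 0) - counts_b.get(c, 0))
    return (diff + 1) // 2
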