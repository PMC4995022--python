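"""Independent brute-force oracles used by the tests.

These stay deliberately naive (plain memoized recursions, full double
sums, exhaustive scans) so they share no code path with the package.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations


def levenshtein_recursive(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def osa_recursive(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def damerau_levenshtein_exhaustive(a: str, b: str) -> int:
    """Lowrance-Wagner recursion scanning all (k, l) transposition
    anchors rather than tracking last occurrences."""

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0 and j == 0:
            return 0
        options = []
        if i > 0:
            options.append(d(i - 1, j) + 1)
        if j > 0:
            options.append(d(i, j - 1) + 1)
        if i > 0 and j > 0:
            options.append(d(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
            for k in range(1, i):
                for l in range(1, j):
                    if a[k - 1] == b[j - 1] and a[i - 1] == b[l - 1]:
                        options.append(d(k - 1, l - 1) + (i - k - 1) + 1 + (j - l - 1))
        return min(options)

    return d(len(a), len(b))


def lcs_distance_recursive(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def lcs(i, j):
        if i == 0 or j == 0:
            return 0
        if a[i - 1] == b[j - 1]:
            return lcs(i - 1, j - 1) + 1
        return max(lcs(i - 1, j), lcs(i, j - 1))

    return len(a) + len(b) - 2 * lcs(len(a), len(b))


def hamming_naive(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def gini_double_sum(sizes) -> float:
    sizes = list(sizes)
    n = len(sizes)
    mean = sum(sizes) / n
    total = sum(abs(x - y) for x in sizes for y in sizes)
    return total / (2 * n * n * mean)


def clones_by_exact_key(records) -> set:
    """Hash-grouping oracle for clonotype assembly at identity 100:
    partition by (V gene, J gene, CDR3 string).  ``records`` is an
    iterable of (sequence_id, v_gene, j_gene, cdr3)."""
    groups = {}
    for sid, v, j, cdr3 in records:
        groups.setdefault((v, j, cdr3), set()).add(sid)
    return {frozenset(g) for g in groups.values()}


def shared_combinations_bruteforce(clone_reps, threshold) -> dict:
    """Exhaustive single-linkage merge of (sample, v, j, cdr3) clone
    representatives; returns sample-combination → shared-clone count."""
    items = list(clone_reps)
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        (_, v1, j1, c1), (_, v2, j2, c2) = items[i], items[j]
        if v1 != v2 or j1 != j2 or len(c1) != len(c2):
            continue
        ident = 100.0 * (1 - sum(x != y for x, y in zip(c1, c2)) / len(c1))
        if ident >= threshold:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(items[i][0])
    out = {}
    for members in comps.values():
        samples = tuple(sorted(set(members)))
        if len(samples) >= 2:
            out[samples] = out.get(samples, 0) + 1
    return out
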