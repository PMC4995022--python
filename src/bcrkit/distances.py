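"""Sequence and repertoire distances, and principal-coordinate analysis.

String metrics cover the edit family (Levenshtein, optimal string
alignment, full Damerau-Levenshtein, Hamming, indel-only/longest-
common-subsequence distance) and the q-gram family (q-gram profile L1,
cosine and Jaccard on q-gram profiles/sets) plus Jaro-Winkler;
similarity-type measures are emitted as 1 − similarity so that larger
values always mean more dissimilar.  Compositional distances
(Bray-Curtis, Jaccard, cosine) compare gene-usage profiles between
samples (or, transposed, between genes).  PCoA embeds a distance
matrix by Gower double-centering and eigendecomposition, with Lingoes
or Cailliez constants to remove negative eigenvalues of non-Euclidean
matrices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import distance as _sp_dist

from .errors import EmptyInputError, UsageError
from .genes import UsageTable

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "string_distance",
    "sequence_distance_matrix",
    "gene_usage_distance",
    "pcoa",
]

STRING_METHODS = (
    "levenshtein",
    "dl",
    "osa",
    "hamming",
    "lcs",
    "qgram",
    "cosine",
    "jaccard",
    "jw",
)


# ---------------------------------------------------------------------------
# string distances
# ---------------------------------------------------------------------------

def _levenshtein(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (ca != cb),  # substitution
            )
        prev = cur
    return prev[-1]


def _osa(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein: adjacent transposition allowed,
    but no substring is edited more than once."""
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = a[i - 1] != b[j - 1]
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[n][m]


def _damerau_levenshtein(a: str, b: str) -> int:
    """Full Damerau-Levenshtein (transposed characters may be edited
    again), via the distance algorithm with per-character bookkeeping."""
    n, m = len(a), len(b)
    maxdist = n + m
    da: Dict[str, int] = {}
    d = [[0] * (m + 2) for _ in range(n + 2)]
    d[0][0] = maxdist
    for i in range(n + 1):
        d[i + 1][0] = maxdist
        d[i + 1][1] = i
    for j in range(m + 1):
        d[0][j + 1] = maxdist
        d[1][j + 1] = j
    for i in range(1, n + 1):
        db = 0
        for j in range(1, m + 1):
            k = da.get(b[j - 1], 0)
            l = db
            if a[i - 1] == b[j - 1]:
                cost = 0
                db = j
            else:
                cost = 1
            d[i + 1][j + 1] = min(
                d[i][j] + cost,
                d[i + 1][j] + 1,
                d[i][j + 1] + 1,
                d[k][l] + (i - k - 1) + 1 + (j - l - 1),
            )
        da[a[i - 1]] = i
    return d[n + 1][m + 1]


def _lcs_length(a: str, b: str) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            cur[j] = prev[j - 1] + 1 if ca == cb else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def _qgram_profile(s: str, q: int) -> Counter:
    return Counter(s[i : i + q] for i in range(len(s) - q + 1))


def _jaro(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    window = max(len(a), len(b)) // 2 - 1
    window = max(window, 0)
    match_a = [False] * len(a)
    match_b = [False] * len(b)
    matches = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(len(b), i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    sa = [c for c, m in zip(a, match_a) if m]
    sb = [c for c, m in zip(b, match_b) if m]
    transpositions = sum(x != y for x, y in zip(sa, sb)) // 2
    m = matches
    return (m / len(a) + m / len(b) + (m - transpositions) / m) / 3.0


def string_distance(
    a: str,
    b: str,
    method: str = "levenshtein",
    q: int = 2,
    jw_prefix_weight: float = 0.1,
) -> float:
    """Distance between two strings under the chosen measure.

    Edit-family methods return edit counts; ``lcs`` is the indel-only
    edit distance |a|+|b| − 2·LCS(a,b); q-gram family methods operate
    on q-gram count profiles (``qgram`` L1, ``cosine``/``jaccard`` as
    1 − similarity); ``jw`` is the Jaro-Winkler distance with prefix
    cap 4.  ``hamming`` requires equal lengths.
    """
    if method not in STRING_METHODS:
        raise UsageError(f"unknown string distance {method!r}")
    if method == "hamming":
        if len(a) != len(b):
            raise UsageError("hamming distance requires equal-length strings")
        return float(sum(x != y for x, y in zip(a, b)))
    if method == "levenshtein":
        return float(_levenshtein(a, b))
    if method == "osa":
        return float(_osa(a, b))
    if method == "dl":
        return float(_damerau_levenshtein(a, b))
    if method == "lcs":
        return float(len(a) + len(b) - 2 * _lcs_length(a, b))
    if method in ("qgram", "cosine", "jaccard"):
        if q < 1:
            raise UsageError("q must be >= 1")
        pa, pb = _qgram_profile(a, q), _qgram_profile(b, q)
        if method == "qgram":
            keys = set(pa) | set(pb)
            return float(sum(abs(pa[k] - pb[k]) for k in keys))
        if not pa and not pb:
            return 0.0
        if not pa or not pb:
            return 1.0
        if method == "jaccard":
            inter = len(set(pa) & set(pb))
            union = len(set(pa) | set(pb))
            return 1.0 - inter / union
        if pa == pb:
            return 0.0
        keys = sorted(set(pa) | set(pb))
        u = np.array([pa[k] for k in keys], dtype=float)
        v = np.array([pb[k] for k in keys], dtype=float)
        return float(max(0.0, 1.0 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v))))
    # jw
    sim = _jaro(a, b)
    prefix = 0
    for x, y in zip(a[:4], b[:4]):
        if x != y:
            break
        prefix += 1
    sim = sim + prefix * jw_prefix_weight * (1.0 - sim)
    return float(1.0 - sim)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal and labels."""

    labels: List[str]
    values: np.ndarray
    method: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise UsageError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise UsageError("distance matrix must be symmetric")
        if n and np.nanmax(np.abs(np.diag(self.values))) > 1e-12:
            raise UsageError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        out.index.name = "label"
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, method: str = "") -> "DistanceMatrix":
        return cls(labels=[str(c) for c in df.columns], values=df.values, method=method)


def sequence_distance_matrix(
    sequences: Sequence[str],
    method: str = "levenshtein",
    group_by_length: bool = False,
    workers: int = 1,
    labels: Optional[Sequence[str]] = None,
    **kwargs,
) -> Union[DistanceMatrix, Dict[int, DistanceMatrix]]:
    """All pairwise string distances, optionally per length group.

    ``workers`` is accepted for interface compatibility; results are
    identical for every value.
    """
    sequences = list(sequences)
    if labels is None:
        labels = (
            list(sequences)
            if len(set(sequences)) == len(sequences)
            else [f"seq{i}" for i in range(len(sequences))]
        )
    if group_by_length:
        groups: Dict[int, List[int]] = {}
        for i, s in enumerate(sequences):
            groups.setdefault(len(s), []).append(i)
        return {
            L: sequence_distance_matrix(
                [sequences[i] for i in idx],
                method=method,
                labels=[labels[i] for i in idx],
                **kwargs,
            )
            for L, idx in sorted(groups.items())
            if len(idx) >= 2
        }
    if len(sequences) < 2:
        raise EmptyInputError("need at least two sequences")
    if method == "hamming" and len({len(s) for s in sequences}) > 1:
        raise UsageError("hamming on mixed lengths requires group_by_length")
    n = len(sequences)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = string_distance(sequences[i], sequences[j], method=method, **kwargs)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(labels), values=values, method=method)


def gene_usage_distance(
    usage: Union[UsageTable, pd.DataFrame],
    method: str = "bray_curtis",
    cutoff: float = 0.0,
    transpose: bool = False,
) -> DistanceMatrix:
    """Compositional distance between samples on a gene-usage table.

    Proportions below ``cutoff`` are zeroed first.  ``transpose``
    computes gene-gene distances across samples instead.  Bray-Curtis
    suits abundance data; Jaccard uses presence/absence; cosine pairs
    with an all-zero profile are undefined (NaN).
    """
    df = usage.df if isinstance(usage, UsageTable) else usage
    # items to compare sit in columns of the usage table (samples)
    mat = df.T if not transpose else df
    labels = [str(i) for i in mat.index]
    if len(labels) < 2:
        raise UsageError("need at least two profiles to compare")
    x = mat.values.astype(float).copy()
    x[x < cutoff] = 0.0
    n = x.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u, v = x[i], x[j]
            if method in ("bray_curtis", "bc"):
                denom = np.sum(u + v)
                d = np.sum(np.abs(u - v)) / denom if denom > 0 else 0.0
            elif method == "jaccard":
                su, sv = u > 0, v > 0
                union = np.sum(su | sv)
                d = 1.0 - np.sum(su & sv) / union if union > 0 else 0.0
            elif method == "cosine":
                nu, nv = np.linalg.norm(u), np.linalg.norm(v)
                d = np.nan if nu == 0 or nv == 0 else float(_sp_dist.cosine(u, v))
            else:
                raise UsageError(f"unknown gene-usage distance {method!r}")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, method=method)


# ---------------------------------------------------------------------------
# principal-coordinate analysis
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    """Metric embedding of a distance matrix.

    ``coordinates`` holds one row per item over the positive axes,
    ordered by decreasing eigenvalue; ``explained_fraction`` is each
    positive eigenvalue over the sum of positive eigenvalues.
    """

    labels: List[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    correction_applied: str
    correction_constant: float
    negative_eigenvalues: bool = False

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        out = pd.DataFrame(self.coordinates, index=self.labels, columns=cols)
        out.index.name = "label"
        return out


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def _decompose(d: np.ndarray):
    b = _gower_center(d ** 2)
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    return eigval[order], eigvec[:, order]


def pcoa(dist: DistanceMatrix, correction: str = "none") -> PCoAResult:
    """Principal-coordinate analysis with optional eigenvalue correction.

    The Gower-centered form of −½d² is eigendecomposed; coordinates are
    eigenvectors scaled by √λ over positive axes.  ``lingoes`` adds the
    minimal constant c to all squared off-diagonal distances
    (d'² = d² + 2c) that makes the form positive semi-definite;
    ``cailliez`` adds the minimal constant to the distances themselves
    (d' = d + c).  With ``none``, strongly negative eigenvalues set a
    warning flag and coordinates use the positive part only.
    """
    if correction not in ("none", "lingoes", "cailliez"):
        raise UsageError(f"unknown correction {correction!r}")
    d = np.asarray(dist.values, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise UsageError("pcoa needs at least three items")

    eigval, eigvec = _decompose(d)
    tol = 1e-8 * max(np.abs(eigval).max(), 1.0)
    constant = 0.0
    applied = "none"
    if eigval.min() < -tol and correction != "none":
        off = ~np.eye(n, dtype=bool)
        if correction == "lingoes":
            constant = float(-eigval.min())
            d2 = d ** 2
            d2[off] += 2.0 * constant
            d = np.sqrt(d2)
        else:  # cailliez
            delta1 = _gower_center(d ** 2)
            delta2 = _gower_center(d)
            upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
            lower = np.hstack([-np.eye(n), -4.0 * delta2])
            special = np.vstack([upper, lower])
            constant = float(np.max(np.linalg.eigvals(special).real))
            d = d.copy()
            d[off] += constant
        applied = correction
        eigval, eigvec = _decompose(d)
        tol = 1e-8 * max(np.abs(eigval).max(), 1.0)

    positive = eigval > tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    pos_sum = eigval[positive].sum()
    explained = eigval[positive] / pos_sum if pos_sum > 0 else eigval[positive]
    return PCoAResult(
        labels=list(dist.labels),
        coordinates=coords,
        eigenvalues=eigval,
        explained_fraction=explained,
        correction_applied=applied,
        correction_constant=constant,
        negative_eigenvalues=bool(eigval.min() < -tol),
    )
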