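"""Per-position amino-acid distributions and Hill-number diversity.

Because indels make it hard to align CDR3s of different lengths,
sequences are grouped by length and diversity is computed per position.
The true diversity (Hill number) of order q is

    D_q = (Σ_i p_i^q)^(1/(1−q)),

with the q→1 limit D_1 = exp(−Σ p_i ln p_i); D_0 is richness and D_2
the inverse Simpson concentration.  D_q equals n exactly for n equally
common types, for every order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, UsageError

__all__ = [
    "AADistribution",
    "DiversityProfile",
    "aa_distribution",
    "hill_number",
    "true_diversity",
    "convert_index",
    "compare_diversity",
]

PLACEHOLDERS = set("*X#")


@dataclass
class AADistribution:
    """Per-length, per-position relative amino-acid frequencies.

    ``per_length[L]`` is a positions × symbols frame of proportions
    p_i; each row sums to 1 over the symbols observed at that position.
    """

    per_length: Dict[int, pd.DataFrame]
    n_sequences: Dict[int, int]

    @property
    def lengths(self) -> List[int]:
        return sorted(self.per_length)


@dataclass
class DiversityProfile:
    """True diversity per position for each sequence length, with the
    per-length mean and standard deviation over positions."""

    order: float
    per_length: Dict[int, np.ndarray]
    mean: Dict[int, float]
    sd: Dict[int, float]

    @property
    def lengths(self) -> List[int]:
        return sorted(self.per_length)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (L, pos + 1, d)
            for L in self.lengths
            for pos, d in enumerate(self.per_length[L])
        ]
        return pd.DataFrame(rows, columns=["length", "position", "D"])


def aa_distribution(
    sequences: Iterable[str], exclude_placeholders: bool = False
) -> AADistribution:
    """Relative amino-acid frequency per position, grouped by length.

    Placeholder symbols ('*', 'X', '#') count as ordinary observed
    types unless ``exclude_placeholders``.
    """
    by_length: Dict[int, List[str]] = {}
    for s in sequences:
        s = (s or "").strip()
        if s:
            by_length.setdefault(len(s), []).append(s)
    if not by_length:
        raise EmptyInputError("no sequences given")

    per_length = {}
    n_sequences = {}
    for L, seqs in by_length.items():
        arr = np.array([list(s) for s in seqs])
        cols: Dict[str, np.ndarray] = {}
        symbols = sorted(set(arr.ravel()))
        if exclude_placeholders:
            symbols = [s for s in symbols if s not in PLACEHOLDERS]
        counts = np.zeros((L, len(symbols)))
        for j, sym in enumerate(symbols):
            counts[:, j] = (arr == sym).sum(axis=0)
        denom = counts.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        per_length[L] = pd.DataFrame(
            counts / denom, index=pd.RangeIndex(1, L + 1, name="position"), columns=symbols
        )
        n_sequences[L] = len(seqs)
    return AADistribution(per_length=per_length, n_sequences=n_sequences)


def hill_number(p: Sequence[float], q: float) -> float:
    """True diversity of order q of one probability vector.

    q=0 counts strictly positive proportions (no epsilon); q=1 is the
    exponential of Shannon entropy with 0·ln 0 := 0; other orders use
    the closed form, with |q−1| < 1e-9 routed to the limit.
    """
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise EmptyInputError("empty probability vector")
    if q == 0:
        return float(p.size)
    if abs(q - 1) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def true_diversity(dist, order: float = 1) -> DiversityProfile:
    """Hill-number profile of an amino-acid distribution (or of raw
    sequences, which are tabulated first) at the given order."""
    if not isinstance(dist, AADistribution):
        dist = aa_distribution(dist)
    per_length = {}
    mean = {}
    sd = {}
    for L, frame in dist.per_length.items():
        d = np.array([hill_number(row, order) for row in frame.values])
        per_length[L] = d
        mean[L] = float(d.mean())
        sd[L] = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return DiversityProfile(order=order, per_length=per_length, mean=mean, sd=sd)


def convert_index(value: float, index_kind: str) -> float:
    """Convert a classical diversity index to true diversity.

    richness x → x; Shannon entropy x → exp(x); Simpson concentration
    x → 1/x.
    """
    if index_kind == "richness":
        return float(value)
    if index_kind == "shannon":
        return float(math.exp(value))
    if index_kind == "simpson":
        if value <= 0:
            raise UsageError("Simpson concentration must be positive")
        return float(1.0 / value)
    raise UsageError(f"unknown index kind {index_kind!r}")


def compare_diversity(
    samples: Mapping[str, Iterable[str]], order: float = 1
) -> pd.DataFrame:
    """Per-sample mean ± sd diversity aligned on sequence length.

    Profiles are computed independently per sample; the output covers
    the union of observed lengths, with NaN where a sample lacks the
    length.
    """
    if len(samples) < 2:
        raise UsageError("compare_diversity needs at least two samples")
    profiles = {name: true_diversity(seqs, order) for name, seqs in samples.items()}
    lengths = sorted({L for p in profiles.values() for L in p.lengths})
    cols = {}
    for name, prof in profiles.items():
        cols[(name, "mean")] = [prof.mean.get(L, np.nan) for L in lengths]
        cols[(name, "sd")] = [prof.sd.get(L, np.nan) for L in lengths]
    out = pd.DataFrame(cols, index=pd.Index(lengths, name="length"))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample", "stat"])
    return out
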