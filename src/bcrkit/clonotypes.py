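"""Clonotype assembly, shared clones, clone filters and statistics.

Sequences descend from one recombination event when they use the same
V gene (optionally also the same J gene) and carry CDR3 sequences of
equal length whose identity reaches a chosen threshold.  Identity is
positional (Hamming-based) on the equal-length CDR3s, so a 100%
threshold degenerates to exact CDR3 grouping while lower thresholds
admit somatic hypermutations; clustering within a candidate group is
single-linkage, making the partition independent of record order.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyInputError, UsageError
from .genes import parse_gene_label
from .errors import ParseError
from .io import RepertoireTable

__all__ = [
    "Clone",
    "CloneSet",
    "SharedCloneTable",
    "GiniResult",
    "assemble_clones",
    "shared_clones",
    "filter_clones",
    "cdr3_length_distribution",
    "copy_number_distribution",
    "gini_index",
]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass
class Clone:
    clone_id: str
    v_gene: str
    j_gene: Optional[str]
    cdr3_length: int
    representative_cdr3: str
    member_ids: List[str]
    member_cdr3: List[str]
    functionality_counts: Dict[str, int] = field(default_factory=dict)
    junction_frame_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class CloneSet:
    sample_name: str
    clones: List[Clone]
    identity_threshold: float
    require_same_j: bool
    sequence_kind: str
    n_excluded: int = 0  # records without a usable CDR3 / V gene

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def sizes(self) -> List[int]:
        return [c.size for c in self.clones]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "clone_id": c.clone_id,
                "v_gene": c.v_gene,
                "j_gene": c.j_gene or "",
                "cdr3_length": c.cdr3_length,
                "representative_cdr3": c.representative_cdr3,
                "size": c.size,
                "member_ids": ";".join(c.member_ids),
            }
            for c in self.clones
        ]
        return pd.DataFrame(rows)


def _identity_matrix(cdr3s: Sequence[str]) -> np.ndarray:
    """Pairwise percent identity of equal-length strings (vectorised)."""
    arr = np.frombuffer("".join(cdr3s).encode("ascii"), dtype=np.uint8).reshape(
        len(cdr3s), -1
    )
    mism = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return 100.0 * (1.0 - mism / arr.shape[1])


def _gene_candidates(raw: str) -> Optional[Tuple[str, ...]]:
    try:
        return parse_gene_label(raw).at_level("gene")
    except ParseError:
        return None


def assemble_clones(
    table: RepertoireTable,
    identity_threshold: float = 100.0,
    require_same_j: bool = True,
    sequence_kind: str = "aa",
    gene_match: str = "first",
) -> CloneSet:
    """Partition a repertoire into clonotypes.

    Parameters
    ----------
    identity_threshold:
        Percent CDR3 identity in (0, 100]; 100 keeps only identical
        CDR3s together, lower values admit point mutations.
    require_same_j:
        Also require a shared J gene.
    sequence_kind:
        Cluster on the amino-acid ("aa", default) or nucleotide ("nt")
        CDR3.
    gene_match:
        "first" matches genes by the first annotated candidate;
        "intersect" lets ambiguous annotations match whenever their
        candidate sets overlap.
    """
    if not 0 < identity_threshold <= 100:
        raise UsageError("identity_threshold must be in (0, 100]")
    if sequence_kind not in ("aa", "nt"):
        raise UsageError(f"unknown sequence kind {sequence_kind!r}")
    if gene_match not in ("first", "intersect"):
        raise UsageError(f"unknown gene_match mode {gene_match!r}")
    cdr3_col = "cdr3_aa" if sequence_kind == "aa" else "cdr3_nt"

    df = table.df
    idx: List[int] = []  # row positions of clonable records
    v_cands: List[Tuple[str, ...]] = []
    j_cands: List[Optional[Tuple[str, ...]]] = []
    cdr3s: List[str] = []
    n_excluded = 0
    for i, (cdr3, v_raw, j_raw) in enumerate(
        zip(df[cdr3_col], df["v_gene"], df["j_gene"])
    ):
        cdr3 = (cdr3 or "").strip()
        vc = _gene_candidates(v_raw)
        jc = _gene_candidates(j_raw) if require_same_j else None
        if not cdr3 or vc is None or (require_same_j and jc is None):
            n_excluded += 1
            continue
        idx.append(i)
        v_cands.append(vc)
        j_cands.append(jc)
        cdr3s.append(cdr3)

    n = len(idx)
    uf = _UnionFind(n)

    # bucket by a shared gene candidate (+ CDR3 length); two records can
    # only merge if some bucket contains both
    buckets: Dict[tuple, List[int]] = {}
    for k in range(n):
        vs = v_cands[k] if gene_match == "intersect" else v_cands[k][:1]
        for v in vs:
            buckets.setdefault((v, len(cdr3s[k])), []).append(k)

    def _j_compatible(a: int, b: int) -> bool:
        if not require_same_j:
            return True
        if gene_match == "first":
            return j_cands[a][0] == j_cands[b][0]
        return bool(set(j_cands[a]) & set(j_cands[b]))

    for members in buckets.values():
        if len(members) < 2:
            continue
        if identity_threshold == 100:
            exact: Dict[str, List[int]] = {}
            for k in members:
                exact.setdefault(cdr3s[k], []).append(k)
            groups = exact.values()
            for grp in groups:
                for k in grp[1:]:
                    if _j_compatible(grp[0], k):
                        uf.union(grp[0], k)
            continue
        ident = _identity_matrix([cdr3s[k] for k in members])
        ai, bi = np.nonzero(np.triu(ident >= identity_threshold, k=1))
        for a, b in zip(ai, bi):
            ka, kb = members[a], members[b]
            if _j_compatible(ka, kb):
                uf.union(ka, kb)

    components: Dict[int, List[int]] = {}
    for k in range(n):
        components.setdefault(uf.find(k), []).append(k)

    clones = []
    for root in sorted(components):
        members = components[root]
        rows = df.iloc[[idx[k] for k in members]]
        member_cdr3 = [cdr3s[k] for k in members]
        rep = _representative(member_cdr3)
        v = Counter(v_cands[k][0] for k in members).most_common(1)[0][0]
        j = (
            Counter(j_cands[k][0] for k in members).most_common(1)[0][0]
            if require_same_j
            else None
        )
        member_ids = list(rows["sequence_id"])
        digest = hashlib.sha1(
            "|".join([v, j or "", str(len(rep))] + sorted(member_ids)).encode()
        ).hexdigest()[:12]
        clones.append(
            Clone(
                clone_id=digest,
                v_gene=v,
                j_gene=j,
                cdr3_length=len(rep),
                representative_cdr3=rep,
                member_ids=member_ids,
                member_cdr3=member_cdr3,
                functionality_counts=dict(Counter(rows["functionality"])),
                junction_frame_counts=dict(
                    Counter(rows["junction_frame"].replace("", "null"))
                ),
            )
        )
    return CloneSet(
        sample_name=table.sample_name,
        clones=clones,
        identity_threshold=identity_threshold,
        require_same_j=require_same_j,
        sequence_kind=sequence_kind,
        n_excluded=n_excluded,
    )


def _representative(cdr3s: Sequence[str]) -> str:
    """Most frequent CDR3, ties broken lexicographically."""
    counts = Counter(cdr3s)
    top = max(counts.values())
    return min(s for s, c in counts.items() if c == top)


@dataclass
class SharedCloneTable:
    """Clones found in ≥2 samples, with per-combination summary counts."""

    table: pd.DataFrame  # one row per shared clone
    summary: pd.DataFrame  # one row per sample combination
    clones_per_sample: pd.Series


def shared_clones(
    clone_sets: Mapping[str, CloneSet],
    identity_threshold: Optional[float] = None,
    require_same_j: Optional[bool] = None,
) -> SharedCloneTable:
    """Merge clones across samples under the clonotype criteria.

    Two clones (from any samples) merge when they share the V gene
    (and J gene, if required) and their representative CDR3s have equal
    length and identity at or above the threshold; linkage is single.
    Only merged groups spanning ≥2 distinct samples are reported.
    """
    if len(clone_sets) < 2:
        raise UsageError("shared_clones needs at least two samples")
    sets = list(clone_sets.items())
    if identity_threshold is None:
        identity_threshold = sets[0][1].identity_threshold
    if require_same_j is None:
        require_same_j = sets[0][1].require_same_j

    entries = [
        (sample, clone) for sample, cs in sets for clone in cs.clones
    ]
    n = len(entries)
    uf = _UnionFind(n)
    buckets: Dict[tuple, List[int]] = {}
    for k, (_, c) in enumerate(entries):
        key = (c.v_gene, c.j_gene if require_same_j else None, c.cdr3_length)
        buckets.setdefault(key, []).append(k)
    for members in buckets.values():
        if len(members) < 2:
            continue
        reps = [entries[k][1].representative_cdr3 for k in members]
        ident = _identity_matrix(reps)
        ai, bi = np.nonzero(np.triu(ident >= identity_threshold, k=1))
        for a, b in zip(ai, bi):
            uf.union(members[a], members[b])

    components: Dict[int, List[int]] = {}
    for k in range(n):
        components.setdefault(uf.find(k), []).append(k)

    rows = []
    combo_counts: Counter = Counter()
    for root in sorted(components):
        members = components[root]
        samples = sorted({entries[k][0] for k in members})
        if len(samples) < 2:
            continue
        clones = [entries[k][1] for k in members]
        combo = ";".join(samples)
        combo_counts[combo] += 1
        rows.append(
            {
                "samples": combo,
                "n_samples": len(samples),
                "v_gene": clones[0].v_gene,
                "j_gene": clones[0].j_gene or "",
                "cdr3_length": clones[0].cdr3_length,
                "representative_cdr3": _representative(
                    [c.representative_cdr3 for c in clones]
                ),
                "total_size": sum(c.size for c in clones),
                "clone_ids": ";".join(c.clone_id for c in clones),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "samples",
            "n_samples",
            "v_gene",
            "j_gene",
            "cdr3_length",
            "representative_cdr3",
            "total_size",
            "clone_ids",
        ],
    )
    summary = pd.DataFrame(
        sorted(combo_counts.items()), columns=["samples", "n_shared_clones"]
    )
    per_sample = pd.Series(
        {sample: len(cs) for sample, cs in sets}, name="n_clones"
    )
    return SharedCloneTable(table=table, summary=summary, clones_per_sample=per_sample)


def filter_clones(
    clones: CloneSet,
    by: str,
    param,
    rule: str = "all",
) -> CloneSet:
    """Keep clones by size range or by member functionality/frame.

    ``by='size'``: ``param`` is a minimum size or an inclusive
    ``(lo, hi)`` range.  ``by='functionality'`` / ``'junction_frame'``:
    ``param`` names the category; ``rule`` is "all" (every member
    matches) or "majority" (>50% match).
    """
    if by == "size":
        if isinstance(param, (tuple, list)):
            lo, hi = param
            if lo > hi:
                raise UsageError("invalid size bounds: lo > hi")
            kept = [c for c in clones.clones if lo <= c.size <= hi]
        else:
            kept = [c for c in clones.clones if c.size >= param]
    elif by in ("functionality", "junction_frame"):
        if rule not in ("all", "majority"):
            raise UsageError(f"unknown rule {rule!r}")
        attr = "functionality_counts" if by == "functionality" else "junction_frame_counts"

        def _match_count(c: Clone) -> int:
            counts = getattr(c, attr)
            if by == "functionality" and param in ("productive", "unproductive"):
                return sum(
                    v for k, v in counts.items() if k == param or k == f"{param} (see comment)"
                )
            key = param.replace("_", "-") if by == "junction_frame" else param
            return counts.get(key, 0)

        if rule == "all":
            kept = [c for c in clones.clones if _match_count(c) == c.size]
        else:
            kept = [c for c in clones.clones if _match_count(c) > c.size / 2]
    else:
        raise UsageError(f"unknown clone filter {by!r}")
    return CloneSet(
        sample_name=clones.sample_name,
        clones=kept,
        identity_threshold=clones.identity_threshold,
        require_same_j=clones.require_same_j,
        sequence_kind=clones.sequence_kind,
        n_excluded=clones.n_excluded,
    )


def cdr3_length_distribution(
    data,
    stratify_by_functionality: bool = False,
    abundance: str = "relative",
) -> pd.DataFrame:
    """Distribution of CDR3 amino-acid lengths.

    Accepts a repertoire (per-sequence lengths) or a clone set
    (per-clone lengths).  With functionality stratification the output
    gives, per length, the proportion of productive vs unproductive
    sequences (each length row sums to 1 over labelled records).
    """
    if abundance not in ("relative", "absolute"):
        raise UsageError(f"unknown abundance mode {abundance!r}")
    if isinstance(data, CloneSet):
        lengths = pd.Series([c.cdr3_length for c in clones_iter(data)])
        functionality = None
    elif isinstance(data, RepertoireTable):
        mask = data.df["cdr3_aa"].str.len() > 0
        lengths = data.df.loc[mask, "cdr3_aa"].str.len()
        functionality = data.df.loc[mask, "functionality"]
    else:
        raise UsageError("expected a RepertoireTable or CloneSet")
    if lengths.empty:
        raise EmptyInputError("no CDR3 sequences to summarise")

    if not stratify_by_functionality:
        counts = lengths.value_counts().sort_index()
        counts.index.name = "cdr3_length"
        if abundance == "relative":
            counts = counts / counts.sum()
        return counts.to_frame("value")

    if functionality is None:
        raise UsageError("functionality stratification needs a RepertoireTable")
    folded = functionality.map(
        lambda f: "productive"
        if f.startswith("productive")
        else ("unproductive" if f.startswith("unproductive") else None)
    )
    sub = pd.DataFrame({"length": lengths, "functionality": folded}).dropna()
    pivot = sub.pivot_table(
        index="length", columns="functionality", aggfunc="size", fill_value=0
    )
    pivot.index.name = "cdr3_length"
    if abundance == "relative":
        pivot = pivot.div(pivot.sum(axis=1), axis=0)
    return pivot


def clones_iter(cs: CloneSet) -> Iterable[Clone]:
    return iter(cs.clones)


def copy_number_distribution(clones: CloneSet) -> pd.DataFrame:
    """Histogram of clone sizes (copy numbers)."""
    sizes = pd.Series(clones.sizes)
    if sizes.empty:
        raise EmptyInputError("no clones")
    counts = sizes.value_counts().sort_index()
    counts.index.name = "clone_size"
    return counts.to_frame("n_clones")


@dataclass(frozen=True)
class GiniResult:
    value: float
    n_clones: int


def gini_index(clone_sizes: Sequence[float]) -> GiniResult:
    """Gini inequality index of a clone-size distribution.

    G = Σ_i Σ_j |x_i − x_j| / (2 n² x̄): 0 for perfectly even clone
    sizes, approaching 1 when a single clone dominates.  Computed via
    the sorted form, which is algebraically identical to the double sum.
    """
    x = np.asarray(list(clone_sizes), dtype=float)
    if x.size == 0:
        raise EmptyInputError("gini_index needs at least one clone size")
    if np.any(x <= 0):
        raise UsageError("clone sizes must be positive")
    n = x.size
    xs = np.sort(x)
    # Σ_i Σ_j |x_i − x_j| = 2 Σ_i (2i − n − 1) x_(i) with i = 1..n
    i = np.arange(1, n + 1)
    g = float(np.sum((2 * i - n - 1) * xs) / (n * n * xs.mean()))
    return GiniResult(value=g, n_clones=int(n))
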