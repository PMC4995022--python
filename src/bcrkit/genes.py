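"""IMGT gene nomenclature parsing and V(D)J usage statistics.

IMGT names immunoglobulin genes hierarchically: subgroup (IGHV1) →
gene (IGHV1-69) → allele (IGHV1-69*01).  Annotation strings carry a
species prefix ("Homsap"), a functionality marker ("F", "ORF", "P") and
possibly several candidate assignments joined by ", or ".  Usage tables
count sequences per label at a chosen level, either giving each of k
ambiguous candidates a fractional weight 1/k (default, conserves
totals) or crediting only the first candidate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ParseError, UsageError
from .io import NO_RESULTS_MARKER, RepertoireTable

__all__ = [
    "GeneCandidate",
    "GeneLabel",
    "UsageTable",
    "CombinationMatrix",
    "parse_gene_label",
    "gene_usage",
    "gene_combinations",
]

FAMILY_COLUMNS = {"V": "v_gene", "D": "d_gene", "J": "j_gene"}
LEVELS = ("subgroup", "gene", "allele")

_FUNCTIONALITY_MARKERS = {"f", "orf", "p", "(f)", "[f]", "(p)", "[p]", "(orf)", "[orf]"}
_GENE_TOKEN = re.compile(r"^(?:IG[HKL]|TR[ABDG])[VDJ]")
_SUBGROUP_RE = re.compile(r"^([A-Z]+\d+)")
_FAMILY_RE = re.compile(r"^([A-Z]+)")


@dataclass(frozen=True)
class GeneCandidate:
    subgroup: str
    gene: str
    allele: str


@dataclass(frozen=True)
class GeneLabel:
    """A parsed gene annotation; ``candidates`` is ordered as annotated."""

    family: str
    candidates: Tuple[GeneCandidate, ...]

    @property
    def subgroup(self) -> str:
        return self.candidates[0].subgroup

    @property
    def gene(self) -> str:
        return self.candidates[0].gene

    @property
    def allele(self) -> str:
        return self.candidates[0].allele

    def at_level(self, level: str) -> Tuple[str, ...]:
        """Candidate labels at the requested level, duplicates preserved
        in order (coarser levels may collapse candidates)."""
        if level not in LEVELS:
            raise UsageError(f"unknown gene level {level!r}")
        return tuple(getattr(c, level) for c in self.candidates)


def _parse_candidate(token: str) -> GeneCandidate:
    # the gene token is the word carrying the locus prefix; species
    # prefix and functionality markers are simply the other words
    words = [w for w in token.split() if _GENE_TOKEN.match(w)]
    if not words:
        raise ParseError(f"no gene token in {token!r}", raw=token)
    allele = words[0].rstrip(",")
    gene = allele.split("*")[0]
    m = _SUBGROUP_RE.match(gene)
    if m is None:
        raise ParseError(f"cannot extract subgroup from {allele!r}", raw=token)
    return GeneCandidate(subgroup=m.group(1), gene=gene, allele=allele)


def parse_gene_label(raw: str) -> GeneLabel:
    """Parse an IMGT annotation string such as
    ``"Homsap IGHV1-69*01 F, or Homsap IGHV1-69D*01 F"``."""
    text = (raw or "").strip()
    if not text or text.lower() == NO_RESULTS_MARKER:
        raise ParseError(f"unparsable gene annotation {raw!r}", raw=raw)
    candidates = []
    for part in re.split(r",\s*or\s+", text):
        part = part.strip().rstrip(",")
        if part:
            candidates.append(_parse_candidate(part))
    if not candidates:
        raise ParseError(f"unparsable gene annotation {raw!r}", raw=raw)
    fam = _FAMILY_RE.match(candidates[0].subgroup)
    return GeneLabel(family=fam.group(1), candidates=tuple(candidates))


def natural_key(label: str):
    """Sort key ordering IGHV2-5 before IGHV10-1 (numeric runs compared
    as integers)."""
    parts = re.split(r"(\d+)", label)
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p != "")


@dataclass
class UsageTable:
    """Gene usage per sample (columns) and label (rows)."""

    level: str
    abundance: str
    df: pd.DataFrame

    @property
    def samples(self) -> List[str]:
        return list(self.df.columns)

    @property
    def labels(self) -> List[str]:
        return list(self.df.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out.index.name = "label"
        return out


@dataclass
class CombinationMatrix:
    """Joint V(D)J gene-pair abundance; rows = family1, cols = family2."""

    family1: str
    family2: str
    level: str
    abundance: str
    include_na: bool
    df: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out.index.name = self.family1
        return out


def _label_weights(raw: str, level: str, ambiguity: str) -> dict:
    """Map label → weight for one annotation string; {} if unassigned."""
    try:
        label = parse_gene_label(raw)
    except ParseError:
        return {}
    cands = label.at_level(level)
    if ambiguity == "first":
        return {cands[0]: 1.0}
    if ambiguity != "fractional":
        raise UsageError(f"unknown ambiguity mode {ambiguity!r}")
    w = 1.0 / len(cands)
    out: dict = {}
    for c in cands:
        out[c] = out.get(c, 0.0) + w
    return out


def _usage_series(
    rows: Iterable[str], level: str, ambiguity: str, integer_mode: bool
) -> pd.Series:
    counts: dict = {}
    for raw in rows:
        for lab, w in _label_weights(raw, level, ambiguity).items():
            counts[lab] = counts.get(lab, 0.0) + w
    s = pd.Series(counts, dtype=float)
    if integer_mode and np.allclose(s.values, np.round(s.values)):
        s = s.round().astype(float)
    return s


def gene_usage(
    tables,
    family: str = "V",
    level: str = "gene",
    abundance: str = "relative",
    stratify_by: Optional[str] = None,
    ambiguity: str = "fractional",
) -> UsageTable:
    """V(D)J gene usage per sample, optionally stratified.

    Parameters
    ----------
    tables:
        One repertoire or a list of repertoires (multi-sample comparison).
    family:
        "V", "D" or "J".
    level:
        "subgroup", "gene" or "allele".
    abundance:
        "relative" proportions (each column sums to 1 over assigned
        weight) or "absolute" counts.
    stratify_by:
        Optional "functionality" or "junction_frame"; yields one column
        block per stratum, columns named ``sample|stratum``.
    ambiguity:
        "fractional" (1/k per candidate) or "first".
    """
    if isinstance(tables, RepertoireTable):
        tables = [tables]
    if family not in FAMILY_COLUMNS:
        raise UsageError(f"unknown gene family {family!r}")
    if level not in LEVELS:
        raise UsageError(f"unknown gene level {level!r}")
    if abundance not in ("relative", "absolute"):
        raise UsageError(f"unknown abundance mode {abundance!r}")
    col = FAMILY_COLUMNS[family]

    columns = {}
    for table in tables:
        if stratify_by is None:
            groups = {table.sample_name: table.df}
        elif stratify_by in ("functionality", "junction_frame"):
            groups = {
                f"{table.sample_name}|{stratum}": sub
                for stratum, sub in table.df.groupby(table.df[stratify_by].replace("", "null"))
            }
        else:
            raise UsageError(f"unknown stratification {stratify_by!r}")
        for name, sub in groups.items():
            s = _usage_series(sub[col], level, ambiguity, abundance == "absolute")
            if abundance == "relative" and s.sum() > 0:
                s = s / s.sum()
            columns[name] = s

    df = pd.DataFrame(columns).fillna(0.0)
    df = df.reindex(sorted(df.index, key=natural_key))
    return UsageTable(level=level, abundance=abundance, df=df)


def gene_combinations(
    table: RepertoireTable,
    family1: str,
    family2: str,
    level: str = "subgroup",
    abundance: str = "relative",
    include_na: bool = True,
    ambiguity: str = "fractional",
) -> CombinationMatrix:
    """Joint abundance of gene pairs, e.g. IGHV × IGHD combinations.

    Sequences lacking an assignment in either family contribute to the
    "NA" row/column when ``include_na``; otherwise they are dropped
    from the denominator.
    """
    if family1 == family2:
        raise UsageError("family1 and family2 must differ")
    for fam in (family1, family2):
        if fam not in FAMILY_COLUMNS:
            raise UsageError(f"unknown gene family {fam!r}")
    c1, c2 = FAMILY_COLUMNS[family1], FAMILY_COLUMNS[family2]

    cells: dict = {}
    for raw1, raw2 in zip(table.df[c1], table.df[c2]):
        w1 = _label_weights(raw1, level, ambiguity) or {"NA": 1.0}
        w2 = _label_weights(raw2, level, ambiguity) or {"NA": 1.0}
        if not include_na and ("NA" in w1 or "NA" in w2):
            continue
        for l1, a in w1.items():
            for l2, b in w2.items():
                cells[(l1, l2)] = cells.get((l1, l2), 0.0) + a * b

    rows = sorted({k[0] for k in cells} - {"NA"}, key=natural_key)
    cols = sorted({k[1] for k in cells} - {"NA"}, key=natural_key)
    if include_na:
        if any(k[0] == "NA" for k in cells):
            rows.append("NA")
        if any(k[1] == "NA" for k in cells):
            cols.append("NA")
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    for (l1, l2), w in cells.items():
        if l1 in mat.index and l2 in mat.columns:
            mat.loc[l1, l2] = w
    if abundance == "relative":
        total = mat.values.sum()
        if total > 0:
            mat = mat / total
    elif abundance != "absolute":
        raise UsageError(f"unknown abundance mode {abundance!r}")
    return CombinationMatrix(
        family1=family1, family2=family2, level=level,
        abundance=abundance, include_na=include_na, df=mat,
    )
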