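"""Somatic-hypermutation statistics.

The annotator reports V-region point mutations per sequence in compact
notation (``a2>g`` for a silent nucleotide substitution,
``a2>g,S1>T`` when the substitution replaces the germline amino acid).
This module turns those cells into :class:`MutationEvent` lists and
computes per-sequence silent/replacement counts with R/S ratios, the
20×20 germline→mutated amino-acid replacement matrix with
physicochemical-change flags, and the nucleotide composition of the
-3..+3 context around silent mutations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence


import numpy as np
import pandas as pd

from . import _aa_classes as aac
from .errors import EmptyInputError, UsageError
from .io import RepertoireTable

__all__ = [
    "MutationEvent",
    "MutationSummary",
    "ReplacementMatrix",
    "events_from_table",
    "mutation_summary",
    "replacement_aa_matrix",
    "silent_base_context",
]

REGIONS = ("V-REGION", "FR1", "FR2", "FR3", "CDR1", "CDR2")

_REGION_MUT_COLUMNS = {
    "V-REGION": "mut_v_region",
    "FR1": "mut_fr1",
    "CDR1": "mut_cdr1",
    "FR2": "mut_fr2",
    "CDR2": "mut_cdr2",
    "FR3": "mut_fr3",
}
_REGION_SEQ_COLUMNS = {
    "V-REGION": "v_region",
    "FR1": "fr1",
    "CDR1": "cdr1",
    "FR2": "fr2",
    "CDR2": "cdr2",
    "FR3": "fr3",
}

#: compact IMGT-style event: nt change, optional amino-acid change
_EVENT_RE = re.compile(
    r"([acgt])(\d+)>([acgt])(?:\s*,\s*([A-Z*X#])(\d+)>([A-Z*X#]))?"
)

_PLACEHOLDERS = set("*X#")


@dataclass(frozen=True)
class MutationEvent:
    sequence_id: str
    region: str
    position: int  # 1-based within the region
    germline_nt: str
    observed_nt: str
    kind: str  # "silent" or "replacement"
    germline_aa: Optional[str] = None
    observed_aa: Optional[str] = None


def parse_mutation_cell(cell: str, sequence_id: str, region: str) -> List[MutationEvent]:
    """Parse one mutation-table cell into events.

    A substitution is a replacement iff an amino-acid change with
    differing residues is attached; otherwise it is silent.
    """
    events = []
    for m in _EVENT_RE.finditer(cell or ""):
        germ_nt, pos, obs_nt, germ_aa, _aa_pos, obs_aa = m.groups()
        if germ_nt == obs_nt:
            continue
        replacement = germ_aa is not None and germ_aa != obs_aa
        events.append(
            MutationEvent(
                sequence_id=sequence_id,
                region=region,
                position=int(pos),
                germline_nt=germ_nt,
                observed_nt=obs_nt,
                kind="replacement" if replacement else "silent",
                germline_aa=germ_aa if replacement else None,
                observed_aa=obs_aa if replacement else None,
            )
        )
    return events


def events_from_table(table: RepertoireTable, region: str = "V-REGION") -> List[MutationEvent]:
    """All mutation events of a repertoire for one region."""
    if region not in REGIONS:
        raise UsageError(f"unknown region {region!r}")
    col = _REGION_MUT_COLUMNS[region]
    events: List[MutationEvent] = []
    for sid, cell in zip(table.df["sequence_id"], table.df[col]):
        events.extend(parse_mutation_cell(cell, sid, region))
    return events


@dataclass
class MutationSummary:
    """Per-sequence mutation counts plus cohort aggregates.

    ``per_sequence`` has columns n_total/n_silent/n_replacement/rs_ratio
    (rs_ratio is NaN when no silent mutation was observed — kept out of
    the aggregate means rather than reported as infinity).
    """

    region: str
    per_sequence: pd.DataFrame
    aggregate: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.per_sequence.reset_index()


def mutation_summary(
    events: Iterable[MutationEvent],
    region: str = "V-REGION",
    sequence_ids: Optional[Sequence[str]] = None,
) -> MutationSummary:
    """Silent/replacement counts and R/S ratio per sequence and cohort.

    ``sequence_ids`` optionally fixes the cohort (sequences without
    events then count as zero-mutation rows).
    """
    if region not in REGIONS:
        raise UsageError(f"unknown region {region!r}")
    counts: Dict[str, List[int]] = {}
    for ev in events:
        if ev.region != region:
            continue
        row = counts.setdefault(ev.sequence_id, [0, 0])
        row[0 if ev.kind == "silent" else 1] += 1
    ids = list(sequence_ids) if sequence_ids is not None else sorted(counts)
    data = {
        "n_silent": [counts.get(i, [0, 0])[0] for i in ids],
        "n_replacement": [counts.get(i, [0, 0])[1] for i in ids],
    }
    per_seq = pd.DataFrame(data, index=pd.Index(ids, name="sequence_id"))
    per_seq["n_total"] = per_seq["n_silent"] + per_seq["n_replacement"]
    per_seq["rs_ratio"] = np.where(
        per_seq["n_silent"] > 0,
        per_seq["n_replacement"] / per_seq["n_silent"].replace(0, np.nan),
        np.nan,
    )
    per_seq = per_seq[["n_total", "n_silent", "n_replacement", "rs_ratio"]]
    agg = pd.DataFrame(
        {
            "mean": per_seq.mean(numeric_only=True),
            "median": per_seq.median(numeric_only=True),
        }
    )
    return MutationSummary(region=region, per_sequence=per_seq, aggregate=agg)


@dataclass
class ReplacementMatrix:
    """Proportions of replacement mutations from germline (rows) to
    mutated (columns) amino acid, with class-change flags per cell."""

    proportions: pd.DataFrame
    flags: Dict[str, pd.DataFrame]  # hydropathy_change / chemical_change / volume_change
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        out = self.proportions.copy()
        out.index.name = "germline"
        return out


def _flag_matrix(classification: dict) -> pd.DataFrame:
    aas = list(aac.AMINO_ACIDS)
    mat = pd.DataFrame(False, index=aas, columns=aas)
    for a in aas:
        for b in aas:
            mat.loc[a, b] = aac.changes_class(a, b, classification)
    return mat


def replacement_aa_matrix(events: Iterable[MutationEvent]) -> ReplacementMatrix:
    """20×20 amino-acid replacement matrix over all replacement events.

    Cell (a, b) holds the fraction of replacement events mutating
    germline residue a to residue b; the diagonal is structurally zero.
    Events involving placeholder residues ('*', 'X', '#') are dropped.
    Flags mark substitutions crossing IMGT hydropathy, chemical or
    volume classes — a property of the residue pair, not of the data.
    """
    aas = list(aac.AMINO_ACIDS)
    counts = pd.DataFrame(0.0, index=aas, columns=aas)
    n = 0
    for ev in events:
        if ev.kind != "replacement":
            continue
        a, b = ev.germline_aa, ev.observed_aa
        if a in _PLACEHOLDERS or b in _PLACEHOLDERS or a not in aas or b not in aas:
            continue
        counts.loc[a, b] += 1
        n += 1
    if n == 0:
        raise EmptyInputError("no replacement events to summarise")
    flags = {
        "hydropathy_change": _flag_matrix(aac.HYDROPATHY),
        "chemical_change": _flag_matrix(aac.CHEMICAL),
        "volume_change": _flag_matrix(aac.VOLUME),
    }
    return ReplacementMatrix(proportions=counts / n, flags=flags, n_events=n)


def silent_base_context(
    events: Iterable[MutationEvent],
    region_seqs: Mapping[str, str],
    flank: int = 3,
) -> pd.DataFrame:
    """Base composition around silent mutations, offsets −flank..+flank.

    For every silent from→to substitution the bases at the given
    offsets (0 excluded) of the region sequence are tallied; positions
    truncated by a region boundary drop out of that offset's
    denominator.  Returns a long-format frame indexed by
    (mutation, offset) with A/C/G/T proportion columns; offsets with no
    resolvable flank for a mutation type are absent.
    """
    bases = ["A", "C", "G", "T"]
    tallies: Dict[tuple, np.ndarray] = {}
    n_silent = 0
    for ev in events:
        if ev.kind != "silent":
            continue
        n_silent += 1
        seq = (region_seqs.get(ev.sequence_id) or "").upper()
        if not seq:
            continue
        mut = f"{ev.germline_nt}>{ev.observed_nt}"
        for off in range(-flank, flank + 1):
            if off == 0:
                continue
            idx = ev.position - 1 + off
            if 0 <= idx < len(seq) and seq[idx] in bases:
                key = (mut, off)
                vec = tallies.setdefault(key, np.zeros(4))
                vec[bases.index(seq[idx])] += 1
    if n_silent == 0:
        raise EmptyInputError("no silent events to summarise")
    rows = []
    for (mut, off) in sorted(tallies):
        vec = tallies[(mut, off)]
        rows.append((mut, off, *(vec / vec.sum())))
    out = pd.DataFrame(rows, columns=["mutation", "offset", *bases])
    return out.set_index(["mutation", "offset"])
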