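"""Reading, combining and writing IMGT/HighV-QUEST-style annotation tables.

IMGT/HighV-QUEST emits one folder per analysis containing numbered
tab-separated tables (``1_Summary.txt``, ``3_Nt-sequences.txt``,
``5_AA-sequences.txt``, ``7_V-REGION-mutation-and-AA-change-table.txt``,
...).  This module joins the table kinds into a single
:class:`RepertoireTable` keyed by sequence ID, optionally dropping
sequences the annotator marked "no results" (recognised in the
"D-GENE and allele" column), and round-trips repertoires through a flat
TSV representation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .errors import FormatError, UsageError

__all__ = [
    "Functionality",
    "JunctionFrame",
    "SequenceRecord",
    "RepertoireTable",
    "read_repertoire",
    "combine_outputs",
    "write_table",
    "NO_RESULTS_MARKER",
]

#: Marker IMGT writes when a sequence could not be analysed; matched
#: case-insensitively after whitespace trimming (dialects vary).
NO_RESULTS_MARKER = "no results"


class Functionality(str, enum.Enum):
    PRODUCTIVE = "productive"
    PRODUCTIVE_SEE_COMMENT = "productive (see comment)"
    UNPRODUCTIVE = "unproductive"
    UNPRODUCTIVE_SEE_COMMENT = "unproductive (see comment)"
    UNKNOWN = "unknown"
    NO_RESULTS = "no results"


class JunctionFrame(str, enum.Enum):
    IN_FRAME = "in-frame"
    OUT_OF_FRAME = "out-of-frame"
    NULL = "null"


#: canonical column names of the flat representation
CANONICAL_COLUMNS = [
    "sequence_id",
    "functionality",
    "junction_frame",
    "v_gene",
    "d_gene",
    "j_gene",
    "cdr3_nt",
    "cdr3_aa",
    "v_region",
    "fr1",
    "cdr1",
    "fr2",
    "cdr2",
    "fr3",
    "mut_v_region",
    "mut_fr1",
    "mut_cdr1",
    "mut_fr2",
    "mut_cdr2",
    "mut_fr3",
]

#: region-name → canonical column for nucleotide region sequences
REGION_COLUMNS = {
    "V-REGION": "v_region",
    "FR1": "fr1",
    "CDR1": "cdr1",
    "FR2": "fr2",
    "CDR2": "cdr2",
    "FR3": "fr3",
}

_SUMMARY_MAP = {
    "Sequence ID": "sequence_id",
    "Functionality": "functionality",
    "JUNCTION frame": "junction_frame",
    "V-GENE and allele": "v_gene",
    "D-GENE and allele": "d_gene",
    "J-GENE and allele": "j_gene",
}
_NT_MAP = {
    "Sequence ID": "sequence_id",
    "CDR3-IMGT": "cdr3_nt",
    "V-REGION": "v_region",
    "FR1-IMGT": "fr1",
    "CDR1-IMGT": "cdr1",
    "FR2-IMGT": "fr2",
    "CDR2-IMGT": "cdr2",
    "FR3-IMGT": "fr3",
}
_AA_MAP = {
    "Sequence ID": "sequence_id",
    "CDR3-IMGT": "cdr3_aa",
}
_MUT_MAP = {
    "Sequence ID": "sequence_id",
    "V-REGION": "mut_v_region",
    "FR1-IMGT": "mut_fr1",
    "CDR1-IMGT": "mut_cdr1",
    "FR2-IMGT": "mut_fr2",
    "CDR2-IMGT": "mut_cdr2",
    "FR3-IMGT": "mut_fr3",
}

TABLE_KINDS = ("summary", "nt", "aa", "mutation")
_KIND_MAPS = {"summary": _SUMMARY_MAP, "nt": _NT_MAP, "aa": _AA_MAP, "mutation": _MUT_MAP}


@dataclass
class SequenceRecord:
    """One annotated rearrangement, as joined across the table kinds."""

    sequence_id: str
    functionality: Functionality
    junction_frame: JunctionFrame
    v_gene_raw: str
    d_gene_raw: str
    j_gene_raw: str
    cdr3_aa: str
    cdr3_nt: str
    region_seqs: Mapping[str, str] = field(default_factory=dict)


@dataclass
class RepertoireTable:
    """An ordered collection of annotated sequences from one sample.

    The backing frame ``df`` holds one row per sequence with the
    canonical columns; record order is preserved from the input files.
    """

    sample_name: str
    df: pd.DataFrame
    source_tables: frozenset = frozenset()
    n_filtered_no_results: int = 0

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        for c in missing:
            self.df[c] = ""
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)
        if self.df["sequence_id"].duplicated().any():
            dup = self.df["sequence_id"][self.df["sequence_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate sequence ID {dup!r} in table")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RepertoireTable):
            return NotImplemented
        return self.sample_name == other.sample_name and self.df.equals(other.df)

    @property
    def records(self) -> Iterator[SequenceRecord]:
        for row in self.df.itertuples(index=False):
            yield SequenceRecord(
                sequence_id=row.sequence_id,
                functionality=_functionality_enum(row.functionality),
                junction_frame=_frame_enum(row.junction_frame),
                v_gene_raw=row.v_gene,
                d_gene_raw=row.d_gene,
                j_gene_raw=row.j_gene,
                cdr3_aa=row.cdr3_aa,
                cdr3_nt=row.cdr3_nt,
                region_seqs={
                    name: getattr(row, col)
                    for name, col in REGION_COLUMNS.items()
                    if getattr(row, col)
                },
            )

    def subset(self, mask) -> "RepertoireTable":
        """New table with the rows where ``mask`` holds, order preserved."""
        return RepertoireTable(
            sample_name=self.sample_name,
            df=self.df.loc[mask].reset_index(drop=True),
            source_tables=self.source_tables,
        )


def _norm(s) -> str:
    return "" if pd.isna(s) else str(s).strip()


def _functionality_enum(value: str) -> Functionality:
    v = _norm(value).lower()
    for member in Functionality:
        if member.value == v:
            return member
    return Functionality.UNKNOWN


def _frame_enum(value: str) -> JunctionFrame:
    v = _norm(value).lower().replace("_", "-")
    if v == "in-frame":
        return JunctionFrame.IN_FRAME
    if v == "out-of-frame":
        return JunctionFrame.OUT_OF_FRAME
    return JunctionFrame.NULL


def normalize_functionality(value: str) -> str:
    return _functionality_enum(value).value


def normalize_frame(value: str) -> str:
    f = _frame_enum(value)
    return "" if f is JunctionFrame.NULL else f.value


def _sniff_kind(path: Path) -> str | None:
    """Classify an IMGT table file by numbered-filename prefix, falling
    back to header sniffing so renamed exports still load."""
    name = path.name.lower()
    if name[:1].isdigit() and "_" in name:
        body = name.split("_", 1)[1]
        if "summary" in body:
            return "summary"
        if "nt-sequences" in body:
            return "nt"
        if "aa-sequences" in body:
            return "aa"
        if "mutation" in body:
            return "mutation"
    try:
        header = path.open(encoding="utf-8").readline().rstrip("\n").split("\t")
    except OSError:
        return None
    cols = set(header)
    if "Functionality" in cols and "V-GENE and allele" in cols:
        return "summary"
    if "CDR3-IMGT" in cols and "V-REGION" in cols:
        return "nt"
    if "CDR3-IMGT" in cols:
        return "aa"
    if "V-REGION" in cols and "FR1-IMGT" in cols:
        return "mutation"
    return None


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")


def _classify_folder(folder: Path) -> dict:
    kinds: dict[str, Path] = {}
    for p in sorted(folder.iterdir()):
        if not p.is_file() or not p.suffix.lower() in (".txt", ".tsv"):
            continue
        kind = _sniff_kind(p)
        if kind is not None and kind not in kinds:
            kinds[kind] = p
    return kinds


def _is_no_results(value: str) -> bool:
    return _norm(value).lower() == NO_RESULTS_MARKER


def read_repertoire(
    path, filter_no_results: bool = False, sample_name: str | None = None
) -> RepertoireTable:
    """Read an IMGT output folder (or a flat TSV) into a repertoire.

    Table kinds found in a folder are joined on ``Sequence ID``; the
    join keeps every sequence of the summary table (or of the first
    kind found).  With ``filter_no_results``, sequences whose
    "D-GENE and allele" entry is the "no results" marker are dropped
    and their count recorded on the result.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    name = sample_name or path.stem

    if path.is_file():
        df = _read_tsv(path)
        if "sequence_id" in df.columns:
            merged = df
            source = frozenset(["flat"])
        else:
            raise FormatError("flat table lacks required column 'sequence_id'")
    else:
        kinds = _classify_folder(path)
        if not kinds:
            raise FormatError(f"no parsable IMGT tables found in {path}")
        merged = None
        for kind in TABLE_KINDS:
            if kind not in kinds:
                continue
            raw = _read_tsv(kinds[kind])
            colmap = _KIND_MAPS[kind]
            if "Sequence ID" not in raw.columns:
                raise FormatError(f"{kinds[kind].name}: missing required column 'Sequence ID'")
            cols = {src: dst for src, dst in colmap.items() if src in raw.columns}
            part = raw[list(cols)].rename(columns=cols)
            if merged is None:
                merged = part
            else:
                merged = merged.merge(part, on="sequence_id", how="left")
        source = frozenset(kinds)

    merged = merged.fillna("")
    n_dropped = 0
    if filter_no_results and "d_gene" in merged.columns:
        mask = merged["d_gene"].map(_is_no_results)
        n_dropped = int(mask.sum())
        merged = merged.loc[~mask]

    if "functionality" in merged.columns:
        merged = merged.assign(functionality=merged["functionality"].map(normalize_functionality))
    if "junction_frame" in merged.columns:
        merged = merged.assign(junction_frame=merged["junction_frame"].map(normalize_frame))
    merged = merged.reset_index(drop=True)

    table = RepertoireTable(sample_name=name, df=merged, source_tables=source)
    table.n_filtered_no_results = n_dropped
    return table


def combine_outputs(folders: Sequence, project_name: str, out_dir=None) -> Path:
    """Concatenate several IMGT output folders into one project folder.

    Per table kind, rows are concatenated in folder order and sequence
    IDs are prefixed with the originating folder's basename so they stay
    unique.  Headers must be identical across folders for each kind.
    """
    if not folders:
        raise UsageError("combine_outputs needs at least one input folder")
    folders = [Path(f) for f in folders]
    out_root = Path(out_dir) if out_dir is not None else folders[0].parent
    dest = out_root / project_name
    dest.mkdir(parents=True, exist_ok=True)

    # ID prefixes come from folder basenames; repeated basenames get a
    # positional suffix so prefixed IDs stay unique
    prefixes = []
    seen: dict[str, int] = {}
    for folder in folders:
        base = folder.name
        if base in seen:
            seen[base] += 1
            prefixes.append(f"{base}{seen[base]}")
        else:
            seen[base] = 0
            prefixes.append(base)

    per_kind: dict[str, list[pd.DataFrame]] = {}
    filenames: dict[str, str] = {}
    headers: dict[str, list[str]] = {}
    for prefix, folder in zip(prefixes, folders):
        kinds = _classify_folder(folder)
        if not kinds:
            raise FormatError(f"no parsable IMGT tables found in {folder}")
        for kind, fp in kinds.items():
            raw = _read_tsv(fp)
            if kind in headers and list(raw.columns) != headers[kind]:
                extra = set(raw.columns) ^ set(headers[kind])
                raise FormatError(
                    f"header mismatch for {kind} table in {folder.name}: "
                    f"differing column(s) {sorted(extra)}"
                )
            headers.setdefault(kind, list(raw.columns))
            filenames.setdefault(kind, fp.name)
            if "Sequence ID" in raw.columns:
                raw = raw.assign(
                    **{"Sequence ID": prefix + "_" + raw["Sequence ID"].astype(str)}
                )
            per_kind.setdefault(kind, []).append(raw)

    for kind, parts in per_kind.items():
        combined = pd.concat(parts, ignore_index=True)
        combined.to_csv(dest / filenames[kind], sep="\t", index=False, encoding="utf-8")
    return dest


def write_table(table, path) -> Path:
    """Write a repertoire, DataFrame or labelled matrix as a TSV file.

    Repertoires round-trip losslessly through :func:`read_repertoire`;
    square matrices keep their labels in the first row and column.
    """
    path = Path(path)
    if not path.parent.exists():
        raise UsageError(f"parent directory does not exist: {path.parent}")
    if isinstance(table, RepertoireTable):
        table.df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    elif isinstance(table, pd.DataFrame):
        # labelled matrices keep the index; plain record frames do not
        write_index = table.index.name is not None or not isinstance(
            table.index, pd.RangeIndex
        )
        table.to_csv(path, sep="\t", index=write_index, encoding="utf-8")
    elif hasattr(table, "to_frame"):
        write_table(table.to_frame(), path)
    else:
        raise UsageError(f"cannot serialise object of type {type(table).__name__}")
    return path
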