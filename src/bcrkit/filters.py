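"""Functionality and junction-frame summaries and subsetting.

The annotator labels each rearrangement productive/unproductive (with
"(see comment)" variants) or leaves it unknown; the V-J junction is
in-frame or out-of-frame.  Summaries report category counts and
proportions; filters return order-preserving subsets, folding the
"(see comment)" variants into their base category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from .errors import EmptyInputError, UsageError
from .io import RepertoireTable

__all__ = [
    "CategorySummary",
    "functionality_summary",
    "filter_functionality",
    "junction_frame_summary",
    "filter_junction_frame",
]


@dataclass(frozen=True)
class CategorySummary:
    category: str
    count: int
    proportion: float


_PRODUCTIVE = {"productive", "productive (see comment)"}
_UNPRODUCTIVE = {"unproductive", "unproductive (see comment)"}
_IN_FRAME = {"in-frame"}
_OUT_OF_FRAME = {"out-of-frame"}


def _summarise(values, abundance: str) -> List[CategorySummary]:
    if len(values) == 0:
        raise EmptyInputError("cannot summarise an empty table")
    counts = values.value_counts()
    total = int(counts.sum())
    out = []
    for cat, n in counts.items():
        prop = n / total
        out.append(
            CategorySummary(category=str(cat), count=int(n), proportion=float(prop))
        )
    if abundance not in ("relative", "absolute"):
        raise UsageError(f"unknown abundance mode {abundance!r}")
    return out


def functionality_summary(
    table: RepertoireTable, abundance: str = "relative"
) -> List[CategorySummary]:
    """Counts and proportions per observed functionality category.

    "(see comment)" variants are reported as their own categories.
    """
    return _summarise(table.df["functionality"], abundance)


def junction_frame_summary(
    table: RepertoireTable, abundance: str = "relative"
) -> List[CategorySummary]:
    """Counts/proportions per junction-frame category; blank frames form
    their own ``null`` category."""
    frames = table.df["junction_frame"].replace("", "null")
    return _summarise(frames, abundance)


def filter_functionality(table: RepertoireTable, keep: str) -> RepertoireTable:
    """Subset to productive, unproductive or any-labelled sequences.

    ``any_labeled`` drops only unknown and no-results records.  Record
    order and IDs are preserved; an empty result is not an error.
    """
    col = table.df["functionality"]
    if keep == "productive":
        mask = col.isin(_PRODUCTIVE)
    elif keep == "unproductive":
        mask = col.isin(_UNPRODUCTIVE)
    elif keep == "any_labeled":
        mask = col.isin(_PRODUCTIVE | _UNPRODUCTIVE)
    else:
        raise UsageError(f"unknown functionality filter {keep!r}")
    return table.subset(mask)


def filter_junction_frame(table: RepertoireTable, keep: str) -> RepertoireTable:
    """Subset by junction frame; ``any_labeled`` excludes records whose
    frame the annotator left blank."""
    col = table.df["junction_frame"]
    if keep == "in_frame":
        mask = col.isin(_IN_FRAME)
    elif keep == "out_of_frame":
        mask = col.isin(_OUT_OF_FRAME)
    elif keep == "any_labeled":
        mask = col.isin(_IN_FRAME | _OUT_OF_FRAME)
    else:
        raise UsageError(f"unknown junction-frame filter {keep!r}")
    return table.subset(mask)
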