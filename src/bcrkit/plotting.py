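"""Figure rendering for the analysis results.

Each plot kind maps to one result type: gene-combination heatmaps with
average-linkage dendrograms, the amino-acid replacement matrix with
physicochemical-change markers, CDR3-length bar charts, per-length
diversity profiles (mean ± sd), Gini-index bars and PCoA scatter plots
whose axes carry the explained-variance percentages.  Output is
deterministic: fixed style, no timestamps embedded, so identical specs
yield identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .clonotypes import GiniResult
from .distances import PCoAResult
from .diversity import DiversityProfile
from .errors import UsageError
from .genes import CombinationMatrix
from .mutations import ReplacementMatrix

__all__ = ["PlotSpec", "render_figure"]

PLOT_KINDS = (
    "gene_comb_heatmap",
    "aa_mutation_matrix",
    "cdr3_length_bars",
    "diversity_profile",
    "gini_bars",
    "pcoa_scatter",
)

_EXPECTED_TYPES = {
    "gene_comb_heatmap": CombinationMatrix,
    "aa_mutation_matrix": ReplacementMatrix,
    "cdr3_length_bars": pd.DataFrame,
    "diversity_profile": (DiversityProfile, pd.DataFrame),
    "gini_bars": dict,
    "pcoa_scatter": PCoAResult,
}

plt.rcParams["svg.hashsalt"] = "bcrkit"


@dataclass
class PlotSpec:
    kind: str
    data: Any
    output_path: Path
    options: Dict[str, Any] = field(default_factory=dict)


def _save(fig, path: Path):
    path = Path(path)
    kwargs = {}
    if path.suffix.lower() == ".pdf":
        kwargs["metadata"] = {"CreationDate": None}
    elif path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, **kwargs)
    plt.close(fig)
    return path


def _heatmap_with_dendrograms(mat: pd.DataFrame, title: str, cmap: str):
    values = mat.values.astype(float)
    fig = plt.figure(figsize=(8, 7))
    ax_row = fig.add_axes([0.05, 0.1, 0.12, 0.6])
    ax_col = fig.add_axes([0.2, 0.75, 0.6, 0.15])
    ax_hm = fig.add_axes([0.2, 0.1, 0.6, 0.6])
    ax_cb = fig.add_axes([0.84, 0.1, 0.03, 0.6])

    row_order = np.arange(values.shape[0])
    col_order = np.arange(values.shape[1])
    if values.shape[0] > 1:
        zl = hierarchy.linkage(values, method="average", metric="euclidean")
        dr = hierarchy.dendrogram(zl, orientation="left", ax=ax_row, no_labels=True,
                                  link_color_func=lambda _: "black")
        row_order = dr["leaves"][::-1]
    if values.shape[1] > 1:
        zc = hierarchy.linkage(values.T, method="average", metric="euclidean")
        dc = hierarchy.dendrogram(zc, ax=ax_col, no_labels=True,
                                  link_color_func=lambda _: "black")
        col_order = dc["leaves"]
    ax_row.axis("off")
    ax_col.axis("off")

    ordered = values[np.ix_(row_order, col_order)]
    im = ax_hm.imshow(ordered, aspect="auto", cmap=cmap)
    ax_hm.set_xticks(range(len(col_order)))
    ax_hm.set_xticklabels([str(mat.columns[i]) for i in col_order], rotation=90, fontsize=7)
    ax_hm.set_yticks(range(len(row_order)))
    ax_hm.set_yticklabels([str(mat.index[i]) for i in row_order], fontsize=7)
    fig.colorbar(im, cax=ax_cb)
    ax_col.set_title(title)
    return fig


def render_figure(spec: PlotSpec) -> Path:
    """Render one figure; the input data is never mutated."""
    if spec.kind not in PLOT_KINDS:
        raise UsageError(f"unknown plot kind {spec.kind!r}")
    expected = _EXPECTED_TYPES[spec.kind]
    if not isinstance(spec.data, expected):
        raise UsageError(
            f"plot kind {spec.kind!r} expects {expected}, got {type(spec.data).__name__}"
        )
    opts = spec.options
    title = opts.get("title", "")

    if spec.kind == "gene_comb_heatmap":
        fig = _heatmap_with_dendrograms(spec.data.df, title, opts.get("cmap", "Blues"))

    elif spec.kind == "aa_mutation_matrix":
        rm: ReplacementMatrix = spec.data
        fig, ax = plt.subplots(figsize=(7, 6.5))
        im = ax.imshow(rm.proportions.values * 100, cmap=opts.get("cmap", "Greys"))
        flag = rm.flags[opts.get("flag", "hydropathy_change")]
        ys, xs = np.nonzero(flag.values & (rm.proportions.values > 0))
        ax.scatter(xs, ys, s=12, color="orange", zorder=3)
        aas = list(rm.proportions.index)
        ax.set_xticks(range(len(aas)))
        ax.set_xticklabels(aas, fontsize=7)
        ax.set_yticks(range(len(aas)))
        ax.set_yticklabels(aas, fontsize=7)
        ax.set_xlabel("mutated amino acid")
        ax.set_ylabel("germline amino acid")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="% of replacement mutations")

    elif spec.kind == "cdr3_length_bars":
        df: pd.DataFrame = spec.data
        fig, ax = plt.subplots(figsize=(7, 4))
        if df.shape[1] == 1:
            ax.bar(df.index.astype(float), df.iloc[:, 0].values, color="darkblue")
            ax.set_ylabel("proportion")
        else:
            bottom = np.zeros(len(df))
            colors = opts.get("colors", ["orange", "darkblue", "gray"])
            for color, col in zip(colors, df.columns):
                ax.bar(df.index.astype(float), df[col].values, bottom=bottom,
                       label=str(col), color=color)
                bottom += df[col].values
            ax.legend()
            ax.set_ylabel("proportion per length")
        ax.set_xlabel("CDR3 length (aa)")
        ax.set_title(title)

    elif spec.kind == "diversity_profile":
        fig, ax = plt.subplots(figsize=(7, 4))
        if isinstance(spec.data, DiversityProfile):
            prof = spec.data
            lengths = prof.lengths
            means = [prof.mean[L] for L in lengths]
            sds = [prof.sd[L] for L in lengths]
            ax.errorbar(lengths, means, yerr=sds, fmt="o-", capsize=3)
            ax.set_ylabel(f"true diversity (q={prof.order:g})")
        else:  # comparison frame from compare_diversity
            comp = spec.data
            samples = comp.columns.get_level_values("sample").unique()
            for sample in samples:
                ax.errorbar(
                    comp.index, comp[(sample, "mean")], yerr=comp[(sample, "sd")],
                    fmt="o-", capsize=3, label=str(sample),
                )
            ax.legend()
            ax.set_ylabel("mean true diversity")
        ax.set_xlabel("sequence length (aa)")
        ax.set_title(title)

    elif spec.kind == "gini_bars":
        data = {
            k: (v.value if isinstance(v, GiniResult) else float(v))
            for k, v in spec.data.items()
        }
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(list(data), list(data.values()), color="darkblue")
        ax.set_ylim(0, 1)
        ax.set_ylabel("Gini index")
        ax.set_title(title)

    else:  # pcoa_scatter
        res: PCoAResult = spec.data
        if res.coordinates.shape[1] < 2:
            raise UsageError("pcoa_scatter needs at least two positive axes")
        fig, ax = plt.subplots(figsize=(5.5, 5))
        groups = opts.get("groups")
        if groups is None:
            ax.scatter(res.coordinates[:, 0], res.coordinates[:, 1], color="darkblue")
        else:
            for g in sorted(set(groups)):
                mask = np.array([x == g for x in groups])
                ax.scatter(res.coordinates[mask, 0], res.coordinates[mask, 1], label=str(g))
            ax.legend()
        ax.set_xlabel(f"axis 1 ({100 * res.explained_fraction[0]:.1f}%)")
        ax.set_ylabel(f"axis 2 ({100 * res.explained_fraction[1]:.1f}%)")
        ax.set_title(title)

    return _save(fig, spec.output_path)
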