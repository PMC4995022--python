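"""Synthetic IMGT/HighV-QUEST-style repertoires with planted ground truth.

The generator emits the four annotation tables the reader understands
(Summary, nucleotide sequences, amino-acid sequences, V-region mutation
table) for a repertoire with known clonal structure: each clone owns a
V/D/J gene assignment and a germline CDR3, members copy the clone CDR3
with at most a configured number of point substitutions, and V-region
somatic mutations are planted per position and classified silent or
replacement through the standard genetic code.  Everything downstream
— clone assembly, mutation statistics, gene usage, diversity — can
therefore be checked against exact bookkeeping.

It deliberately does not model VDJ recombination mechanics
(junctional insertions, exonuclease trimming); clones are planted
directly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import UsageError

__all__ = ["GeneratorConfig", "GroundTruth", "generate_repertoire", "GERMLINE_V", "GERMLINE_D", "GERMLINE_J"]

GENETIC_CODE = {
    "".join(c): aa
    for c, aa in zip(
        itertools.product("TCAG", repeat=3),
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
}
_NON_STOP_CODONS = [c for c, aa in GENETIC_CODE.items() if aa != "*"]
_BASES = "ACGT"

#: V-region layout (nt, codon-aligned): FR1 | CDR1 | FR2 | CDR2 | FR3
V_REGION_LAYOUT = [("FR1", 18), ("CDR1", 9), ("FR2", 15), ("CDR2", 9), ("FR3", 21)]
V_REGION_LENGTH = sum(n for _, n in V_REGION_LAYOUT)


def translate(nt: str) -> str:
    return "".join(
        GENETIC_CODE.get(nt[i : i + 3].upper(), "X") for i in range(0, len(nt) - 2, 3)
    )


def _make_orf(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _build_catalog():
    """Small built-in germline set with IMGT-style labels.

    Sequences are arbitrary open reading frames drawn once from a fixed
    generator; only their labels and frame consistency matter.
    """
    rng = np.random.default_rng(20160823)
    v_labels = [
        "IGHV1-2*01", "IGHV1-69*01", "IGHV2-5*01", "IGHV3-23*01", "IGHV3-30*01",
        "IGHV4-34*01", "IGHV4-59*01", "IGHV5-51*01", "IGHV6-1*01", "IGHV7-4-1*01",
    ]
    d_labels = ["IGHD1-1*01", "IGHD2-2*01", "IGHD3-10*01", "IGHD4-17*01", "IGHD5-12*01"]
    j_labels = ["IGHJ1*01", "IGHJ2*01", "IGHJ3*02", "IGHJ4*02", "IGHJ5*02", "IGHJ6*03"]
    v = {lab: _make_orf(rng, V_REGION_LENGTH // 3) for lab in v_labels}
    d = {lab: _make_orf(rng, 5) for lab in d_labels}
    j = {lab: _make_orf(rng, 6) for lab in j_labels}
    return v, d, j


GERMLINE_V, GERMLINE_D, GERMLINE_J = _build_catalog()


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic repertoire.

    Defaults describe a moderately expanded repertoire: power-law clone
    sizes, CDR3s of 8-16 amino acids, a V-region point-mutation rate of
    3 per kilobase (light hypermutation), mostly productive sequences,
    and a small fraction of unanalysable rows.
    """

    n_sequences: int = 1000
    n_clones: int = 50
    clone_size_distribution: str = "power_law"  # or "uniform"
    power_law_alpha: float = 2.0
    cdr3_length_range: Tuple[int, int] = (8, 16)  # amino acids
    per_position_mutation_rate: float = 0.003  # V-region nt substitutions
    cdr3_mutation_prob: float = 0.3  # member carries a mutated CDR3
    max_cdr3_mutations: int = 1  # nt substitutions per member CDR3
    functionality_mix: Dict[str, float] = field(
        default_factory=lambda: {"productive": 0.85, "unproductive": 0.12, "unknown": 0.03}
    )
    no_results_fraction: float = 0.02  # extra rows marked "No results"
    ambiguous_v_fraction: float = 0.05  # rows with a second V candidate
    seed: int = 0

    def validate(self):
        if self.n_clones < 1 or self.n_clones > self.n_sequences:
            raise UsageError("need 1 <= n_clones <= n_sequences")
        lo, hi = self.cdr3_length_range
        if lo < 4 or hi < lo:
            raise UsageError("invalid cdr3_length_range")
        probs = [
            self.per_position_mutation_rate,
            self.cdr3_mutation_prob,
            self.no_results_fraction,
            self.ambiguous_v_fraction,
            *self.functionality_mix.values(),
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise UsageError("probabilities must lie in [0, 1]")
        if abs(sum(self.functionality_mix.values()) - 1.0) > 1e-9:
            raise UsageError("functionality_mix must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth: clone membership, gene labels, mutation events."""

    sequences: pd.DataFrame  # one row per emitted sequence
    events: pd.DataFrame  # planted V-region mutation events
    clone_sizes: pd.Series  # planted clone id → size
    config: GeneratorConfig


def _clone_sizes(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Positive sizes summing to n_sequences."""
    sizes = np.ones(cfg.n_clones, dtype=int)
    remaining = cfg.n_sequences - cfg.n_clones
    if remaining > 0:
        if cfg.clone_size_distribution == "uniform":
            weights = np.ones(cfg.n_clones)
        elif cfg.clone_size_distribution == "power_law":
            weights = (np.arange(1, cfg.n_clones + 1)) ** (-cfg.power_law_alpha)
        else:
            raise UsageError(
                f"unknown clone_size_distribution {cfg.clone_size_distribution!r}"
            )
        sizes += rng.multinomial(remaining, weights / weights.sum())
    return sizes


def _mutate_cdr3(nt: str, n_mut: int, rng: np.random.Generator) -> str:
    """Apply nt substitutions, re-drawing any that create a stop codon."""
    seq = list(nt)
    for _ in range(n_mut):
        for _attempt in range(20):
            pos = int(rng.integers(0, len(seq)))
            old = seq[pos]
            new = rng.choice([b for b in _BASES if b != old])
            trial = seq.copy()
            trial[pos] = new
            codon_start = 3 * (pos // 3)
            if GENETIC_CODE["".join(trial[codon_start : codon_start + 3])] != "*":
                seq = trial
                break
    return "".join(seq)


def _plant_v_mutations(germ: str, rate: float, rng: np.random.Generator):
    """Bernoulli(rate) substitution per position; each event classified
    against the germline codon with only that substitution applied."""
    seq = list(germ)
    events = []
    hit = np.nonzero(rng.random(len(germ)) < rate)[0]
    for pos in hit:
        old = germ[pos]
        new = str(rng.choice([b for b in _BASES if b != old]))
        seq[pos] = new
        codon_start = 3 * (pos // 3)
        germ_codon = germ[codon_start : codon_start + 3]
        mut_codon = germ_codon[: pos - codon_start] + new + germ_codon[pos - codon_start + 1 :]
        germ_aa = GENETIC_CODE[germ_codon]
        obs_aa = GENETIC_CODE[mut_codon]
        events.append(
            {
                "position": int(pos) + 1,
                "germline_nt": old.lower(),
                "observed_nt": new.lower(),
                "kind": "silent" if germ_aa == obs_aa else "replacement",
                "germline_aa": germ_aa,
                "observed_aa": obs_aa,
                "aa_position": pos // 3 + 1,
            }
        )
    return "".join(seq), events


def _region_of(position: int) -> Tuple[str, int]:
    """Map a 1-based V-region position to (region name, local position)."""
    offset = 0
    for name, length in V_REGION_LAYOUT:
        if position <= offset + length:
            return name, position - offset
        offset += length
    raise ValueError(position)


def _format_events(events: List[dict]) -> Dict[str, str]:
    """Render planted events as compact mutation-table cells."""
    def fmt(ev, pos, aa_pos):
        token = f"{ev['germline_nt']}{pos}>{ev['observed_nt']}"
        if ev["kind"] == "replacement":
            token += f",{ev['germline_aa']}{aa_pos}>{ev['observed_aa']}"
        return token

    cells = {"V-REGION": "; ".join(fmt(e, e["position"], e["aa_position"]) for e in events)}
    by_region: Dict[str, List[str]] = {}
    for e in events:
        region, local = _region_of(e["position"])
        by_region.setdefault(region, []).append(fmt(e, local, (local - 1) // 3 + 1))
    for name, _ in V_REGION_LAYOUT:
        cells[name] = "; ".join(by_region.get(name, []))
    return cells


def generate_repertoire(
    config: GeneratorConfig, out_dir, folder_name: str = "synthetic_imgt"
) -> Tuple[Path, GroundTruth]:
    """Write a synthetic IMGT-style folder; return its path and truth.

    Identical config and seed produce byte-identical folders.  Clones
    sharing a (V gene, J gene, CDR3 length) key are kept at least two
    thirds apart in CDR3 amino-acid identity, so with at most one
    substitution per member the planted partition stays recoverable at
    practical clustering thresholds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    dest = out_dir / folder_name
    dest.mkdir(parents=True, exist_ok=True)

    v_labels = list(GERMLINE_V)
    d_labels = list(GERMLINE_D)
    j_labels = list(GERMLINE_J)

    sizes = _clone_sizes(config, rng)
    lo, hi = config.cdr3_length_range

    # clone identities, with separation between same-key clones
    clones = []
    key_cdr3: Dict[tuple, List[str]] = {}
    for cid in range(config.n_clones):
        v = v_labels[rng.integers(len(v_labels))]
        d = d_labels[rng.integers(len(d_labels))]
        j = j_labels[rng.integers(len(j_labels))]
        length = int(rng.integers(lo, hi + 1))
        key = (v.split("*")[0], j.split("*")[0], length)
        for _attempt in range(200):
            cdr3_nt = _make_orf(rng, length)
            aa = translate(cdr3_nt)
            min_dist = min(
                (sum(x != y for x, y in zip(aa, other)) for other in key_cdr3.get(key, [])),
                default=length,
            )
            if min_dist >= max(3, (2 * length) // 3):
                break
        key_cdr3.setdefault(key, []).append(aa)
        clones.append({"clone": cid, "v": v, "d": d, "j": j, "cdr3_nt": cdr3_nt})

    func_names = list(config.functionality_mix)
    func_probs = np.array([config.functionality_mix[k] for k in func_names])

    rows = []
    truth_rows = []
    event_rows = []
    seq_counter = 0
    for clone, size in zip(clones, sizes):
        germ_v_seq = GERMLINE_V[clone["v"]]
        for _member in range(size):
            sid = f"seq{seq_counter:06d}"
            seq_counter += 1
            cdr3_nt = clone["cdr3_nt"]
            if rng.random() < config.cdr3_mutation_prob:
                cdr3_nt = _mutate_cdr3(cdr3_nt, config.max_cdr3_mutations, rng)
            cdr3_aa = translate(cdr3_nt)
            v_seq, events = _plant_v_mutations(
                germ_v_seq, config.per_position_mutation_rate, rng
            )
            functionality = str(rng.choice(func_names, p=func_probs))
            if functionality == "productive":
                frame = "in-frame"
            elif functionality == "unproductive":
                frame = "out-of-frame" if rng.random() < 0.7 else "in-frame"
            else:
                frame = ""
            v_string = f"Homsap {clone['v']} F"
            if rng.random() < config.ambiguous_v_fraction:
                gene = clone["v"].split("*")[0]
                v_string += f", or Homsap {gene}*02 F"
            cells = _format_events(events)
            offset = 0
            region_seqs = {}
            for name, length in V_REGION_LAYOUT:
                region_seqs[name] = v_seq[offset : offset + length]
                offset += length
            rows.append(
                {
                    "sequence_id": sid,
                    "functionality": functionality,
                    "junction_frame": frame,
                    "v_string": v_string,
                    "d_string": f"Homsap {clone['d']} F",
                    "j_string": f"Homsap {clone['j']} F",
                    "cdr3_nt": cdr3_nt,
                    "cdr3_aa": cdr3_aa,
                    "v_region": v_seq,
                    **{f"region_{k}": v for k, v in region_seqs.items()},
                    **{f"mut_{k}": v for k, v in cells.items()},
                }
            )
            truth_rows.append(
                {
                    "sequence_id": sid,
                    "clone": clone["clone"],
                    "v_gene": clone["v"].split("*")[0],
                    "d_gene": clone["d"].split("*")[0],
                    "j_gene": clone["j"].split("*")[0],
                    "cdr3_aa": cdr3_aa,
                    "functionality": functionality,
                    "junction_frame": frame,
                    "n_silent": sum(e["kind"] == "silent" for e in events),
                    "n_replacement": sum(e["kind"] == "replacement" for e in events),
                }
            )
            for e in events:
                event_rows.append({"sequence_id": sid, "region": "V-REGION", **e})

    # unanalysable rows ("No results") on top of the planted repertoire
    n_no_results = int(round(config.no_results_fraction * config.n_sequences))
    for _ in range(n_no_results):
        sid = f"seq{seq_counter:06d}"
        seq_counter += 1
        rows.append(
            {
                "sequence_id": sid,
                "functionality": "No results",
                "junction_frame": "",
                "v_string": "",
                "d_string": "No results",
                "j_string": "",
                "cdr3_nt": "",
                "cdr3_aa": "",
                "v_region": "",
                **{f"region_{name}": "" for name, _ in V_REGION_LAYOUT},
                "mut_V-REGION": "",
                **{f"mut_{name}": "" for name, _ in V_REGION_LAYOUT},
            }
        )

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    frame_df = pd.DataFrame(rows)
    frame_df.insert(0, "Sequence number", np.arange(1, len(frame_df) + 1))

    summary = frame_df[
        ["Sequence number", "sequence_id", "functionality", "v_string", "d_string", "j_string", "junction_frame"]
    ].rename(
        columns={
            "sequence_id": "Sequence ID",
            "functionality": "Functionality",
            "v_string": "V-GENE and allele",
            "d_string": "D-GENE and allele",
            "j_string": "J-GENE and allele",
            "junction_frame": "JUNCTION frame",
        }
    )
    nt = frame_df[
        ["Sequence number", "sequence_id", "v_region"]
        + [f"region_{name}" for name, _ in V_REGION_LAYOUT]
        + ["cdr3_nt"]
    ].rename(
        columns={
            "sequence_id": "Sequence ID",
            "v_region": "V-REGION",
            "cdr3_nt": "CDR3-IMGT",
            **{f"region_{name}": f"{name}-IMGT" for name, _ in V_REGION_LAYOUT},
        }
    )
    aa = frame_df[["Sequence number", "sequence_id", "cdr3_aa"]].rename(
        columns={"sequence_id": "Sequence ID", "cdr3_aa": "CDR3-IMGT"}
    )
    mut = frame_df[
        ["Sequence number", "sequence_id", "mut_V-REGION"]
        + [f"mut_{name}" for name, _ in V_REGION_LAYOUT]
    ].rename(
        columns={
            "sequence_id": "Sequence ID",
            "mut_V-REGION": "V-REGION",
            **{f"mut_{name}": f"{name}-IMGT" for name, _ in V_REGION_LAYOUT},
        }
    )
    summary.to_csv(dest / "1_Summary.txt", sep="\t", index=False)
    nt.to_csv(dest / "3_Nt-sequences.txt", sep="\t", index=False)
    aa.to_csv(dest / "5_AA-sequences.txt", sep="\t", index=False)
    mut.to_csv(dest / "7_V-REGION-mutation-and-AA-change-table.txt", sep="\t", index=False)

    truth = GroundTruth(
        sequences=pd.DataFrame(truth_rows),
        events=pd.DataFrame(
            event_rows,
            columns=[
                "sequence_id", "region", "position", "germline_nt", "observed_nt",
                "kind", "germline_aa", "observed_aa", "aa_position",
            ],
        ),
        clone_sizes=pd.Series(sizes, index=pd.RangeIndex(config.n_clones, name="clone")),
        config=config,
    )
    truth.sequences.to_csv(dest / "ground_truth.tsv", sep="\t", index=False)
    cfg_dict = asdict(config)
    cfg_dict["cdr3_length_range"] = list(config.cdr3_length_range)
    (dest / "config.json").write_text(json.dumps(cfg_dict, indent=2))
    return dest, truth
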