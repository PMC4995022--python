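"""Shared fixtures: tiny hand-built repertoires and synthetic folders."""

from __future__ import annotations

import pandas as pd
import pytest

from bcrkit.io import RepertoireTable
from bcrkit.synth import GeneratorConfig, generate_repertoire


def make_table(rows, sample_name="sample"):
    """Build a RepertoireTable from a list of partial row dicts."""
    df = pd.DataFrame(rows)
    if "sequence_id" not in df.columns:
        df.insert(0, "sequence_id", [f"s{i}" for i in range(len(rows))])
    return RepertoireTable(sample_name=sample_name, df=df.fillna(""))


@pytest.fixture
def toy_table():
    """6 productive + 4 unproductive sequences with mixed frames."""
    rows = []
    for i in range(6):
        rows.append(
            {
                "functionality": "productive",
                "junction_frame": "in-frame",
                "v_gene": "Homsap IGHV1-69*01 F",
                "j_gene": "Homsap IGHJ4*02 F",
                "d_gene": "Homsap IGHD2-2*01 F",
                "cdr3_aa": "CARDYW",
                "cdr3_nt": "tgtgcgagagattactgg",
            }
        )
    for i in range(4):
        rows.append(
            {
                "functionality": "unproductive",
                "junction_frame": "out-of-frame",
                "v_gene": "Homsap IGHV3-23*01 F",
                "j_gene": "Homsap IGHJ6*03 F",
                "d_gene": "Homsap IGHD1-1*01 F",
                "cdr3_aa": "CAKGW",
                "cdr3_nt": "tgtgcgaaagggtgg",
            }
        )
    return make_table(rows)


@pytest.fixture(scope="session")
def synth_folder(tmp_path_factory):
    """A clean synthetic repertoire (no CDR3 mutations) plus its truth."""
    cfg = GeneratorConfig(
        n_sequences=400, n_clones=25, seed=11, cdr3_mutation_prob=0.0,
        per_position_mutation_rate=0.01,
    )
    path, truth = generate_repertoire(cfg, tmp_path_factory.mktemp("synth"))
    return path, truth


@pytest.fixture(scope="session")
def mutated_synth_folder(tmp_path_factory):
    """Synthetic repertoire whose members carry CDR3 point mutations."""
    cfg = GeneratorConfig(
        n_sequences=400, n_clones=25, seed=12, cdr3_mutation_prob=0.5,
        per_position_mutation_rate=0.005,
    )
    path, truth = generate_repertoire(cfg, tmp_path_factory.mktemp("synthmut"))
    return path, truth
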