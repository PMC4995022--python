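"""Clonotype assembly, shared clones, clone filters, Gini index."""

import numpy as np
import pytest

from bcrkit.clonotypes import (
    assemble_clones,
    cdr3_length_distribution,
    copy_number_distribution,
    filter_clones,
    gini_index,
    shared_clones,
)
from bcrkit.errors import EmptyInputError, UsageError
from bcrkit.io import read_repertoire

from conftest import make_table
from oracles import clones_by_exact_key, gini_double_sum, shared_combinations_bruteforce


def _seq(sid, cdr3, v="IGHV1-69*01", j="IGHJ4*02", functionality="productive",
         frame="in-frame"):
    return {
        "sequence_id": sid,
        "cdr3_aa": cdr3,
        "v_gene": f"Homsap {v} F",
        "j_gene": f"Homsap {j} F",
        "functionality": functionality,
        "junction_frame": frame,
    }


class TestAssembleClones:
    def test_identical_cdr3_single_clone(self):
        t = make_table([_seq(f"s{i}", "CARDYW") for i in range(3)])
        cs = assemble_clones(t, identity_threshold=100)
        assert len(cs) == 1 and cs.clones[0].size == 3

    def test_different_v_genes_never_merge(self):
        t = make_table([_seq("a", "CARDYW", v="IGHV1-69*01"),
                        _seq("b", "CARDYW", v="IGHV3-23*01")])
        cs = assemble_clones(t, identity_threshold=100)
        assert len(cs) == 2

    def test_threshold_straddles_single_mismatch(self):
        # length 7, 1 mismatch → identity 6/7 = 85.7%
        t = make_table([_seq("a", "CARDYWF"), _seq("b", "CARDYWW")])
        assert len(assemble_clones(t, identity_threshold=85)) == 1
        assert len(assemble_clones(t, identity_threshold=90)) == 2

    def test_same_j_requirement(self):
        t = make_table([_seq("a", "CARDYW", j="IGHJ4*02"),
                        _seq("b", "CARDYW", j="IGHJ6*03")])
        assert len(assemble_clones(t, require_same_j=True)) == 2
        assert len(assemble_clones(t, require_same_j=False)) == 1

    def test_invalid_threshold(self):
        t = make_table([_seq("a", "CARDYW")])
        for bad in (0, -1, 101):
            with pytest.raises(UsageError):
                assemble_clones(t, identity_threshold=bad)

    def test_empty_cdr3_excluded_and_counted(self):
        t = make_table([_seq("a", "CARDYW"), _seq("b", "")])
        cs = assemble_clones(t)
        assert len(cs) == 1 and cs.n_excluded == 1

    def test_exact_threshold_matches_hash_grouping_oracle(self, synth_folder):
        path, truth = synth_folder
        table = read_repertoire(path, filter_no_results=True)
        cs = assemble_clones(table, identity_threshold=100)
        got = {frozenset(c.member_ids) for c in cs.clones}
        records = [
            (r.sequence_id, r.v_gene, r.j_gene, r.cdr3_aa)
            for r in truth.sequences.itertuples(index=False)
        ]
        assert got == clones_by_exact_key(records)

    def test_size_conservation(self, mutated_synth_folder):
        path, truth = mutated_synth_folder
        table = read_repertoire(path, filter_no_results=True)
        cs = assemble_clones(table, identity_threshold=80)
        assert sum(cs.sizes) + cs.n_excluded == len(table)

    def test_lower_threshold_never_more_clones(self, mutated_synth_folder):
        path, _ = mutated_synth_folder
        table = read_repertoire(path, filter_no_results=True)
        counts = [
            len(assemble_clones(table, identity_threshold=th))
            for th in (100, 90, 80, 70)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_representative_tie_breaks_lexicographically(self):
        t = make_table([_seq("a", "CARDYWF"), _seq("b", "CARDYWW")])
        cs = assemble_clones(t, identity_threshold=85)
        assert cs.clones[0].representative_cdr3 == "CARDYWF"


class TestSharedClones:
    def _sets(self, spec):
        """spec: sample → list of cdr3 (all same V/J)."""
        return {
            name: assemble_clones(
                make_table([_seq(f"{name}{i}", c) for i, c in enumerate(cdr3s)],
                           sample_name=name)
            )
            for name, cdr3s in spec.items()
        }

    def test_identical_clone_in_two_samples(self):
        sets = self._sets({"s1": ["CARDYW"], "s2": ["CARDYW"]})
        shared = shared_clones(sets, identity_threshold=100)
        assert len(shared.table) == 1
        assert shared.table.iloc[0]["samples"] == "s1;s2"

    def test_disjoint_v_genes_share_nothing(self):
        s1 = assemble_clones(make_table([_seq("a", "CARDYW", v="IGHV1-2*01")], "s1"))
        s2 = assemble_clones(make_table([_seq("b", "CARDYW", v="IGHV5-51*01")], "s2"))
        shared = shared_clones({"s1": s1, "s2": s2})
        assert len(shared.table) == 0

    def test_three_sample_chain_matches_bruteforce(self):
        # chain: A↔B and B↔C within 1 mismatch, A↔C at 2 → one merged
        # public clone across all three under single linkage at 85%
        spec = {
            "A": ["CARDYWF", "WWWWWWW"],
            "B": ["CARDYWW", "CCCCCCC"],
            "C": ["CARDYVW", "WWWWWWW"],
        }
        sets = self._sets(spec)
        shared = shared_clones(sets, identity_threshold=85)
        reps = [
            (name, c.v_gene, c.j_gene, c.representative_cdr3)
            for name, cs in sets.items()
            for c in cs.clones
        ]
        expected = shared_combinations_bruteforce(reps, 85)
        got = {
            tuple(row.samples.split(";")): row.n_shared_clones
            for row in shared.summary.itertuples(index=False)
        }
        assert got == expected

    def test_symmetric_under_sample_order(self):
        sets = self._sets({"s1": ["CARDYW"], "s2": ["CARDYW"], "s3": ["CCCCCC"]})
        a = shared_clones(dict(sets))
        b = shared_clones(dict(reversed(list(sets.items()))))
        assert sorted(a.summary["samples"]) == sorted(b.summary["samples"])

    def test_needs_two_samples(self):
        sets = self._sets({"s1": ["CARDYW"]})
        with pytest.raises(UsageError):
            shared_clones(sets)


class TestCloneFiltersAndStats:
    def _cs(self):
        rows = (
            [_seq(f"a{i}", "CARDYW") for i in range(5)]
            + [_seq(f"b{i}", "CCKGWF", v="IGHV3-23*01") for i in range(2)]
            + [_seq("c0", "WWWWWW", v="IGHV5-51*01",
                    functionality="unproductive", frame="out-of-frame")]
        )
        return assemble_clones(make_table(rows))

    def test_filter_by_min_size(self):
        cs = self._cs()
        assert sorted(c.size for c in filter_clones(cs, "size", 2).clones) == [2, 5]

    def test_filter_by_size_range(self):
        cs = self._cs()
        kept = filter_clones(cs, "size", (1, 2))
        assert sorted(c.size for c in kept.clones) == [1, 2]

    def test_filter_functionality_all_members(self):
        cs = self._cs()
        kept = filter_clones(cs, "functionality", "productive", rule="all")
        assert len(kept) == 2

    def test_majority_rule(self):
        rows = [_seq("a0", "CARDYW"), _seq("a1", "CARDYW"),
                _seq("a2", "CARDYW", functionality="unproductive")]
        cs = assemble_clones(make_table(rows))
        assert len(filter_clones(cs, "functionality", "productive", rule="all")) == 0
        assert len(filter_clones(cs, "functionality", "productive", rule="majority")) == 1

    def test_cdr3_length_distribution(self):
        t = make_table([
            _seq("a", "AAAAAAAAAAAA"), _seq("b", "BBBBBBBBBBBB"),
            _seq("c", "CCCCCCCCCCCCC"),
        ])
        dist = cdr3_length_distribution(t)
        assert dist.loc[12, "value"] == pytest.approx(2 / 3)
        assert dist.loc[13, "value"] == pytest.approx(1 / 3)

    def test_cdr3_length_stratified_mix(self):
        rows = [
            _seq("a", "AAAAAA"), _seq("b", "CCCCCC"),
            _seq("c", "DDDDDD", functionality="unproductive"),
            _seq("d", "EEEEEEEE"),
        ]
        dist = cdr3_length_distribution(make_table(rows), stratify_by_functionality=True)
        assert dist.loc[6, "productive"] == pytest.approx(2 / 3)
        assert dist.loc[6, "unproductive"] == pytest.approx(1 / 3)
        assert dist.loc[8, "productive"] == 1.0

    def test_copy_number_histogram(self):
        cs = self._cs()
        hist = copy_number_distribution(cs)
        assert hist.loc[1, "n_clones"] == 1
        assert hist["n_clones"].sum() == len(cs)


class TestGiniIndex:
    def test_equal_sizes_give_zero(self):
        assert gini_index([5, 5, 5, 5]).value == pytest.approx(0.0)

    def test_closed_form_pairs(self):
        assert gini_index([1, 3]).value == pytest.approx(0.25)
        assert gini_index([1, 1, 1, 97]).value == pytest.approx(0.72)

    def test_matches_double_sum_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            sizes = rng.integers(1, 100, size=rng.integers(1, 30))
            assert gini_index(sizes).value == pytest.approx(gini_double_sum(sizes))

    def test_bounds_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            sizes = rng.integers(1, 1000, size=rng.integers(1, 50))
            g = gini_index(sizes).value
            assert 0.0 <= g <= 1.0

    def test_scale_invariance(self):
        sizes = [1, 4, 9, 16]
        g1 = gini_index(sizes).value
        g2 = gini_index([7 * s for s in sizes]).value
        assert g1 == pytest.approx(g2)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            gini_index([])
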