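"""String distances, compositional distances and PCoA."""

import numpy as np
import pandas as pd
import pytest

from bcrkit.distances import (
    DistanceMatrix,
    gene_usage_distance,
    pcoa,
    sequence_distance_matrix,
    string_distance,
)
from bcrkit.errors import UsageError
from bcrkit.genes import UsageTable

from oracles import (
    damerau_levenshtein_exhaustive,
    hamming_naive,
    lcs_distance_recursive,
    levenshtein_recursive,
    osa_recursive,
)

ORACLES = {
    "levenshtein": levenshtein_recursive,
    "osa": osa_recursive,
    "dl": damerau_levenshtein_exhaustive,
    "lcs": lcs_distance_recursive,
}


class TestStringDistance:
    def test_worked_example_levenshtein_and_lcs(self):
        assert string_distance("AABBCC", "ABBBBC", "levenshtein") == 2
        assert string_distance("AABBCC", "ABBBBC", "lcs") == 4

    @pytest.mark.parametrize("method", ["levenshtein", "dl", "osa", "lcs", "qgram", "cosine", "jaccard", "jw"])
    def test_identity(self, method):
        assert string_distance("CARDYW", "CARDYW", method) == 0.0

    def test_classic_pair(self):
        assert string_distance("kitten", "sitting", "levenshtein") == 3

    def test_transposition_semantics(self):
        # OSA cannot edit a transposed substring again; full DL can
        assert string_distance("CA", "ABC", "osa") == 3
        assert string_distance("CA", "ABC", "dl") == 2
        assert string_distance("AB", "BA", "levenshtein") == 2
        assert string_distance("AB", "BA", "osa") == 1
        assert string_distance("AB", "BA", "dl") == 1

    def test_hamming_requires_equal_lengths(self):
        assert string_distance("ABCD", "ABDD", "hamming") == 1
        with pytest.raises(UsageError):
            string_distance("ABC", "ABCD", "hamming")

    def test_empty_strings(self):
        for method in ("levenshtein", "dl", "osa", "lcs"):
            assert string_distance("", "ABC", method) == 3
            assert string_distance("", "", method) == 0

    def test_qgram_family_by_hand(self):
        # 2-grams of "ABCA": AB BC CA; of "ABC": AB BC
        assert string_distance("ABCA", "ABC", "qgram", q=2) == 1
        assert string_distance("ABCA", "ABC", "jaccard", q=2) == pytest.approx(1 - 2 / 3)
        # cosine: profiles (1,1,1) vs (1,1,0) → 2/(sqrt3*sqrt2)
        assert string_distance("ABCA", "ABC", "cosine", q=2) == pytest.approx(
            1 - 2 / (np.sqrt(3) * np.sqrt(2))
        )

    def test_jaro_winkler_reference_value(self):
        # classic MARTHA/MARHTA: jaro 0.944..., prefix 3 → jw sim 0.9611
        d = string_distance("MARTHA", "MARHTA", "jw")
        assert d == pytest.approx(1 - 0.9611, abs=1e-4)

    @pytest.mark.parametrize("method", ["levenshtein", "osa", "dl", "lcs"])
    def test_edit_family_matches_bruteforce(self, method):
        rng = np.random.default_rng(42)
        oracle = ORACLES[method]
        for _ in range(300):
            a = "".join(rng.choice(list("ABCD"), size=rng.integers(0, 9)))
            b = "".join(rng.choice(list("ABCD"), size=rng.integers(0, 9)))
            assert string_distance(a, b, method) == oracle(a, b), (a, b)

    def test_levenshtein_matches_edlib(self):
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 12)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 12)))
            assert string_distance(a, b, "levenshtein") == edlib.align(a, b)["editDistance"]

    def test_edit_operation_subset_ordering(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = "".join(rng.choice(list("ABC"), size=rng.integers(0, 8)))
            b = "".join(rng.choice(list("ABC"), size=rng.integers(0, 8)))
            lcs = string_distance(a, b, "lcs")
            lev = string_distance(a, b, "levenshtein")
            dl = string_distance(a, b, "dl")
            osa = string_distance(a, b, "osa")
            assert lcs >= lev >= osa >= dl

    def test_triangle_inequality_levenshtein_hamming(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c = (
                "".join(rng.choice(list("AB"), size=6)) for _ in range(3)
            )
            for m in ("levenshtein", "hamming"):
                dab = string_distance(a, b, m)
                dbc = string_distance(b, c, m)
                dac = string_distance(a, c, m)
                assert dac <= dab + dbc


class TestSequenceDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = sequence_distance_matrix(["AAA"] * 3, labels=list("abc"))
        assert np.all(dm.values == 0)

    def test_grouped_by_length_splits(self):
        res = sequence_distance_matrix(
            ["AAAAA", "AAAAB", "CCCCCCC", "CCCCCCA"], method="hamming", group_by_length=True
        )
        assert sorted(res) == [5, 7]
        assert res[5].values[0, 1] == 1

    def test_hamming_mixed_lengths_rejected(self):
        with pytest.raises(UsageError):
            sequence_distance_matrix(["AAA", "AAAA"], method="hamming")

    def test_workers_do_not_change_result(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACDEF"), size=6)) for _ in range(30)]
        a = sequence_distance_matrix(seqs, workers=1, labels=[str(i) for i in range(30)])
        b = sequence_distance_matrix(seqs, workers=4, labels=[str(i) for i in range(30)])
        assert np.array_equal(a.values, b.values)


class TestGeneUsageDistance:
    @staticmethod
    def _usage(cols):
        return UsageTable(level="gene", abundance="relative",
                          df=pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))]))

    @pytest.mark.parametrize("method", ["bray_curtis", "jaccard", "cosine"])
    def test_identical_profiles_zero(self, method):
        u = self._usage({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        assert gene_usage_distance(u, method).values[0, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize("method", ["bray_curtis", "jaccard", "cosine"])
    def test_disjoint_support_is_one(self, method):
        u = self._usage({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert gene_usage_distance(u, method).values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_formula(self):
        u = self._usage({"a": [2.0, 1.0], "b": [1.0, 1.0]})
        assert gene_usage_distance(u, "bray_curtis").values[0, 1] == pytest.approx(0.2)

    def test_cutoff_zeroes_small_proportions(self):
        u = self._usage({"a": [0.95, 0.05], "b": [0.95, 0.0]})
        dm = gene_usage_distance(u, "jaccard", cutoff=0.1)
        assert dm.values[0, 1] == 0.0

    def test_cosine_undefined_for_zero_vector(self):
        u = self._usage({"a": [1.0, 1.0], "b": [0.0, 0.0]})
        assert np.isnan(gene_usage_distance(u, "cosine").values[0, 1])

    def test_transpose_gives_gene_distances(self):
        u = self._usage({"a": [1.0, 0.0], "b": [1.0, 0.0]})
        dm = gene_usage_distance(u, "bray_curtis", transpose=True)
        assert dm.labels == ["g0", "g1"]


class TestPCoA:
    def test_euclidean_self_consistency(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(10)], d))
        rec = np.sqrt(((res.coordinates[:, None] - res.coordinates[None]) ** 2).sum(-1))
        assert np.abs(rec - d).max() < 1e-9
        assert res.coordinates.shape[1] == 2
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equidistant_points_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(list("abc"), d))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    @staticmethod
    def _non_euclidean():
        d = np.array(
            [[0, 1, 8, 1], [1, 0, 1, 1], [8, 1, 0, 1], [1, 1, 1, 0]], dtype=float
        )
        return DistanceMatrix(list("abcd"), d)

    def test_uncorrected_flags_negative_eigenvalues(self):
        res = pcoa(self._non_euclidean(), "none")
        assert res.negative_eigenvalues
        assert res.correction_applied == "none"

    def test_lingoes_correction(self):
        dm = self._non_euclidean()
        res = pcoa(dm, "lingoes")
        assert res.eigenvalues.min() >= -1e-8
        assert res.correction_constant > 0
        # corrected squared distances are d² + 2c off-diagonal
        raw = pcoa(dm, "none")
        c = -raw.eigenvalues.min()
        assert res.correction_constant == pytest.approx(c)

    def test_cailliez_correction(self):
        res = pcoa(self._non_euclidean(), "cailliez")
        assert res.eigenvalues.min() >= -1e-8
        assert res.correction_constant > 0

    def test_matches_skbio_uncorrected(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        mine = pcoa(DistanceMatrix([str(i) for i in range(8)], d))
        ref = skbio_ord.pcoa(d)
        ref_eig = np.sort(np.asarray(ref.eigvals))[::-1][:3]
        assert np.allclose(mine.eigenvalues[:3], ref_eig, atol=1e-8)

    def test_too_few_items_rejected(self):
        with pytest.raises(UsageError):
            pcoa(DistanceMatrix(list("ab"), np.zeros((2, 2))))
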