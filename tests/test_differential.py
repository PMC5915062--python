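import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcmproteo import datasets, differential
from lcmproteo.model import ContrastSpec, SampleAnnotation, SpectralCountMatrix
from tests.conftest import make_matrix


class TestReplaceZeros:
    def test_zeros_become_pseudocount(self):
        np.testing.assert_allclose(
            differential.replace_zeros(np.array([0, 3, 0])), [0.125, 3, 0.125]
        )

    def test_positive_unchanged(self):
        np.testing.assert_allclose(
            differential.replace_zeros(np.array([1, 2, 9])), [1, 2, 9]
        )

    def test_custom_pseudocount(self):
        np.testing.assert_allclose(
            differential.replace_zeros(np.array([0]), pseudocount=1.0), [1.0]
        )


class TestFoldChange:
    def test_equal_means_give_zero(self, small_study):
        matrix, annotations, contrast = small_study
        fc = differential.log2_fold_change(matrix, annotations, contrast)
        assert fc["B"] == 0.0

    def test_absent_reference_gives_32_fold(self, small_study):
        # group mean 4 vs all-zero reference floored at 0.125 -> ratio 32
        matrix, annotations, contrast = small_study
        fc = differential.log2_fold_change(matrix, annotations, contrast)
        assert fc["A"] == pytest.approx(5.0)
        assert 2 ** fc["A"] == pytest.approx(32.0)

    def test_both_groups_all_zero_gives_zero(self):
        matrix = make_matrix({"A": [0, 0, 0, 0]}, ["EC1", "EC2", "HE1", "HE2"])
        annotations = [
            SampleAnnotation("EC1", "early_cancer"),
            SampleAnnotation("EC2", "early_cancer"),
            SampleAnnotation("HE1", "healthy_epithelium"),
            SampleAnnotation("HE2", "healthy_epithelium"),
        ]
        fc = differential.log2_fold_change(
            matrix, annotations, ContrastSpec("early_cancer", "healthy_epithelium"))
        assert fc["A"] == 0.0

    @given(
        st.lists(st.integers(0, 50), min_size=4, max_size=4),
        st.lists(st.integers(0, 50), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a_counts, b_counts):
        """Swapping contrast groups negates every log2 fold-change exactly."""
        samples = ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4"]
        matrix = make_matrix({"P": a_counts + b_counts}, samples)
        annotations = (
            [SampleAnnotation(f"A{i}", "early_cancer") for i in range(1, 5)]
            + [SampleAnnotation(f"B{i}", "healthy_epithelium") for i in range(1, 5)]
        )
        fwd = differential.log2_fold_change(
            matrix, annotations, ContrastSpec("early_cancer", "healthy_epithelium"))
        rev = differential.log2_fold_change(
            matrix, annotations, ContrastSpec("healthy_epithelium", "early_cancer"))
        assert fwd["P"] == -rev["P"]


def hypergeom_tails(present_a, n_a, present_b, n_b):
    """Exhaustive enumeration over all 2x2 tables with the given margins."""
    total = present_a + present_b
    N = n_a + n_b
    denom = math.comb(N, n_a)
    probs = {}
    for x in range(max(0, total - n_b), min(n_a, total) + 1):
        probs[x] = math.comb(total, x) * math.comb(N - total, n_a - x) / denom
    lower = sum(p for x, p in probs.items() if x <= present_a)
    upper = sum(p for x, p in probs.items() if x >= present_a)
    return lower, upper


class TestFisherPresence:
    def test_fully_separated_groups(self):
        # presence 11/11 vs 0/13: doubled extreme tail = 2 / C(24, 11)
        p = differential.fisher_presence_p(11, 11, 0, 13)
        assert p == pytest.approx(2 / math.comb(24, 11))

    def test_balanced_presence_gives_one(self):
        assert differential.fisher_presence_p(5, 10, 5, 10) == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(11, 13), (5, 7), (13, 13)])
    def test_matches_exhaustive_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pa = int(rng.integers(0, n_a + 1))
            pb = int(rng.integers(0, n_b + 1))
            lower, upper = hypergeom_tails(pa, n_a, pb, n_b)
            expected = min(1.0, 2 * min(lower, upper))
            assert differential.fisher_presence_p(pa, n_a, pb, n_b) == pytest.approx(
                expected, rel=1e-10)


class TestWelchLog:
    def test_constant_equal_groups_give_p_one(self):
        matrix = make_matrix({"P": [3, 3, 3, 3]}, ["EC1", "EC2", "HE1", "HE2"])
        annotations = [
            SampleAnnotation("EC1", "early_cancer"),
            SampleAnnotation("EC2", "early_cancer"),
            SampleAnnotation("HE1", "healthy_epithelium"),
            SampleAnnotation("HE2", "healthy_epithelium"),
        ]
        p = differential.differential_test(
            matrix, annotations, ContrastSpec("early_cancer", "healthy_epithelium"))
        assert p["P"] == 1.0

    def test_requires_two_samples_per_group(self):
        matrix = make_matrix({"P": [3, 4]}, ["EC1", "HE1"])
        annotations = [
            SampleAnnotation("EC1", "early_cancer"),
            SampleAnnotation("HE1", "healthy_epithelium"),
        ]
        with pytest.raises(ValueError, match="2 samples"):
            differential.differential_test(
                matrix, annotations,
                ContrastSpec("early_cancer", "healthy_epithelium"))


class TestVolcano:
    def test_schema_and_sorting(self, small_study):
        matrix, annotations, contrast = small_study
        table = differential.volcano_table(matrix, annotations, contrast)
        assert list(table.columns) == ["protein_id", "log2_fc",
                                       "neg_log10_p", "p_value"]
        assert len(table) == 3
        assert table["p_value"].is_monotonic_increasing
        # -log10 identity
        np.testing.assert_allclose(table["neg_log10_p"],
                                   -np.log10(table["p_value"]))


class TestCellLineContrast:
    def test_published_fold_change_rows_classify_as_printed(self):
        """The 33 published fold-change rows split 19 tumor+HeLa / 14 tumor-only."""
        fc = datasets.cell_line_fold_changes()
        labels = differential.classify_fold_changes(fc, fc_min=2.5)
        assert (labels == "tumor_and_HeLa").sum() == 19
        assert (labels == "tumor_only").sum() == 14
        assert labels[fc["gene"] == "AKAP13"].iloc[0] == "tumor_and_HeLa"
        assert labels[fc["gene"] == "CLCA4"].iloc[0] == "tumor_only"

    def test_flat_profile_unclassified(self):
        fc = pd.DataFrame([{c: 0.0 for c in
                            ["early_cancer", "late_cancer", "HeLa", "U87", "HEK293"]}])
        assert differential.classify_fold_changes(fc).iloc[0] == "unclassified"

    def test_from_counts_end_to_end(self):
        samples = ["EC1", "EC2", "LC1", "LC2", "HE1", "HE2", "HeLa", "U87", "HEK"]
        matrix = make_matrix({"P": [8, 8, 8, 8, 0, 0, 8, 0, 0],
                              "Q": [1, 1, 1, 1, 1, 1, 1, 1, 1]}, samples)
        annotations = [
            SampleAnnotation("EC1", "early_cancer"),
            SampleAnnotation("EC2", "early_cancer"),
            SampleAnnotation("LC1", "late_cancer"),
            SampleAnnotation("LC2", "late_cancer"),
            SampleAnnotation("HE1", "healthy_epithelium"),
            SampleAnnotation("HE2", "healthy_epithelium"),
            SampleAnnotation("HeLa", "cell_line:HeLa"),
            SampleAnnotation("U87", "cell_line:U87"),
            SampleAnnotation("HEK", "cell_line:HEK293"),
        ]
        out = differential.cell_line_contrast(matrix, annotations, fc_min=2.5)
        assert out.loc["P", "classification"] == "tumor_and_HeLa"
        assert out.loc["Q", "classification"] == "unclassified"

    def test_missing_cell_line_is_error(self, small_study):
        matrix, annotations, _ = small_study
        with pytest.raises(ValueError, match="lacks group"):
            differential.cell_line_contrast(matrix, annotations)


class TestReplicateOverlap:
    def test_identical_sets(self):
        assert differential.replicate_overlap([{"A", "B"}, {"A", "B"}])["overall"] == 100.0

    def test_disjoint_sets(self):
        assert differential.replicate_overlap([{"A"}, {"B"}])["overall"] == 0.0

    def test_half_overlap(self):
        result = differential.replicate_overlap([{"A", "B", "C"}, {"B", "C", "D"}])
        assert result["overall"] == 50.0
        assert result["pairwise"][(0, 1)] == 50.0
        assert not result["acceptable"]
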