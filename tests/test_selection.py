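import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcmproteo import differential, selection
from lcmproteo.model import SampleAnnotation, SelectionParams
from tests.conftest import brute_force_bh, make_matrix


def build_study(rows: dict[str, list[int]]):
    """11 early / 2 late / 13 healthy / 13 stroma columns."""
    samples = ([f"EC{i:02d}" for i in range(11)] + ["LC00", "LC01"]
               + [f"HE{i:02d}" for i in range(13)]
               + [f"ST{i:02d}" for i in range(13)])
    annotations = (
        [SampleAnnotation(f"EC{i:02d}", "early_cancer") for i in range(11)]
        + [SampleAnnotation("LC00", "late_cancer"),
           SampleAnnotation("LC01", "late_cancer")]
        + [SampleAnnotation(f"HE{i:02d}", "healthy_epithelium") for i in range(13)]
        + [SampleAnnotation(f"ST{i:02d}", "stroma") for i in range(13)]
    )
    return make_matrix(rows, samples), annotations


def pattern(early_present, stroma_present=0, late_present=0):
    row = [1] * early_present + [0] * (11 - early_present)
    row += [1] * late_present + [0] * (2 - late_present)
    row += [0] * 13
    row += [1] * stroma_present + [0] * (13 - stroma_present)
    return row


class TestAllOrNothing:
    params = SelectionParams()

    def selected(self, rows, p):
        matrix, annotations = build_study(rows)
        p_values = pd.Series(p, index=list(rows))
        return selection.all_or_nothing(matrix, annotations, self.params, p_values)

    def test_full_presence_selected(self):
        assert self.selected({"A": pattern(11)}, {"A": 1e-5}) == ["A"]

    def test_six_of_eleven_rejected(self):
        assert self.selected({"A": pattern(6)}, {"A": 1e-5}) == []

    def test_single_stroma_count_rejected(self):
        assert self.selected({"A": pattern(8, stroma_present=1)}, {"A": 1e-5}) == []

    def test_presence_in_late_cancer_permitted(self):
        assert self.selected({"A": pattern(8, late_present=2)}, {"A": 1e-5}) == ["A"]

    def test_p_above_cutoff_rejected(self):
        assert self.selected({"A": pattern(11)}, {"A": 0.06}) == []

    def test_exclude_target_overlap_is_error(self):
        with pytest.raises(ValueError, match="overlap"):
            SelectionParams(target_group="early_cancer",
                            exclude_groups=("early_cancer", "stroma"))

    def test_recovers_planted_exclusives_exactly(self, simulated_study):
        """Sensitivity and specificity 1 against the simulation ground truth."""
        from lcmproteo.model import ContrastSpec

        _, matrix, annotations, truth = simulated_study
        p = differential.differential_test(
            matrix, annotations,
            ContrastSpec("early_cancer", "healthy_epithelium",
                         test_method="fisher_presence"))
        got = set(selection.all_or_nothing(matrix, annotations,
                                           SelectionParams(), p))
        planted = set(truth.proteins_of_class("tumor_exclusive"))
        assert got == planted


class TestExclusiveInGroup:
    others = ("early_cancer", "late_cancer", "stroma")

    def check(self, row, min_present=6):
        matrix, annotations = build_study({"A": row})
        return selection.exclusive_in_group(
            matrix, annotations, "healthy_epithelium", self.others, min_present)

    def healthy_pattern(self, healthy_present, early_present=0):
        row = [1] * early_present + [0] * (11 - early_present) + [0, 0]
        row += [1] * healthy_present + [0] * (13 - healthy_present)
        row += [0] * 13
        return row

    def test_six_of_thirteen_selected(self):
        assert self.check(self.healthy_pattern(6)) == ["A"]

    def test_five_of_thirteen_rejected(self):
        assert self.check(self.healthy_pattern(5)) == []

    def test_any_cancer_count_rejected(self):
        assert self.check(self.healthy_pattern(13, early_present=1)) == []


class TestBonferroni:
    def test_threshold_arithmetic(self):
        threshold, flags = selection.bonferroni(
            pd.Series([0.004, 0.006]), alpha=0.05, m=10)
        assert threshold == 0.005
        assert list(flags) == [True, False]

    def test_single_test_identity(self):
        threshold, _ = selection.bonferroni(pd.Series([0.02]), alpha=0.05, m=1)
        assert threshold == 0.05

    def test_family_of_5061_reproduces_printed_cutoff(self):
        # 0.05 / 5061 = 9.8795e-6, i.e. 9.88e-6 at 3 significant digits
        threshold, _ = selection.bonferroni(pd.Series([0.5]), alpha=0.05, m=5061)
        assert threshold == pytest.approx(9.88e-6, rel=5e-4)

    def test_strict_inequality_at_threshold(self):
        threshold, flags = selection.bonferroni(pd.Series([0.005]), 0.05, 10)
        assert not flags.iloc[0]


class TestBenjaminiHochberg:
    def test_single_small_p_rejected(self):
        flags, adj = selection.benjamini_hochberg(pd.Series([0.01]), q=0.05)
        assert flags.iloc[0]
        assert adj.iloc[0] == pytest.approx(0.01)

    def test_all_ones(self):
        flags, adj = selection.benjamini_hochberg(pd.Series([1.0, 1.0]), q=0.05)
        assert not flags.any()
        assert (adj == 1.0).all()

    def test_step_up_example(self):
        flags, _ = selection.benjamini_hochberg(
            pd.Series([0.01, 0.02, 0.03, 0.9]), q=0.05)
        assert list(flags) == [True, True, True, False]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            m = int(rng.integers(1, 51))
            p = rng.uniform(1e-6, 1.0, size=m)
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 1)
                p[p == 0] = 0.05
            flags, _ = selection.benjamini_hochberg(pd.Series(p), q=0.05)
            np.testing.assert_array_equal(flags.to_numpy(),
                                          brute_force_bh(p, 0.05))

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity_of_regimes(self, p_list):
        """Bonferroni-significant implies BH-significant implies p < p_max."""
        p = pd.Series(p_list)
        _, bonf = selection.bonferroni(p, alpha=0.05)
        bh, _ = selection.benjamini_hochberg(p, q=0.05)
        assert not (bonf & ~bh).any()
        assert (p[bh] <= 0.05).all()
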