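import numpy as np
import pandas as pd
import pytest

from lcmproteo.model import samples_in_group
from lcmproteo.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_gene_sets,
    simulate_prm_series,
    simulate_study,
)


class TestSimulateStudy:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig()

    def test_all_null_when_no_planting(self):
        config = SimulationConfig(n_proteins=50, prop_fc_up=0, prop_fc_down=0,
                                  prop_tumor_exclusive=0,
                                  prop_healthy_exclusive=0, seed=1)
        _, _, truth = simulate_study(config)
        assert set(truth.classes.values()) == {"null"}

    def test_same_seed_identical_matrices(self):
        config = SimulationConfig(n_proteins=100, seed=5)
        m1, a1, _ = simulate_study(config)
        m2, a2, _ = simulate_study(config)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        assert a1 == a2

    def test_group_sizes_match_design(self):
        config = SimulationConfig(n_proteins=50, seed=2)
        _, annotations, _ = simulate_study(config)
        sizes = {g: len(samples_in_group(annotations, g))
                 for g in ("early_cancer", "late_cancer",
                           "healthy_epithelium", "stroma")}
        assert sizes == {"early_cancer": 11, "late_cancer": 11,
                         "healthy_epithelium": 13, "stroma": 13}

    def test_planted_exclusives_hold_exactly(self):
        """Exactly the planted tumor-exclusive proteins have zero counts in
        all 26 healthy/stroma samples and the configured early presence."""
        config = SimulationConfig(n_proteins=2000, prop_tumor_exclusive=0.0155,
                                  tumor_exclusive_presence=8, seed=9)
        matrix, annotations, truth = simulate_study(config)
        planted = set(truth.proteins_of_class("tumor_exclusive"))
        assert len(planted) == 31
        he_st = (samples_in_group(annotations, "healthy_epithelium")
                 + samples_in_group(annotations, "stroma"))
        ec = samples_in_group(annotations, "early_cancer")
        zero_in_controls = set(
            matrix.counts.index[(matrix.counts[he_st] == 0).all(axis=1)])
        assert planted <= zero_in_controls
        for pid in planted:
            assert int((matrix.counts.loc[pid, ec] >= 1).sum()) == 8
        # direct scan: nothing else is control-exclusive with >= 7/11 presence
        others = zero_in_controls - planted
        for pid in others:
            presence = int((matrix.counts.loc[pid, ec] >= 1).sum())
            assert presence < 7 or truth.classes[pid] == "healthy_exclusive"

    def test_fc_up_effect_size_realized(self):
        """Mean cancer count of planted fc_up proteins tracks mu * 2^effect
        (thinned by dropout) within sampling error."""
        config = SimulationConfig(n_proteins=4000, prop_fc_up=0.25,
                                  log2_effect=2.0, seed=14)
        matrix, annotations, truth = simulate_study(config)
        up = truth.proteins_of_class("fc_up")
        cancer = (samples_in_group(annotations, "early_cancer")
                  + samples_in_group(annotations, "late_cancer"))
        observed = matrix.counts.loc[up, cancer].to_numpy().mean()
        expected = config.nb_mean * 2**config.log2_effect * (1 - config.dropout)
        assert observed == pytest.approx(expected, rel=0.05)

    def test_detection_per_sample_in_realistic_range(self):
        config = SimulationConfig(seed=3)
        matrix, _, _ = simulate_study(config)
        detected = (matrix.counts >= 1).sum(axis=0)
        assert detected.min() >= 1296 * 2000 / 3000  # scaled study range
        assert detected.max() <= 2189


class TestSimulateGeneSets:
    def test_planted_members_in_designated_set(self):
        bg = [f"g{i}" for i in range(200)]
        coll = simulate_gene_sets(5, 20, bg, planted_members=bg[:10], seed=1)
        assert set(bg[:10]) <= set(coll.sets["NET01"].members)
        assert len(coll.sets) == 5
        assert all(len(s.members) == 20 for s in coll.sets.values())

    def test_seed_determinism(self):
        bg = [f"g{i}" for i in range(100)]
        a = simulate_gene_sets(4, 10, bg, seed=7)
        b = simulate_gene_sets(4, 10, bg, seed=7)
        assert a.sets == b.sets


class TestSimulatePRM:
    def test_noise_free_is_exactly_linear(self):
        series = simulate_prm_series(slope=10.0, intercept=2.0, cv=0.0, seed=0)
        np.testing.assert_allclose(series["area"],
                                   10.0 * series["level"] + 2.0)

    def test_blank_level_carries_intercept_only(self):
        series = simulate_prm_series(slope=10.0, intercept=5.0, cv=0.0, seed=0)
        blank = series.loc[series["level"] == 0, "area"]
        np.testing.assert_allclose(blank, 5.0)

    def test_default_levels_and_replicates(self):
        series = simulate_prm_series(slope=1.0, seed=0)
        assert sorted(series["level"].unique()) == [0, 0.625, 1.25, 2.5, 5, 10, 20]
        assert (series.groupby("level").size() == 3).all()


class TestSimulateExpression:
    def test_strata_ordered(self):
        genes = [f"g{i}" for i in range(300)]
        expr = simulate_expression(genes, 30, high_set=genes[:50],
                                   low_set=genes[50:100], seed=2)
        means = expr.values.mean(axis=1)
        assert means[genes[:50]].mean() > means[genes[100:]].mean() > means[
            genes[50:100]].mean()

    def test_seed_determinism(self):
        genes = [f"g{i}" for i in range(50)]
        a = simulate_expression(genes, 10, seed=4)
        b = simulate_expression(genes, 10, seed=4)
        pd.testing.assert_frame_equal(a.values, b.values)
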