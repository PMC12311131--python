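"""Cohort QC, baseline DE, cohort OLS, proportion test and distance statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scresist import (
    CountMatrix,
    SimCohortSpec,
    baseline_de,
    cohort_ols,
    cohort_qc,
    distance_heterogeneity,
    marker_proportion_test,
    simulate_cohort,
    top_variable_genes,
)
from scresist.qc import lognormalize

from conftest import random_count_matrix


def analyzed_cohort(spec, seed):
    cm, ann, gt = simulate_cohort(spec, seed=seed)
    cm = cohort_qc(cm, min_genes=300, annotation=ann)
    norm = lognormalize(cm)
    ann = ann.reindex(norm.cells)
    return norm, ann, gt


class TestCohortQC:
    def _matrix_with_detected(self, detected):
        n_genes = max(detected) + 1
        counts = np.zeros((n_genes, len(detected)), dtype=int)
        for i, d in enumerate(detected):
            counts[:d, i] = 1
        return CountMatrix([f"G{g:03d}" for g in range(n_genes)],
                           [f"c{i}" for i in range(len(detected))], counts)

    def test_boundary_inclusive(self):
        cm = self._matrix_with_detected([499, 500, 501])
        filtered = cohort_qc(cm, min_genes=500)
        assert list(filtered.cells) == ["c1", "c2"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        cm = random_count_matrix(rng, n_genes=80, n_cells=50, mean=0.5)
        filtered = cohort_qc(cm, min_genes=20)
        expected = [
            cm.cells[i] for i in range(cm.n_cells)
            if sum(1 for g in range(cm.n_genes) if cm.counts[g, i] > 0) >= 20
        ]
        assert list(filtered.cells) == expected

    def test_patient_losing_all_cells_warned(self, caplog):
        cm = self._matrix_with_detected([10, 600])
        ann = pd.DataFrame({"patient": ["P1", "P2"]}, index=cm.cells)
        import logging
        with caplog.at_level(logging.WARNING, logger="scresist.cohort"):
            cohort_qc(cm, min_genes=500, annotation=ann)
        assert "P1" in caplog.text


class TestBaselineDE:
    def test_planted_program_recovered_and_antisymmetric(self):
        spec = SimCohortSpec(timepoints=("D0",), cells_per_patient_per_timepoint=60)
        norm, ann, gt = analyzed_cohort(spec, seed=2)
        sens = norm.cells[ann.condition == "sensitive"]
        res = norm.cells[ann.condition == "resistant"]
        de = baseline_de(norm, sens, res)
        sig_up = de.index[(de.direction == "up_in_a") & (de.p_adj < 0.05)]
        assert len(set(sig_up) & set(gt.marker_up_ids)) >= 40
        swapped = baseline_de(norm, res, sens)
        shared = de.index.intersection(swapped.index)
        np.testing.assert_allclose(
            de.loc[shared, "log2fc"], -swapped.loc[shared, "log2fc"], atol=1e-9
        )


class TestCohortOLS:
    def test_output_contract(self):
        spec = SimCohortSpec(timepoints=("D0", "D14"), cells_per_patient_per_timepoint=40)
        norm, ann, gt = analyzed_cohort(spec, seed=3)
        at_d0 = ann.timepoint == "D0"
        de = baseline_de(norm, norm.cells[(ann.condition == "sensitive") & at_d0],
                         norm.cells[(ann.condition == "resistant") & at_d0])
        scores, summary, tests = cohort_ols(norm, de, ann)
        assert len(scores) == norm.n_cells
        assert set(tests) == {"D0", "D14"}
        assert ((scores["own_arm_similarity"] <= 1.0) | scores["degenerate"]).all()
        assert set(summary.index.get_level_values("condition")) == {"sensitive", "resistant"}

    def test_single_arm_rejected(self):
        spec = SimCohortSpec(timepoints=("D0",), cells_per_patient_per_timepoint=30)
        norm, ann, gt = analyzed_cohort(spec, seed=4)
        keep = ann.condition == "sensitive"
        sub = norm.subset_cells(norm.cells[keep])
        de = pd.DataFrame({"log2fc": [1.0] * 5},
                          index=pd.Index(list(norm.genes[:5]), name="gene"))
        with pytest.raises(ValueError, match="arm"):
            cohort_ols(sub, de, ann.loc[keep])

    def test_extra_heterogeneity_detected_as_lower_similarity(self):
        """Planted 3x activation spread in the resistant arm is flagged as
        significantly lower own-arm similarity at baseline."""
        wins = 0
        for seed in range(6):
            spec = SimCohortSpec(resistant_extra_heterogeneity=3.0,
                                 timepoints=("D0",), cells_per_patient_per_timepoint=60)
            norm, ann, gt = analyzed_cohort(spec, seed=seed)
            de = baseline_de(norm, norm.cells[ann.condition == "sensitive"],
                             norm.cells[ann.condition == "resistant"])
            scores, _, _ = cohort_ols(norm, de, ann)
            res = scores.loc[scores.condition == "resistant", "own_arm_similarity"]
            sens = scores.loc[scores.condition == "sensitive", "own_arm_similarity"]
            wins += stats.mannwhitneyu(res, sens, alternative="less").pvalue < 0.05
        assert wins >= 5

    def test_equal_heterogeneity_not_flagged(self):
        """Direction-specific false-positive control: with equal spread the
        resistant arm is (essentially) never reported as more heterogeneous."""
        hits = 0
        reps = 12
        for seed in range(reps):
            spec = SimCohortSpec(resistant_extra_heterogeneity=1.0,
                                 patient_effect_sd=0.0,
                                 timepoints=("D0",), cells_per_patient_per_timepoint=60)
            norm, ann, gt = analyzed_cohort(spec, seed=100 + seed)
            de = baseline_de(norm, norm.cells[ann.condition == "sensitive"],
                             norm.cells[ann.condition == "resistant"])
            scores, _, _ = cohort_ols(norm, de, ann)
            res = scores.loc[scores.condition == "resistant", "own_arm_similarity"]
            sens = scores.loc[scores.condition == "sensitive", "own_arm_similarity"]
            hits += stats.mannwhitneyu(res, sens, alternative="less").pvalue < 0.05
        # a 5%-level test should reject in about 5% of replicates
        assert hits <= 3


class TestMarkerProportionTest:
    def test_equal_proportions_zero_statistic(self):
        universe = [f"g{i}" for i in range(100)]
        markers = universe[:10]  # 10% of universe
        de = universe[:2] + universe[50:68]  # 2/20 = 10% markers
        res = marker_proportion_test(de, markers, universe)
        assert res.statistic == 0.0
        assert res.p >= 0.5

    def test_extreme_enrichment(self):
        universe = [f"g{i}" for i in range(1000)]
        markers = universe[:100]  # 10%
        de = universe[:50]  # all markers
        res = marker_proportion_test(de, markers, universe)
        assert res.p < 1e-6
        assert res.k_de_markers == 50 and res.n_de == 50

    def test_null_p_calibrated(self):
        # under random DE draws the one-sided p is near-uniform; the
        # continuity correction makes it slightly conservative (mass pushed
        # toward 0.5), so calibration is asserted as bounds: correct tail
        # rate and bounded distance from uniformity
        rng = np.random.default_rng(5)
        universe = np.array([f"g{i}" for i in range(50000)])
        markers = universe[:15000]
        ps = np.array([
            marker_proportion_test(rng.choice(universe, 500, replace=False),
                                   markers, universe).p
            for _ in range(400)
        ])
        assert 0.02 <= (ps < 0.05).mean() <= 0.08
        assert stats.kstest(ps, "uniform").statistic < 0.1

    def test_empty_de_rejected(self):
        with pytest.raises(ValueError):
            marker_proportion_test([], ["a"], ["a", "b"])


class TestDistanceHeterogeneity:
    def _uniform_norm(self, n_genes=30, n_cells=20, value=2.0):
        from scresist import NormalizedMatrix
        return NormalizedMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"c{i}" for i in range(n_cells)],
            np.full((n_genes, n_cells), value),
            np.ones(n_cells),
        )

    def test_identical_cells_zero_distance(self):
        norm = self._uniform_norm()
        genes = list(norm.genes)
        het = distance_heterogeneity(norm, genes[:10], genes, norm.cells,
                                     n_cells=20, n_random=5, seed=0)
        assert het.marker_distance == 0.0
        np.testing.assert_array_equal(het.null_distances, 0.0)

    def test_matches_brute_force_pairwise(self, small_norm):
        genes = list(small_norm.genes)
        het = distance_heterogeneity(small_norm, genes[:8], genes, small_norm.cells,
                                     n_cells=len(small_norm.cells), n_random=3, seed=1)
        idx = small_norm.gene_indexer(sorted(genes[:8]))
        cells = sorted(small_norm.cells)
        vals = small_norm.values[np.ix_(idx, small_norm.cell_indexer(cells))].T
        total, pairs = 0.0, 0
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                total += np.sqrt(((vals[i] - vals[j]) ** 2).sum())
                pairs += 1
        assert het.marker_distance == pytest.approx(total / pairs, abs=1e-10)

    def test_scaling_homogeneity(self, small_norm):
        from scresist import NormalizedMatrix
        genes = list(small_norm.genes)
        het1 = distance_heterogeneity(small_norm, genes[:8], genes, small_norm.cells,
                                      n_cells=30, n_random=4, seed=2)
        scaled = NormalizedMatrix(small_norm.genes, small_norm.cells,
                                  3.0 * small_norm.values, small_norm.size_factors)
        het3 = distance_heterogeneity(scaled, genes[:8], genes, scaled.cells,
                                      n_cells=30, n_random=4, seed=2)
        assert het3.marker_distance == pytest.approx(3 * het1.marker_distance, rel=1e-10)
        np.testing.assert_allclose(het3.null_distances, 3 * het1.null_distances, rtol=1e-10)

    def test_gene_and_cell_order_invariance(self, small_norm):
        genes = list(small_norm.genes)
        rng = np.random.default_rng(3)
        het_a = distance_heterogeneity(small_norm, genes[:8], genes,
                                       list(small_norm.cells), n_cells=15, n_random=4, seed=4)
        shuffled_cells = list(rng.permutation(small_norm.cells))
        shuffled_markers = list(rng.permutation(genes[:8]))
        shuffled_top = list(rng.permutation(genes))
        het_b = distance_heterogeneity(small_norm, shuffled_markers, shuffled_top,
                                       shuffled_cells, n_cells=15, n_random=4, seed=4)
        assert het_a.marker_distance == pytest.approx(het_b.marker_distance, abs=1e-12)
        np.testing.assert_allclose(het_a.null_distances, het_b.null_distances, atol=1e-12)

    def test_markers_must_be_in_top_variable(self, small_norm):
        with pytest.raises(ValueError, match="subset"):
            distance_heterogeneity(small_norm, ["nope"], list(small_norm.genes),
                                   small_norm.cells)

    def test_pool_too_small_rejected(self, small_norm):
        genes = list(small_norm.genes)
        with pytest.raises(ValueError, match="non-marker"):
            distance_heterogeneity(small_norm, genes[:15], genes[:20], small_norm.cells)

    def test_small_group_uses_all_cells_with_warning(self, small_norm, caplog):
        genes = list(small_norm.genes)
        het = distance_heterogeneity(small_norm, genes[:5], genes, small_norm.cells[:10],
                                     n_cells=1000, n_random=2, seed=5)
        assert het.n_cells_sampled == 10
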