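"""Differential expression, consensus rule, enrichment and signatures."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scresist import (
    NormalizedMatrix,
    SimLineSpec,
    consensus_markers,
    group_de,
    ora_enrichment,
    pseudobulk_log2fc,
    pseudobulk_profile,
    signature_score,
    simulate_line,
)
from scresist.pipeline import analyze_line


def make_norm(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:02d}" for i in range(values.shape[0])]
    return NormalizedMatrix(
        genes, [f"c{i:03d}" for i in range(values.shape[1])],
        values, np.ones(values.shape[1]),
    )


class TestPseudobulk:
    def test_single_cell_identity(self, small_norm):
        prof = pseudobulk_profile(small_norm, [small_norm.cells[0]])
        np.testing.assert_allclose(prof.to_numpy(), small_norm.values[:, 0])

    def test_two_cell_mean(self):
        norm = make_norm([[1.0, 3.0], [0.0, 2.0]])
        prof = pseudobulk_profile(norm, norm.cells)
        np.testing.assert_allclose(prof.to_numpy(), [2.0, 1.0])

    def test_matches_direct_mean(self, small_norm):
        subset = small_norm.cells[5:20]
        prof = pseudobulk_profile(small_norm, subset)
        np.testing.assert_allclose(prof.to_numpy(), small_norm.values[:, 5:20].mean(axis=1))

    def test_empty_subset_rejected(self, small_norm):
        with pytest.raises(ValueError):
            pseudobulk_profile(small_norm, [])


class TestGroupDE:
    def test_low_pct_gene_not_tested(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(2, 1, size=(5, 40))
        values[0] = 0.0
        values[0, ::10] = 3.0  # expressed in 10% of each group
        norm = make_norm(values)
        res = group_de(norm, norm.cells[:20], norm.cells[20:], min_pct=0.25,
                       logfc_threshold=0.0)
        assert "G00" not in res.index

    def test_identical_groups_nothing_tested(self):
        values = np.tile(np.arange(1.0, 6.0)[:, None], (1, 20))
        norm = make_norm(values)
        res = group_de(norm, norm.cells[:10], norm.cells[10:])
        assert res.empty

    def test_planted_fourfold_marker_recovered(self):
        spec = SimLineSpec(n_cells_sensitive=200, n_cells_resistant=200,
                           effect_log2fc=2.0, pdr_like_fraction=0.0,
                           program_heterogeneity=0.05, nb_dispersion=50.0)
        cm, ann, gt = simulate_line(spec, seed=5)
        from scresist.qc import lognormalize
        norm = lognormalize(cm)
        res = group_de(norm, ann.index[ann.condition == "resistant"],
                       ann.index[ann.condition == "sensitive"])
        up = res.loc[[g for g in gt.marker_up_ids if g in res.index]]
        assert (up["direction"] == "up_in_a").all()
        assert abs(up["log2fc"].mean() - 2.0) < 0.4
        assert (up["p_adj"] < 0.05).all()

    def test_antisymmetry(self, small_norm):
        a, b = small_norm.cells[:15], small_norm.cells[15:]
        fwd = group_de(small_norm, a, b, min_pct=0.0, logfc_threshold=0.0)
        rev = group_de(small_norm, b, a, min_pct=0.0, logfc_threshold=0.0)
        joined = fwd.join(rev, lsuffix="_f", rsuffix="_r")
        np.testing.assert_allclose(joined["log2fc_f"], -joined["log2fc_r"], atol=1e-9)
        np.testing.assert_allclose(joined["p_raw_f"], joined["p_raw_r"], atol=1e-12)

    def test_bh_adjustment_matches_step_up_definition(self, small_norm):
        res = group_de(small_norm, small_norm.cells[:15], small_norm.cells[15:],
                       min_pct=0.0, logfc_threshold=0.0)
        p = res["p_raw"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        stepup = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            stepup[idx] = running
        np.testing.assert_allclose(res["p_adj"].to_numpy(), stepup, atol=1e-12)

    def test_small_group_rejected(self, small_norm):
        with pytest.raises(ValueError, match="3 cells"):
            group_de(small_norm, small_norm.cells[:2], small_norm.cells[2:])


def brute_force_consensus(per_line, min_lines):
    genes = set()
    for table in per_line.values():
        genes |= set(table.index)
    resistant, sensitive = {}, {}
    for g in genes:
        up = [l for l, t in per_line.items()
              if g in t.index and t.loc[g, "direction"] == "up_in_a" and t.loc[g, "p_adj"] < 0.05]
        down = [l for l, t in per_line.items()
               if g in t.index and t.loc[g, "direction"] == "up_in_b" and t.loc[g, "p_adj"] < 0.05]
        if len(up) >= min_lines and not down:
            resistant[g] = sorted(up)
        if len(down) >= min_lines and not up:
            sensitive[g] = sorted(down)
    return resistant, sensitive


def random_de_tables(rng, n_lines=7, n_genes=30):
    lines = {}
    for i in range(n_lines):
        genes = rng.choice([f"g{j}" for j in range(n_genes)],
                           size=rng.integers(5, n_genes), replace=False)
        lines[f"L{i}"] = pd.DataFrame(
            {
                "direction": rng.choice(["up_in_a", "up_in_b"], size=len(genes)),
                "p_adj": rng.choice([0.001, 0.2], size=len(genes)),
                "log2fc": rng.normal(size=len(genes)),
            },
            index=pd.Index(genes, name="gene"),
        )
    return lines


class TestConsensusMarkers:
    def _table(self, entries):
        return pd.DataFrame(
            {
                "direction": [d for _, d in entries],
                "p_adj": [0.001] * len(entries),
            },
            index=pd.Index([g for g, _ in entries], name="gene"),
        )

    def test_two_line_support_qualifies(self):
        per_line = {
            "L1": self._table([("X", "up_in_a")]),
            "L2": self._table([("X", "up_in_a")]),
            "L3": self._table([]),
        }
        markers = consensus_markers(per_line, min_lines=2)
        assert markers.resistant_specific == {"X": ["L1", "L2"]}

    def test_opposite_detection_disqualifies(self):
        per_line = {
            "L1": self._table([("X", "up_in_a")]),
            "L2": self._table([("X", "up_in_a")]),
            "L3": self._table([("X", "up_in_a")]),
            "L4": self._table([("X", "up_in_b")]),
        }
        markers = consensus_markers(per_line, min_lines=2)
        assert "X" not in markers.resistant_specific
        assert "X" not in markers.sensitive_specific  # only 1 down line anyway

    def test_matches_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            per_line = random_de_tables(rng)
            markers = consensus_markers(per_line, min_lines=2)
            res, sens = brute_force_consensus(per_line, 2)
            assert markers.resistant_specific == res
            assert markers.sensitive_specific == sens

    def test_invariant_under_line_ordering(self):
        rng = np.random.default_rng(23)
        per_line = random_de_tables(rng)
        fwd = consensus_markers(per_line, min_lines=2)
        rev = consensus_markers(dict(reversed(per_line.items())), min_lines=2)
        assert fwd.resistant_specific == rev.resistant_specific
        assert fwd.sensitive_specific == rev.sensitive_specific


def exact_hypergeom_tail(k, N, K, n):
    """P(X >= k) as an exact rational, by direct summation."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


class TestOraEnrichment:
    def test_query_equals_universe_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        res = ora_enrichment(genes, {"S": genes}, genes)
        assert res.loc["S", "p_raw"] == pytest.approx(1.0)

    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        res = ora_enrichment(universe[:5], {"S": universe[:5]}, universe)
        assert res.loc["S", "p_raw"] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_matches_exact_tail_sum(self):
        rng = np.random.default_rng(31)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(30):
            K = int(rng.integers(3, 30))
            n = int(rng.integers(3, 30))
            members = list(rng.choice(universe, K, replace=False))
            query = list(rng.choice(universe, n, replace=False))
            res = ora_enrichment(query, {"S": members}, universe)
            k = int(res.loc["S", "k"])
            assert res.loc["S", "p_raw"] == pytest.approx(
                exact_hypergeom_tail(k, 60, K, n), abs=1e-12
            )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ora_enrichment(["x"], {"S": ["a"]}, ["a", "b"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora_enrichment([], {"S": ["a"]}, [])


class TestSignatureScore:
    def test_constant_matrix_scores_zero(self):
        norm = make_norm(np.full((4, 10), 2.0))
        scores = signature_score(norm, ["G00", "G01"])
        np.testing.assert_allclose(scores.to_numpy(), 0.0)

    def test_single_gene_set_equals_gene_z(self, small_norm):
        gene = small_norm.genes[4]
        scores = signature_score(small_norm, [gene])
        row = small_norm.values[4]
        z = (row - row.mean()) / row.std()
        np.testing.assert_allclose(scores.to_numpy(), z, atol=1e-12)

    def test_planted_program_cells_score_higher(self):
        spec = SimLineSpec(n_cells_sensitive=100, n_cells_resistant=100)
        cm, ann, gt = simulate_line(spec, seed=8)
        from scresist.qc import lognormalize
        norm = lognormalize(cm)
        scores = signature_score(norm, gt.marker_up_ids)
        res = scores[ann.condition == "resistant"]
        sens = scores[ann.condition == "sensitive"]
        p = stats.mannwhitneyu(res, sens, alternative="greater").pvalue
        assert p < 0.01

    def test_no_overlap_names_set(self, small_norm):
        with pytest.raises(ValueError, match="MYSET"):
            signature_score(small_norm, ["nope"], name="MYSET")
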