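"""Signature selection: variance filter, point-biserial statistics, clustering."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from rbratio.errors import (
    DegenerateMetricError,
    DegeneratePhenotypeError,
    InsufficientDataError,
)
from rbratio.io import ExpressionMatrix, PhenotypeLabels
from rbratio.signature import (
    Dendrogram,
    average_linkage,
    cluster_2d,
    correlation_distance_matrix,
    derive_signature,
    gene_sd,
    pearson_permutation_p,
    pearson_with_phenotype,
)
from rbratio.simulate import SimulationConfig, simulate_expression_panel


class TestGeneSd:
    def test_constant_vector_has_zero_sd(self):
        assert gene_sd([0.3, 0.3, 0.3]) == 0.0

    def test_two_point_hand_value(self):
        # sqrt(((0.2-0)^2 + (-0.2-0)^2) / 1) = sqrt(0.08)
        assert gene_sd([0.2, -0.2]) == pytest.approx(math.sqrt(0.08), rel=1e-12)

    def test_single_value_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            gene_sd([0.1])

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=20),
        st.floats(-10, 10),
    )
    def test_shift_invariance(self, values, c):
        shifted = [v + c for v in values]
        assert gene_sd(shifted) == pytest.approx(gene_sd(values), abs=1e-9)


class TestPearsonWithPhenotype:
    def test_values_equal_to_labels_give_perfect_correlation(self):
        y = np.array([1, 1, 0, 0, 1, 0], dtype=float)
        r, p, flag = pearson_with_phenotype(y.copy(), y)
        assert (r, p, flag) == (1.0, 0.0, False)

    def test_constant_gene_is_flagged_degenerate(self):
        y = np.array([1, 0, 1, 0], dtype=float)
        assert pearson_with_phenotype([0.5] * 4, y) == (0.0, 1.0, True)

    def test_single_class_labels_raise(self):
        with pytest.raises(DegeneratePhenotypeError):
            pearson_with_phenotype([1.0, 2.0, 3.0], np.ones(3))

    def test_matches_pooled_t_test_on_random_genes(self, rng):
        """Point-biserial identity: the Pearson p against 0/1 labels equals
        the pooled two-sample t-test p on the same gene."""
        y = np.array([1] * 9 + [0] * 7, dtype=float)
        for _ in range(50):
            x = rng.normal(size=y.size) + y * rng.normal()
            r, p, _ = pearson_with_phenotype(x, y)
            t_p = sps.ttest_ind(x[y == 1], x[y == 0], equal_var=True).pvalue
            assert p == pytest.approx(t_p, rel=1e-10)
            # r also matches scipy's pearsonr
            assert r == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)

    def test_label_swap_negates_r_and_keeps_p(self, rng):
        y = np.array([1, 1, 1, 0, 0, 0, 1, 0], dtype=float)
        x = rng.normal(size=8)
        r1, p1, _ = pearson_with_phenotype(x, y)
        r2, p2, _ = pearson_with_phenotype(x, 1 - y)
        assert r2 == pytest.approx(-r1, abs=1e-14)
        assert p2 == pytest.approx(p1, abs=1e-14)

    def test_analytic_p_agrees_with_permutation_oracle(self):
        """n = 8 panel with values [1..4] vs [-1..-4]: the t-transform p must
        sit within 3 Monte-Carlo standard errors of an exact-style
        permutation p."""
        x = np.array([1, 2, 3, 4, -1, -2, -3, -4], dtype=float)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        r, p, _ = pearson_with_phenotype(x, y)
        n_res = 100_000
        p_perm = pearson_permutation_p(x, y, n_resamples=n_res, rng=7)
        se = math.sqrt(p_perm * (1 - p_perm) / n_res)
        # discreteness floor: C(8,4)=70 label splits
        assert abs(p - p_perm) <= max(3 * se, 2 / 70)
        assert r == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)


class TestDeriveSignature:
    def _planted(self, seed=1, effect=1.0, n_null=500, noise_sd=0.1):
        cfg = SimulationConfig(
            n_pos=15, n_neg=15, n_signature=20, n_null=n_null,
            effect=effect, noise_sd=noise_sd, seed=seed,
        )
        return simulate_expression_panel(cfg)

    def test_recovers_planted_genes_with_few_false_positives(self):
        """Strong planted effect: every planted gene selected, null
        selections near the 500 * alpha = 0.5 expectation."""
        false_positives = 0
        for seed in range(5):
            matrix, labels, truth = self._planted(seed=seed)
            sig = derive_signature(matrix, labels, sd_min=0.1, alpha=0.001)
            assert set(truth) <= set(sig.gene_ids)
            false_positives += len(set(sig.gene_ids) - set(truth))
        assert false_positives <= 5

    def test_infinite_sd_threshold_empties_signature(self, tiny_matrix, tiny_labels):
        sig = derive_signature(tiny_matrix, tiny_labels, sd_min=math.inf)
        assert len(sig) == 0

    def test_permissive_thresholds_select_all_nondegenerate(self, rng):
        values = rng.normal(size=(6, 6))
        matrix = ExpressionMatrix(
            tuple(f"g{i}" for i in range(6)),
            tuple(f"s{j}" for j in range(6)),
            values,
        )
        labels = PhenotypeLabels({f"s{j}": int(j < 3) for j in range(6)})
        sig = derive_signature(matrix, labels, sd_min=0.0, alpha=1.0)
        assert set(sig.gene_ids) == {f"g{i}" for i in range(6)}

    def test_selection_is_monotone_in_thresholds(self):
        matrix, labels, _ = self._planted(seed=3, effect=0.4, n_null=100, noise_sd=0.2)
        loose = derive_signature(matrix, labels, sd_min=0.05, alpha=0.05)
        tight = derive_signature(matrix, labels, sd_min=0.15, alpha=0.001)
        assert set(tight.gene_ids) <= set(loose.gene_ids)

    def test_sorted_by_ascending_p_then_gene_id(self):
        matrix, labels, _ = self._planted(seed=4)
        sig = derive_signature(matrix, labels)
        keys = [(g.p, g.gene_id) for g in sig.selected]
        assert keys == sorted(keys)

    def test_bh_column_is_attached_but_not_selective(self):
        matrix, labels, _ = self._planted(seed=5)
        plain = derive_signature(matrix, labels)
        with_q = derive_signature(matrix, labels, bh=True)
        assert plain.gene_ids == with_q.gene_ids
        assert all(g.q is not None and g.q >= g.p for g in with_q.selected)


def _cophenetic(tree: Dendrogram) -> np.ndarray:
    """Cophenetic distance matrix from a Dendrogram (test-side helper)."""
    n = len(tree.ids)
    members = {i: {i} for i in range(n)}
    d = np.zeros((n, n))
    for k, (a, b, h) in enumerate(tree.merges):
        for i in members[a]:
            for j in members[b]:
                d[i, j] = d[j, i] = h
        members[n + k] = members[a] | members[b]
    return d


class TestClustering:
    def test_identical_samples_merge_first_at_zero_height(self, rng):
        values = rng.normal(size=(5, 3))
        values[:, 1] = values[:, 0]  # sa == sb profile-wise
        matrix = ExpressionMatrix(
            tuple(f"g{i}" for i in range(5)), ("sa", "sb", "sc"), values
        )
        result = cluster_2d(matrix)
        first = result.sample_tree.merges[0]
        assert {first[0], first[1]} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_four_leaf_merge_order_matches_hand_computed_upgma(self):
        # hand-built dissimilarities; UPGMA by hand:
        # merge (A,B) at 0.1; d(AB,C)=0.45, d(AB,D)=0.85 -> merge (AB,C) at
        # 0.45; d(ABC,D)=mean(0.8,0.9,0.95)=53/60
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.8],
                [0.1, 0.0, 0.5, 0.9],
                [0.4, 0.5, 0.0, 0.95],
                [0.8, 0.9, 0.95, 0.0],
            ]
        )
        tree = average_linkage(d, ("A", "B", "C", "D"))
        assert tree.merges[0] == (0, 1, pytest.approx(0.1))
        assert tree.merges[1] == (4, 2, pytest.approx(0.45))
        assert tree.merges[2] == (5, 3, pytest.approx(53 / 60))
        assert tree.leaf_order() == ("A", "B", "C", "D")

    def test_equal_distance_ties_merge_lexicographically_smallest_pair(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        tree = average_linkage(d, ("beta", "alpha", "gamma"))
        # pair (alpha, beta) sorts before (alpha, gamma) and (beta, gamma)
        assert {tree.merges[0][0], tree.merges[0][1]} == {0, 1}

    def test_agrees_with_scipy_average_linkage_on_random_data(self, rng):
        """Cophenetic distances must match scipy's UPGMA exactly (ties are
        measure-zero on continuous random input)."""
        values = rng.normal(size=(12, 8))
        d = correlation_distance_matrix(values)
        tree = average_linkage(d, tuple(f"g{i}" for i in range(12)))
        z = sch.linkage(squareform(d, checks=False), method="average")
        ours = squareform(_cophenetic(tree), checks=False)
        scipys = sch.cophenet(z)
        np.testing.assert_allclose(ours, scipys, atol=1e-9)

    def test_gene_tree_invariant_to_per_gene_constant_shift(self, rng):
        """Pearson is shift-invariant per vector, so adding a constant to a
        gene's profile cannot change the gene tree (the sample tree may
        move: sample columns gain a non-constant vector)."""
        values = rng.normal(size=(6, 10))
        ids = tuple(f"g{i}" for i in range(6))
        samples = tuple(f"s{j}" for j in range(10))
        m1 = ExpressionMatrix(ids, samples, values)
        m2 = ExpressionMatrix(ids, samples, values + rng.normal(size=(6, 1)))
        r1, r2 = cluster_2d(m1), cluster_2d(m2)
        assert r1.gene_order == r2.gene_order
        for (a1, b1, h1), (a2, b2, h2) in zip(r1.gene_tree.merges, r2.gene_tree.merges):
            assert (a1, b1) == (a2, b2)
            assert h1 == pytest.approx(h2, abs=1e-9)

    def test_zero_variance_gene_dropped_with_warning(self, rng):
        values = rng.normal(size=(4, 5))
        values[2] = 0.7
        matrix = ExpressionMatrix(
            ("g0", "g1", "flat", "g3"), tuple(f"s{j}" for j in range(5)), values
        )
        with pytest.warns(UserWarning, match="flat"):
            result = cluster_2d(matrix)
        assert result.dropped_genes == ("flat",)
        assert "flat" not in result.gene_order

    def test_all_constant_matrix_is_degenerate(self):
        matrix = ExpressionMatrix(
            ("g0", "g1"), ("s0", "s1", "s2"), np.full((2, 3), 1.5)
        )
        with pytest.raises(DegenerateMetricError):
            cluster_2d(matrix)

    def test_root_bipartition_separates_planted_classes(self):
        """With a strong planted signature the sample tree's top split must
        be exactly the two phenotype classes."""
        cfg = SimulationConfig(n_pos=8, n_neg=6, n_signature=20, n_null=0,
                               effect=2.0, noise_sd=0.15, seed=11)
        matrix, labels, truth = simulate_expression_panel(cfg)
        result = cluster_2d(matrix.subset_genes(truth))
        side_a, side_b = result.sample_tree.root_bipartition()
        classes = (
            frozenset(s for s in labels.sample_ids if labels[s] == 1),
            frozenset(s for s in labels.sample_ids if labels[s] == 0),
        )
        assert {side_a, side_b} == set(classes)

    def test_newick_is_parseable_and_names_all_leaves(self, rng):
        values = rng.normal(size=(5, 6))
        tree = average_linkage(
            correlation_distance_matrix(values), ("a", "b", "c", "d", "e")
        )
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in "abcde":
            assert leaf in nwk
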