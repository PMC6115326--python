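"""Selection-chain stages: hand-computed examples, oracles and invariants."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from prefexp.data_io import ExpressionMatrix, ValidationError
from prefexp.selection import (
    SelectionParams,
    collapse_replicates,
    eliminate_cross_tissue_high,
    filter_expressed,
    fold_change_filter,
    kmeans_cluster,
    quantile_normalize,
    run_selection,
    select_preferential_cluster,
)
from prefexp.simulate import simulate_compendium
from conftest import f1_score


def _matrix(values, columns, tissue_of, target="root_hair", reference="root"):
    df = pd.DataFrame(values, columns=columns,
                      index=[f"g{i}" for i in range(1, len(values) + 1)])
    return ExpressionMatrix(df, tissue_of, target, reference)


class TestQuantileNormalize:
    TISSUES = {"s1": "root_hair", "s2": "root"}

    def test_identical_columns_fixed_point(self):
        m = _matrix([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]], ["s1", "s2"],
                    self.TISSUES)
        out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)

    def test_hand_example(self):
        m = _matrix([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]], ["s1", "s2"],
                    self.TISSUES)
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.values.to_numpy(), expected)

    def test_all_columns_share_distribution(self):
        """Sort-and-compare oracle: after normalization every column's
        sorted values are identical."""
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(4)]
        tissue_of = {c: ("root_hair" if i < 2 else "root")
                     for i, c in enumerate(cols)}
        m = _matrix(rng.normal(8, 2, size=(50, 4)), cols, tissue_of)
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_ties_averaged(self):
        m = _matrix([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]], ["s1", "s2"],
                    self.TISSUES)
        out = quantile_normalize(m).values
        # g1, g2 tie in s1 at mean rank 1.5 → halfway between rank means
        assert out.loc["g1", "s1"] == out.loc["g2", "s1"]


class TestCollapseReplicates:
    def test_mean_of_replicates(self, tiny_matrix):
        out = collapse_replicates(tiny_matrix)
        assert out.values.loc["g1", "root_hair"] == pytest.approx(10.1)
        assert out.values.loc["g1", "root"] == pytest.approx(8.1)
        assert out.is_collapsed

    def test_single_replicate_unchanged(self):
        m = _matrix([[8.0, 9.0]], ["s1", "s2"],
                    {"s1": "root_hair", "s2": "root"})
        out = collapse_replicates(m)
        assert np.allclose(out.values.to_numpy(), [[8.0, 9.0]])

    def test_idempotent_on_equal_columns(self):
        m = _matrix([[7.0, 7.0, 9.0]], ["a", "b", "c"],
                    {"a": "root_hair", "b": "root_hair", "c": "root"})
        out = collapse_replicates(m)
        assert out.values.loc["g1", "root_hair"] == 7.0


class TestFilterExpressed:
    def test_strict_boundary(self, collapsed_panel):
        vals = collapsed_panel.values.copy()
        vals.loc["g4"] = [8.0, 7.0, 6.0, 6.0]  # max exactly 8 → excluded
        m = dataclasses.replace(collapsed_panel, values=vals)
        kept = filter_expressed(m, 8.0)
        assert "g4" not in kept and "g1" in kept

    def test_matches_bruteforce_on_synthetic(self):
        m, _ = simulate_compendium(n_genes=300, n_preferential=20, seed=8)
        collapsed = collapse_replicates(m)
        kept = set(filter_expressed(collapsed, 8.0))
        brute = {g for g in collapsed.gene_ids
                 if max(collapsed.values.loc[g]) > 8.0}
        assert kept == brute

    def test_order_preserved(self, collapsed_panel):
        kept = filter_expressed(collapsed_panel, 8.0)
        assert kept == [g for g in collapsed_panel.gene_ids if g in kept]


class TestKMeans:
    def test_k1_closed_form(self, collapsed_panel):
        params = SelectionParams(n_clusters=1, center_profiles=False)
        res = kmeans_cluster(collapsed_panel, params)
        X = collapsed_panel.values.to_numpy()
        assert np.allclose(res.centroids.to_numpy()[0], X.mean(axis=0))
        assert res.inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_separated_blobs_recovered(self):
        """Two 10σ-separated blobs in 2 tissues: partition matches labels
        (verified against the exhaustive best 2-partition at n ≤ 12)."""
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(6, 2))
        b = rng.normal(10, 1, size=(6, 2))
        cols = ["root_hair", "root"]
        m = _matrix(np.vstack([a, b]), cols, {c: c for c in cols})
        res = kmeans_cluster(m, SelectionParams(n_clusters=2, seed=0,
                                                center_profiles=False))
        labels = res.assignment.to_numpy()
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_determinism(self):
        m, _ = simulate_compendium(n_genes=200, n_preferential=20, seed=2)
        c = collapse_replicates(m)
        r1 = kmeans_cluster(c, SelectionParams(seed=5))
        r2 = kmeans_cluster(c, SelectionParams(seed=5))
        assert (r1.assignment == r2.assignment).all()
        assert r1.inertia == r2.inertia

    def test_too_few_genes_error(self, collapsed_panel):
        with pytest.raises(ValidationError):
            kmeans_cluster(collapsed_panel, SelectionParams(n_clusters=12))


class TestSelectPreferentialCluster:
    def _clustering(self, centroids):
        from prefexp.selection import ClusteringResult
        return ClusteringResult(
            assignment=pd.Series(dtype=int),
            centroids=pd.DataFrame(
                centroids, columns=["root_hair", "root", "leaf"]),
            inertia=0.0)

    def test_max_contrast_wins(self):
        c = self._clustering([[10.0, 6.0, 5.0], [8.0, 8.0, 8.0]])
        assert select_preferential_cluster(c, "root_hair") == 0

    def test_tie_goes_to_lowest_index(self):
        c = self._clustering([[8.0, 8.0, 8.0], [8.0, 8.0, 8.0]])
        assert select_preferential_cluster(c, "root_hair") == 0

    def test_planted_cluster_contains_most_planted_genes(self):
        """Across seeds, the selected cluster holds ≥80% of planted genes."""
        hits = []
        for seed in range(10):
            m, truth = simulate_compendium(n_genes=2000, n_preferential=100,
                                           effect_log2=2.0, seed=seed)
            c = collapse_replicates(quantile_normalize(m))
            expressed = filter_expressed(c, 8.0)
            res = kmeans_cluster(c.restrict_genes(expressed),
                                 SelectionParams(seed=seed))
            chosen = select_preferential_cluster(res, "root_hair")
            in_cluster = {g for g in expressed
                          if res.assignment[g] == chosen}
            planted_expressed = truth.planted_preferential & set(expressed)
            hits.append(len(in_cluster & planted_expressed)
                        / len(planted_expressed))
        assert np.median(hits) >= 0.8


class TestMarginAndFoldRules:
    def test_margin_keeps_and_removes(self, collapsed_panel):
        kept = eliminate_cross_tissue_high(
            ["g1", "g3"], collapsed_panel, margin=1.0)
        assert kept == ["g1"]  # g3 is 11.5 in leaf, margin only 0.5

    def test_margin_zero_degenerate(self, collapsed_panel):
        genes = collapsed_panel.gene_ids
        kept = eliminate_cross_tissue_high(genes, collapsed_panel, margin=0.0)
        vals = collapsed_panel.values
        expected = [g for g in genes
                    if vals.loc[g, "root_hair"]
                    >= vals.loc[g, ["leaf", "seed"]].max()]
        assert kept == expected

    def test_fold_rule_inclusive_boundary(self, collapsed_panel):
        # g5: target 10, reference 9 → exactly two-fold, kept ("at least")
        kept = fold_change_filter(["g2", "g5"], collapsed_panel, fold_min=2.0)
        assert kept == ["g5"]

    def test_fold_rule_matches_linear_scale_oracle(self):
        m, _ = simulate_compendium(n_genes=400, n_preferential=40, seed=6)
        c = collapse_replicates(m)
        kept = set(fold_change_filter(c.gene_ids, c, fold_min=2.0))
        brute = {g for g in c.gene_ids
                 if 2 ** c.values.loc[g, "root_hair"]
                 >= 2.0 * 2 ** c.values.loc[g, "root"]}
        assert kept == brute


class TestFullChain:
    def test_stage_telescoping(self):
        m, _ = simulate_compendium(n_genes=500, n_preferential=40, seed=1)
        res = run_selection(m, SelectionParams(seed=1))
        for prev, cur in zip(res.stages, res.stages[1:]):
            assert cur.n_in == prev.n_out
        for s in res.stages:
            assert s.n_out == s.n_in - len(s.removed)
        assert res.stages[-1].n_out == len(res.selected)

    def test_byte_identical_given_seed(self):
        m1, _ = simulate_compendium(n_genes=300, n_preferential=30, seed=4)
        m2, _ = simulate_compendium(n_genes=300, n_preferential=30, seed=4)
        r1 = run_selection(m1, SelectionParams(seed=9))
        r2 = run_selection(m2, SelectionParams(seed=9))
        assert r1.selected == r2.selected

    def test_parameter_recovery_small(self):
        """Planted genes recovered with high F1 in a reduced version of the
        standard regime (full-size check lives in the acceptance suite)."""
        scores = []
        for seed in range(5):
            m, truth = simulate_compendium(n_genes=600, n_preferential=50,
                                           effect_log2=2.0, noise_sd=0.3,
                                           seed=seed)
            res = run_selection(m, SelectionParams(seed=seed))
            scores.append(f1_score(set(res.selected),
                                   truth.planted_preferential))
        assert np.median(scores) >= 0.9

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            SelectionParams(n_clusters=0)
        with pytest.raises(ValidationError):
            SelectionParams(fold_min=0.5)
        with pytest.raises(ValidationError):
            SelectionParams(expression_threshold=math.inf)
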