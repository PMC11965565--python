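"""Feature integration, clustering, embeddings, mutation scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from circapheno import phenotyping
from circapheno.exceptions import ConfigurationError
from circapheno.simulate import generate_phenotype_table


class TestCorrelation:
    def test_perfect_linear_relation(self, rng):
        x = rng.normal(0, 1, 15)
        ft = pd.DataFrame({"x": x, "y": 2 * x + 1})
        r, p = phenotyping.correlation_matrix(ft)
        assert r.loc["x", "x"] == pytest.approx(1.0)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] < 1e-10

    def test_sampling_spread_of_moderate_correlation(self):
        rho, errs = 0.6, []
        for seed in range(10):
            g = np.random.default_rng(seed)
            x = g.normal(0, 1, 15)
            y = rho * x + np.sqrt(1 - rho**2) * g.normal(0, 1, 15)
            r, _ = phenotyping.correlation_matrix(pd.DataFrame({"x": x, "y": y}))
            errs.append(abs(r.loc["x", "y"] - rho))
        assert np.median(errs) < 0.25

    def test_zero_variance_column_reported_missing(self, rng):
        ft = pd.DataFrame({"x": rng.normal(0, 1, 10), "c": np.ones(10)})
        r, _ = phenotyping.correlation_matrix(ft)
        assert np.isnan(r.loc["x", "c"])

    def test_star_annotation_thresholds(self):
        assert phenotyping.significance_stars(0.02) == "*"
        assert phenotyping.significance_stars(0.002) == "**"
        assert phenotyping.significance_stars(2e-5) == "****"
        assert phenotyping.significance_stars(0.2) == ""


class TestScaling:
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_minmax_is_order_preserving_and_bounded(self, values):
        df = pd.DataFrame({"v": values})
        scaled = phenotyping.minmax_scale(df)["v"]
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0
        # order-preserving up to float-precision ties
        order = df["v"].sort_values().index
        assert scaled.loc[order].is_monotonic_increasing


class TestPCA:
    def test_duplicated_column_collapses_to_one_component(self, rng):
        x = rng.normal(0, 1, 12)
        ft = phenotyping.minmax_scale(pd.DataFrame({"a": x, "b": x}))
        res = phenotyping.pca_embed(ft)
        assert res.explained_pct[0] > 99.0

    def test_isotropic_noise_splits_variance_evenly(self, rng):
        ft = pd.DataFrame(rng.normal(0, 1, (400, 2)), columns=["a", "b"])
        res = phenotyping.pca_embed(ft)
        assert res.explained_pct[0] < 60.0

    def test_planted_clusters_separate_on_pc1(self):
        feats, labels = generate_phenotype_table(5, seed=2)
        res = phenotyping.pca_embed(phenotyping.minmax_scale(feats))
        pc1 = res.scores["PC1"]
        spread_between = pc1.groupby(labels).mean().std()
        spread_within = pc1.groupby(labels).std().mean()
        assert spread_between > spread_within

    def test_too_many_components_rejected(self, rng):
        ft = pd.DataFrame(rng.normal(0, 1, (5, 2)))
        with pytest.raises(ConfigurationError):
            phenotyping.pca_embed(ft, n_components=3)


class TestClustering:
    def test_four_archetypes_zero_jitter_recovered_exactly(self):
        feats, labels = generate_phenotype_table(3, seed=5, jitter=(0, 0, 0))
        assign = phenotyping.select_k_and_cluster(feats, seed=0)
        assert assign.k == 4
        assert adjusted_rand_score(labels, assign.cluster_id) == 1.0
        assert (assign.labels == labels).all()

    def test_default_jitter_archetypes_recovered(self):
        feats, labels = generate_phenotype_table(4, seed=11)
        assign = phenotyping.select_k_and_cluster(feats, seed=0)
        assert adjusted_rand_score(labels, assign.cluster_id) > 0.8

    def test_two_blobs_give_knee_at_two(self, rng):
        a = rng.normal(0, 0.02, (8, 3))
        b = rng.normal(1, 0.02, (8, 3))
        feats = pd.DataFrame(
            np.vstack([a, b]), columns=list(phenotyping.CLUSTER_FEATURES)
        )
        feats["period_h"] = feats["period_h"] * 4 + 24
        assign = phenotyping.select_k_and_cluster(feats, seed=0)
        assert assign.k == 2

    def test_single_blob_has_weak_silhouette(self, rng):
        feats = pd.DataFrame(
            rng.normal(0, 1, (30, 3)), columns=list(phenotyping.CLUSTER_FEATURES)
        )
        assign = phenotyping.select_k_and_cluster(feats, seed=0)
        assert all(s < 0.45 for s in assign.silhouette_by_k.values())

    def test_fewer_rows_than_clusters_rejected(self):
        feats, _ = generate_phenotype_table(1, seed=0)
        assign = phenotyping.select_k_and_cluster(feats.iloc[:3], k_range=[2], seed=0)
        assert assign.k == 2  # only feasible k survives
        with pytest.raises(ConfigurationError):
            phenotyping.select_k_and_cluster(feats.iloc[:2], k_range=[5], seed=0)

    def test_labels_depend_on_centroids_not_cluster_indices(self):
        feats, labels = generate_phenotype_table(3, seed=9, jitter=(0, 0, 0))
        shuffled = feats.sample(frac=1.0, random_state=1)
        assign = phenotyping.select_k_and_cluster(shuffled, seed=7)
        assert (assign.labels == labels.loc[shuffled.index]).all()


class TestUMAP:
    def test_coincident_archetypes_stay_mutually_nearest(self):
        # zero-jitter archetypes: same-class points must be each other's
        # nearest neighbours in the embedding
        from sklearn.neighbors import NearestNeighbors

        feats, labels = generate_phenotype_table(3, seed=4, jitter=(0, 0, 0))
        emb = phenotyping.umap_embed(phenotyping.minmax_scale(feats), seed=0)
        nn = NearestNeighbors(n_neighbors=3).fit(emb.to_numpy())
        _, idx = nn.kneighbors(emb.to_numpy())
        lab = labels.to_numpy()
        same = [set(lab[row[1:]]) == {lab[row[0]]} for row in idx]
        assert all(same)

    def test_planted_clusters_neighbor_preservation(self):
        feats, labels = generate_phenotype_table(4, seed=6)
        scaled = phenotyping.minmax_scale(feats)
        emb = phenotyping.umap_embed(scaled, seed=0)
        assert phenotyping.neighbor_preservation(scaled, emb, k=3) > 0.8

    def test_too_few_rows_rejected(self, rng):
        ft = pd.DataFrame(rng.normal(0, 1, (3, 4)))
        with pytest.raises(ConfigurationError):
            phenotyping.umap_embed(ft, n_neighbors=3)


class TestMutationScoring:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["cell_line", "gene", "variant_class"])

    def test_no_mutations_scores_zero(self):
        table = self.make_table([("L1", "TP53", "missense")])  # off-panel gene
        score = phenotyping.score_mutations(table, ["PER2"], cell_lines=["L1"])
        assert score.per_line["L1"] == 0.0

    def test_silent_plus_frameshift_scores_four(self):
        table = self.make_table([("L1", "PER2", "silent"), ("L1", "CRY1", "frameshift")])
        score = phenotyping.score_mutations(table, ["PER2", "CRY1"])
        assert score.per_line["L1"] == 4.0

    def test_group_score_is_mean_over_lines(self):
        table = self.make_table(
            [("L1", "PER2", "missense"), ("L2", "PER2", "frameshift"),
             ("L2", "CRY1", "frameshift")]
        )
        score = phenotyping.score_mutations(table, ["PER2", "CRY1"])
        groups = score.group_scores({"L1": "g", "L2": "g"})
        assert groups["g"] == pytest.approx((2 + 6) / 2)

    def test_mean_per_line_convention_switchable(self):
        table = self.make_table([("L1", "PER2", "silent"), ("L1", "CRY1", "frameshift")])
        score = phenotyping.score_mutations(table, ["PER2", "CRY1"], per_line="mean")
        assert score.per_line["L1"] == pytest.approx(2.0)

    def test_unknown_class_strict_raises_lenient_warns(self):
        table = self.make_table([("L1", "PER2", "mystery")])
        with pytest.raises(ConfigurationError):
            phenotyping.score_mutations(table, ["PER2"], strict=True)
        with pytest.warns(UserWarning):
            score = phenotyping.score_mutations(table, ["PER2"])
        assert score.per_line["L1"] == 2.0

    def test_group_score_invariant_to_line_order(self):
        rows = [("L1", "PER2", "missense"), ("L2", "CRY1", "nonsense"),
                ("L3", "PER1", "silent")]
        a = phenotyping.score_mutations(self.make_table(rows), ["PER1", "PER2", "CRY1"])
        b = phenotyping.score_mutations(self.make_table(rows[::-1]), ["PER1", "PER2", "CRY1"])
        assert a.per_line.sort_index().equals(b.per_line.sort_index())

    def test_default_panel_and_severity_map_load(self):
        genes = phenotyping.default_core_clock_genes()
        assert len(genes) == 16 and "PER2" in genes
        sev = phenotyping.default_severity_map()
        assert sev["silent"] == 1 and sev["frameshift"] == 3

    def test_burden_linkage_produced(self):
        table = self.make_table(
            [("L1", "PER2", "missense"), ("L2", "CRY1", "nonsense")]
        )
        score = phenotyping.score_mutations(table, ["PER2", "CRY1"])
        assert score.burden_linkage is not None


class TestClusterTable:
    def test_expression_clustering_orders_both_axes(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (8, 5)))
        row, col = phenotyping.cluster_table(table)
        assert row.shape == (7, 4) and col.shape == (4, 4)
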