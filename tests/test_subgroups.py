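"""Embedding, silhouette-guided k selection, hierarchical subgroups."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ctcmet import (cluster_cells, count_subgroups_per_patient,
                    cross_check_embeddings, embed_cells, silhouette_select_k)
from ctcmet.subgroups import Embedding, SubgroupError


def _pass_through(points):
    df = pd.DataFrame(np.asarray(points, float), columns=["dim1", "dim2"],
                      index=[f"c{i}" for i in range(len(points))])
    return Embedding(df, "passthrough", {}, 0)


FOUR_POINTS = [(0, 0), (0, 1), (10, 10), (10, 11)]


class TestSilhouetteSelection:
    def test_two_pairs_select_k2_with_hand_computed_silhouette(self):
        """For two tight, distant pairs the per-point silhouette is
        (b - a)/max(a, b) with a = 1 and b = mean distance to the other
        pair, evaluated directly from the coordinates."""
        emb = _pass_through(FOUR_POINTS)
        report = silhouette_select_k(emb, k_range={2, 3})
        assert report.selected_k == 2
        pts = np.asarray(FOUR_POINTS, float)
        a = 1.0  # intra-pair distance
        b = np.mean(np.linalg.norm(pts[0] - pts[2:], axis=1))
        expected = (b - a) / max(a, b)
        # all four points are symmetric up to the +-1 offset
        assert report.mean_silhouettes[2] == pytest.approx(expected, abs=0.01)
        assert report.mean_silhouettes[2] > 0.9

    def test_single_candidate_trivially_selected(self):
        emb = _pass_through(FOUR_POINTS)
        assert silhouette_select_k(emb, k_range={2}).selected_k == 2

    def test_matches_direct_silhouette_definition(self):
        """Mean silhouette equals an independently coded evaluation of
        s(i) = (b - a)/max(a, b) over all pairwise distances (n <= 50)."""
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (20, 2)),
                         rng.normal(6, 1, (15, 2)),
                         rng.normal((0, 8), 1, (15, 2))])
        emb = _pass_through(pts)
        report = silhouette_select_k(emb, k_range=range(2, 6))
        labels = cluster_cells(emb, report.selected_k).labels.to_numpy()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        s = np.empty(len(pts))
        for i in range(len(pts)):
            same = (labels == labels[i])
            a = d[i, same & (np.arange(len(pts)) != i)].mean()
            b = min(d[i, labels == other].mean()
                    for other in np.unique(labels) if other != labels[i])
            s[i] = (b - a) / max(a, b)
        assert report.mean_silhouettes[report.selected_k] == \
            pytest.approx(s.mean(), abs=1e-10)

    def test_invalid_k_range_rejected(self):
        with pytest.raises(SubgroupError, match="k_range"):
            silhouette_select_k(_pass_through(FOUR_POINTS), k_range={1, 2})


class TestClusterCells:
    def test_k1_puts_everything_together(self):
        asg = cluster_cells(_pass_through(FOUR_POINTS), k=1)
        assert set(asg.labels) == {1}

    def test_two_pairs_recovered_exactly(self):
        asg = cluster_cells(_pass_through(FOUR_POINTS), k=2)
        assert asg.labels.iloc[0] == asg.labels.iloc[1]
        assert asg.labels.iloc[2] == asg.labels.iloc[3]
        assert asg.labels.iloc[0] != asg.labels.iloc[2]

    def test_sizes_non_increasing_by_label(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.5, (12, 2)),
                         rng.normal(8, 0.5, (5, 2)),
                         rng.normal((0, 9), 0.5, (8, 2))])
        asg = cluster_cells(_pass_through(pts), k=3)
        sizes = asg.sizes.to_numpy()
        assert (np.diff(sizes) <= 0).all()
        assert sizes.sum() == len(pts)
        assert list(asg.sizes.index) == [1, 2, 3]

    def test_k_above_n_rejected(self):
        with pytest.raises(SubgroupError, match="exceeds"):
            cluster_cells(_pass_through(FOUR_POINTS), k=9)


class TestEmbedding:
    def test_fixed_seed_deterministic(self, subgroup_dataset):
        *_, scaled, _ = subgroup_dataset
        e1 = embed_cells(scaled, seed=42)
        e2 = embed_cells(scaled, seed=42)
        pd.testing.assert_frame_equal(e1.coords, e2.coords)
        assert np.allclose(e1.coords.mean(axis=0), 0, atol=1e-6)

    def test_duplicate_rows_land_together(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (20, 20)),
                       rng.normal(5, 1, (20, 20))])
        X[1] = X[0]
        emb = embed_cells(pd.DataFrame(X), perplexity=5, pca_components=None)
        coords = emb.coords.to_numpy()
        span = np.ptp(coords, axis=0).max()
        d01 = np.linalg.norm(coords[0] - coords[1])
        assert d01 < 0.01 * span

    def test_too_few_cells_for_perplexity_rejected(self):
        with pytest.raises(SubgroupError, match="perplexity"):
            embed_cells(pd.DataFrame(np.eye(10)), perplexity=10)

    def test_two_blobs_fully_recovered_across_seeds(self):
        """20 + 20 cells, 10-SD separation: 2-clustering of the embedding
        matches the truth (ARI = 1) for >= 95% of seeds."""
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (20, 10)),
                       rng.normal(10, 1, (20, 10))])
        truth = np.repeat([0, 1], 20)
        hits = 0
        seeds = range(20)
        for seed in seeds:
            emb = embed_cells(pd.DataFrame(X), seed=seed, perplexity=6,
                              pca_components=None)
            labels = cluster_cells(emb, 2).labels
            hits += adjusted_rand_score(truth, labels) == 1.0
        assert hits >= 0.95 * len(seeds)


class TestCrossCheck:
    def test_identical_assignments_ari_one(self):
        a = pd.Series([1, 1, 2, 2, 3, 3])
        assert adjusted_rand_score(a, a) == 1.0

    def test_random_labelings_ari_near_zero(self):
        rng = np.random.default_rng(10)
        vals = [adjusted_rand_score(rng.integers(0, 3, 120),
                                    rng.integers(0, 3, 120))
                for _ in range(100)]
        assert np.abs(np.mean(vals)) < 0.02
        assert np.max(np.abs(vals)) < 0.1

    def test_tsne_umap_assignments_concordant(self, subgroup_dataset):
        *_, scaled, truth = subgroup_dataset
        out = cross_check_embeddings(scaled, k=3)
        assert out["min_cross_method_ari"] >= 0.8
        ari = out["ari_matrix"]
        assert np.allclose(ari, ari.T) and np.allclose(np.diag(ari), 1.0)


class TestPatientCounts:
    def test_counts_example(self):
        labels = pd.Series([1, 1, 2], index=["c1", "c2", "c3"], name="subgroup")
        from ctcmet.subgroups import SubgroupAssignment
        asg = SubgroupAssignment(labels, k=3)
        mapping = pd.Series(["p1"] * 3, index=labels.index)
        counts = count_subgroups_per_patient(asg, mapping)
        assert counts.loc["p1"].tolist() == [2, 1, 0]

    def test_row_sums_conserved(self, subgroup_dataset):
        *_, scaled, truth = subgroup_dataset
        emb = embed_cells(scaled)
        asg = cluster_cells(emb, 3)
        rng = np.random.default_rng(0)
        mapping = pd.Series(rng.choice(["p1", "p2", "p3"], len(asg.labels)),
                            index=asg.labels.index)
        counts = count_subgroups_per_patient(asg, mapping)
        totals = mapping.value_counts()
        assert counts.sum(axis=1).sort_index().equals(
            totals.sort_index().rename(None))

    def test_truth_labels_reproduce_generator_draws(self):
        """Using the generator's own labels, per-patient counts equal the
        multinomial draws exactly."""
        from ctcmet import SimCohortConfig, simulate_patient_cohort, \
            three_subgroup_config
        from ctcmet.subgroups import SubgroupAssignment
        cfg = three_subgroup_config(n_metabolites=5, n_signature=1)
        _, _, truth = simulate_patient_cohort(SimCohortConfig(), cfg, seed=4)
        labels = truth.cell_labels.map({"1": 1, "2": 2, "3": 3}).rename("subgroup")
        counts = count_subgroups_per_patient(
            SubgroupAssignment(labels, k=3), truth.cell_to_patient)
        for pid, grp in truth.cell_labels.groupby(truth.cell_to_patient):
            for sg in ("1", "2", "3"):
                assert counts.loc[pid, f"CTC{sg}"] == (grp == sg).sum()

    def test_unmapped_cell_rejected(self):
        from ctcmet.subgroups import SubgroupAssignment
        labels = pd.Series([1, 2], index=["c1", "c2"], name="subgroup")
        mapping = pd.Series(["p1"], index=["c1"])
        with pytest.raises(SubgroupError, match="c2"):
            count_subgroups_per_patient(SubgroupAssignment(labels, 2), mapping)
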