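import numpy as np
import pandas as pd
import pytest

import gliostate as gs
from gliostate.errors import ClusteringError, InvalidParameterError


def frame(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{i}" for i in range(values.shape[1])],
    )


class TestFitPCA:
    def test_rank_one_data_loads_on_first_component(self):
        data = frame([[0, 1, 2, 3], [5, 5, 5, 5], [2, 2, 2, 2]])
        pca = gs.fit_pca(data, 2)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)
        assert abs(pca.loadings.loc["g0", "PC1"]) == pytest.approx(1.0)

    def test_duplicated_sample_gets_identical_scores(self, rng):
        X = rng.normal(size=(20, 5))
        X = np.hstack([X, X[:, [0]]])  # s5 duplicates s0
        pca = gs.fit_pca(frame(X), 3)
        assert np.allclose(pca.scores.loc["s0"], pca.scores.loc["s5"])

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(10, 6))
        data = frame(X)
        pca = gs.fit_pca(data, 5)  # n_samples - 1 components: exact
        centered = X.T - X.T.mean(axis=0)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-8)

    def test_unit_norm_loadings_and_monotone_variance(self, small_norm):
        pca = gs.fit_pca(small_norm, 4)
        norms = np.linalg.norm(pca.loadings.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0)
        evr = pca.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-12

    def test_component_count_validated(self, small_norm):
        with pytest.raises(InvalidParameterError):
            gs.fit_pca(small_norm, 100)


class TestDriverGenes:
    def _pca_from_loadings(self, loadings):
        load = pd.DataFrame({"PC1": loadings})
        load.index = [f"g{i}" for i in range(len(loadings))]
        load /= np.linalg.norm(load.to_numpy())
        return gs.PCAResult(
            loadings=load,
            scores=pd.DataFrame({"PC1": [0.0, 0.0]}, index=["a", "b"]),
            explained_variance_ratio=np.array([1.0]),
        )

    def test_equal_magnitudes_select_nothing(self):
        pca = self._pca_from_loadings([0.5, -0.5, 0.5, -0.5])
        assert gs.select_driver_genes(pca, 0).genes == []

    def test_dominant_loading_ranks_first(self, rng):
        loadings = np.concatenate([[10.0], rng.normal(0, 0.1, 99)])
        pca = self._pca_from_loadings(loadings)
        drivers = gs.select_driver_genes(pca, 0, tail_fraction=0.05)
        assert drivers.genes[0] == "g0"
        assert len(drivers.genes) <= 5  # at most 5% of 100 genes

    def test_sign_flip_invariant(self, rng):
        loadings = rng.normal(size=50)
        up = self._pca_from_loadings(loadings)
        down = self._pca_from_loadings(-loadings)
        assert gs.select_driver_genes(up, 0).genes == gs.select_driver_genes(down, 0).genes

    def test_literal_mode_selects_most_genes(self, rng):
        pca = self._pca_from_loadings(rng.normal(size=100))
        literal = gs.select_driver_genes(pca, 0, mode="literal")
        assert len(literal.genes) >= 90

    def test_component_out_of_range(self, rng):
        pca = self._pca_from_loadings(rng.normal(size=10))
        with pytest.raises(InvalidParameterError):
            gs.select_driver_genes(pca, 3)


class TestKMeansStates:
    def test_single_cluster_inertia_is_total_ss(self, rng):
        scores = pd.DataFrame(rng.normal(size=(8, 2)), columns=["PC1", "PC2"])
        labels, inertia = gs.kmeans_states(scores, k=1, seed=0)
        assert labels.nunique() == 1
        centered = scores - scores.mean()
        assert inertia == pytest.approx(float((centered**2).sum().sum()))

    def test_separated_blobs_recovered(self, rng):
        blobs = np.vstack(
            [rng.normal(loc, 0.1, size=(10, 2)) for loc in ([0, 0], [20, 0], [0, 20])]
        )
        scores = pd.DataFrame(blobs, columns=["PC1", "PC2"])
        labels, _ = gs.kmeans_states(scores, k=3, seed=1)
        groups = [set(labels.iloc[i * 10 : (i + 1) * 10]) for i in range(3)]
        assert all(len(g) == 1 for g in groups)
        assert len(set.union(*groups)) == 3

    def test_seeded_determinism(self, rng):
        scores = pd.DataFrame(rng.normal(size=(12, 3)))
        a, _ = gs.kmeans_states(scores, k=3, seed=5)
        b, _ = gs.kmeans_states(scores, k=3, seed=5)
        assert a.equals(b)

    def test_k_exceeding_samples_rejected(self, rng):
        scores = pd.DataFrame(rng.normal(size=(4, 2)))
        with pytest.raises(InvalidParameterError):
            gs.kmeans_states(scores, k=5, seed=0)


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero_height(self):
        data = frame([[1, 2, 3], [1, 2, 3], [9, 9, 9]])
        tree = gs.hierarchical_cluster(data)
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_manhattan_metric_drives_first_merge(self):
        # |(0,0)-(0,1)| = 1 beats |(0,0)-(1,1)| = 2 and any pair with (10,10)
        data = frame([[0, 0], [0, 1], [10, 10]])
        tree = gs.hierarchical_cluster(data)
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_ward_heights_nondecreasing(self, rng):
        data = frame(rng.normal(size=(15, 6)))
        tree = gs.hierarchical_cluster(data)
        heights = tree.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_missing_values_rejected(self):
        data = frame([[1, np.nan], [2, 3]])
        with pytest.raises(ClusteringError):
            gs.hierarchical_cluster(data)

    def test_column_axis_clusters_samples(self, small_norm):
        tree = gs.hierarchical_cluster(small_norm.values, axis="columns")
        assert sorted(tree.leaf_order) == sorted(small_norm.values.columns)


class TestStateTrajectoryRecovery:
    def test_chronic_block_drives_separating_component(self, small_sim):
        _, counts, truth = small_sim
        norm = gs.housekeeping_normalize(counts, truth.housekeeping_genes)
        pca = gs.fit_pca(norm, 3)
        div = norm.metadata["div"]
        sep = [
            abs(
                pca.scores.loc[(div >= 6).to_numpy(), c].mean()
                - pca.scores.loc[(div == 0).to_numpy(), c].mean()
            )
            for c in pca.scores
        ]
        comp = int(np.argmax(sep))
        drivers = gs.select_driver_genes(pca, comp)
        chronic = set(truth.block_genes("dam")) | set(truth.block_genes("homeostatic"))
        hits = len(chronic & set(drivers.genes))
        assert hits / len(drivers.genes) >= 0.8
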