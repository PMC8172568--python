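import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from screversal.cluster import (
    ClusterLabels,
    assign_cell_types,
    build_snn,
    cluster_modularity,
    modularity,
    pca_embed,
)
from screversal.io import GeneSetCollection
from screversal.preprocess import NormMatrix, filter_genes, lognormalize, select_hvg
from screversal.simulate import SimulationConfig, simulate_dataset


def _norm(values, genes=None):
    values = np.asarray(values, dtype=float)
    return NormMatrix(
        values=values,
        gene_ids=np.array(genes or [f"g{i}" for i in range(values.shape[0])], dtype=object),
        barcodes=np.array([f"c{j}" for j in range(values.shape[1])], dtype=object),
    )


class TestPCA:
    def test_collinear_cells_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 30)
        V = np.vstack([2 * t, -t, 3 * t])  # all genes proportional to t
        emb = pca_embed(_norm(V), [f"g{i}" for i in range(3)], n_pcs=2)
        total = emb.explained_variance.sum()
        assert emb.explained_variance[0] / total == pytest.approx(1.0, abs=1e-10)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(0)
        V = rng.normal(size=(50, 200))
        genes = [f"g{i}" for i in range(50)]
        emb = pca_embed(_norm(V), genes, n_pcs=10)
        # oracle: dense eigendecomposition of the standardized covariance
        X = V.T
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        Z = Z - Z.mean(0)
        C = Z.T @ Z / (Z.shape[0] - 1)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(emb.explained_variance, evals[:10], atol=1e-8)
        # coordinates reproduce the projection up to the fixed sign rule
        np.testing.assert_allclose(
            np.var(emb.coords, axis=0, ddof=1), evals[:10], atol=1e-8
        )

    def test_permuting_cells_permutes_embedding(self):
        rng = np.random.default_rng(1)
        V = rng.normal(size=(20, 60))
        genes = [f"g{i}" for i in range(20)]
        emb = pca_embed(_norm(V), genes, n_pcs=5)
        perm = rng.permutation(60)
        emb_p = pca_embed(_norm(V[:, perm]), genes, n_pcs=5)
        np.testing.assert_allclose(emb_p.coords, emb.coords[perm], atol=1e-8)

    def test_constant_input_is_error(self):
        V = np.ones((5, 20))
        with pytest.raises(ValueError):
            pca_embed(_norm(V), [f"g{i}" for i in range(5)], n_pcs=2)

    def test_too_many_pcs_is_error(self):
        rng = np.random.default_rng(2)
        V = rng.normal(size=(5, 20))
        with pytest.raises(ValueError):
            pca_embed(_norm(V), [f"g{i}" for i in range(5)], n_pcs=5)


class TestSNN:
    def test_two_far_groups_disconnect(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3)) + 100.0
        from screversal.cluster import Embedding

        emb = Embedding(coords=np.vstack([a, b]), explained_variance=np.array([1.0, 0.5, 0.2]))
        W = build_snn(emb, k=5)
        cross = W[:20, 20:]
        assert cross.nnz == 0

    def test_identical_neighbor_sets_have_weight_one(self):
        # two coincident points among a far-away cloud share all neighbors
        rng = np.random.default_rng(4)
        pts = np.vstack([[0, 0], [0, 0], rng.normal(size=(30, 2)) + 50])
        from screversal.cluster import Embedding

        emb = Embedding(coords=pts, explained_variance=np.array([1.0, 0.5]))
        W = build_snn(emb, k=5)
        assert W[0, 1] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        from screversal.cluster import Embedding

        emb = Embedding(coords=rng.normal(size=(50, 4)), explained_variance=np.arange(4, 0, -1.0))
        W = build_snn(emb, k=8)
        assert (W != W.T).nnz == 0

    def test_k_validation(self):
        from screversal.cluster import Embedding

        emb = Embedding(coords=np.zeros((5, 2)), explained_variance=np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            build_snn(emb, k=0)
        with pytest.raises(ValueError):
            build_snn(emb, k=5)


class TestModularityClustering:
    def _two_cliques(self, n=12):
        A = np.zeros((2 * n, 2 * n))
        A[:n, :n] = 1.0
        A[n:, n:] = 1.0
        np.fill_diagonal(A, 0.0)
        return sp.csr_matrix(A)

    @pytest.mark.parametrize("resolution", [0.5, 1.0, 1.4])
    def test_two_cliques_two_clusters(self, resolution):
        labels = cluster_modularity(self._two_cliques(), resolution=resolution, seed=0)
        assert labels.n_clusters == 2
        assert len(set(labels.labels[:12])) == 1
        assert len(set(labels.labels[12:])) == 1

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(7)
        A = sp.random(80, 80, density=0.1, random_state=7)
        A = ((A + A.T) > 0).astype(float).tocsr()
        l1 = cluster_modularity(A, seed=5)
        l2 = cluster_modularity(A, seed=5)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_edgeless_graph_gives_singletons(self, caplog):
        W = sp.csr_matrix((6, 6))
        labels = cluster_modularity(W, seed=0)
        assert labels.n_clusters == 6

    def test_beats_singleton_modularity(self):
        W = self._two_cliques()
        labels = cluster_modularity(W, resolution=1.0, seed=0)
        q = modularity(W, labels.labels, resolution=1.0)
        q_singletons = modularity(W, np.arange(W.shape[0]), resolution=1.0)
        assert q >= q_singletons

    def test_recovers_simulated_cell_types(self):
        cfg = SimulationConfig(
            n_genes=800,
            n_cell_types=4,
            cells_per_sample_per_type=40,
            marker_genes_per_type=25,
            marker_boost_ln=float(np.log(5)),
            f_de=0.0,
            signature_shift_ln=0.0,
            seed=23,
        )
        m, meta, _ = simulate_dataset(cfg)
        m = m.subset(gene_mask=filter_genes(m, 5))
        norm = lognormalize(m)
        hvg = select_hvg(m, n_hvg=300)
        emb = pca_embed(norm, hvg, n_pcs=20)
        W = build_snn(emb, k=20)
        labels = cluster_modularity(W, resolution=1.4, seed=0)
        ari = adjusted_rand_score(meta["cell_type"], labels.labels)
        assert ari >= 0.8


class TestAssignCellTypes:
    def _setup(self):
        # 3 clusters x 4 cells; marker sets A (g0,g1) and B (g2,g3)
        V = np.zeros((5, 12))
        V[0:2, 0:4] = 5.0   # cluster 0: set A high
        V[2:4, 4:8] = 5.0   # cluster 1: set B high
        V[0:4, 8:12] = 5.0  # cluster 2: both high -> excluded
        norm = _norm(V)
        labels = ClusterLabels(labels=np.repeat([0, 1, 2], 4), resolution=1.0)
        sets = GeneSetCollection(
            sets={"A": ("", ["g0", "g1"]), "B": ("", ["g2", "g3"])}
        )
        return norm, labels, sets

    def test_assignment_and_mixed_exclusion(self):
        norm, labels, sets = self._setup()
        assignment, excluded, _ = assign_cell_types(norm, labels, sets)
        assert assignment == {0: "A", 1: "B"}
        assert 2 in excluded and "multiple" in excluded[2]

    def test_no_signal_cluster_excluded(self):
        V = np.zeros((5, 8))
        V[0:2, 0:4] = 5.0
        norm = _norm(V)
        labels = ClusterLabels(labels=np.repeat([0, 1], 4), resolution=1.0)
        sets = GeneSetCollection(sets={"A": ("", ["g0", "g1"])})
        assignment, excluded, _ = assign_cell_types(norm, labels, sets)
        assert assignment == {0: "A"}
        assert excluded[1] == "no marker signal"

    def test_overlapping_marker_sets_rejected(self):
        norm, labels, _ = self._setup()
        sets = GeneSetCollection(sets={"A": ("", ["g0"]), "B": ("", ["g0", "g1"])})
        with pytest.raises(ValueError):
            assign_cell_types(norm, labels, sets)

    def test_absent_marker_set_is_error(self):
        norm, labels, _ = self._setup()
        sets = GeneSetCollection(sets={"A": ("", ["nope1", "nope2"])})
        with pytest.raises(ValueError):
            assign_cell_types(norm, labels, sets)

    def test_end_to_end_type_recovery_on_simulation(self):
        cfg = SimulationConfig(
            n_genes=800,
            n_cell_types=3,
            cells_per_sample_per_type=40,
            marker_genes_per_type=25,
            f_de=0.0,
            signature_shift_ln=0.0,
            seed=29,
        )
        m, meta, truth = simulate_dataset(cfg)
        m = m.subset(gene_mask=filter_genes(m, 5))
        norm = lognormalize(m)
        hvg = select_hvg(m, n_hvg=300)
        emb = pca_embed(norm, hvg, n_pcs=20)
        labels = cluster_modularity(build_snn(emb, k=20), resolution=1.4, seed=0)
        sets = {}
        for k, ct in enumerate(truth.cell_types):
            genes = [str(g) for g in truth.gene_ids[truth.is_marker[:, k]] if g in set(m.gene_ids)]
            sets[ct] = ("", genes)
        assignment, excluded, _ = assign_cell_types(
            norm, labels, GeneSetCollection(sets=sets)
        )
        assigned = np.array([assignment.get(int(c), "") for c in labels.labels])
        match = (assigned == meta["cell_type"].to_numpy()).mean()
        assert match >= 0.9
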