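"""Normalization, HVG selection, PCA, SNN clustering, marker genes."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from symcell.embed import (ClusterConfig, NormalizedMatrix, cluster_workflow,
                           find_markers, lognormalize,
                           merge_state_split_clusters, pca, scale_clip,
                           select_hvg, snn_cluster)
from symcell.io import CountMatrix

from conftest import SMALL_CLUSTERING


def _matrix(dense):
    dense = np.asarray(dense)
    return CountMatrix(
        sp.csr_matrix(dense),
        np.array([f"BC{i}" for i in range(dense.shape[0])], dtype=object),
        np.array([f"g{j}" for j in range(dense.shape[1])], dtype=object),
        np.array(["host"] * dense.shape[1], dtype=object),
    )


def _norm(values, gene_prefix="g"):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values,
        np.array([f"BC{i}" for i in range(values.shape[0])], dtype=object),
        np.array([f"{gene_prefix}{j}" for j in range(values.shape[1])],
                 dtype=object),
    )


def test_lognormalize_formula():
    m = _matrix([[1, 9], [0, 5]])
    norm = lognormalize(m, scale=1e4)
    assert norm.values[0, 0] == pytest.approx(np.log(1001), abs=1e-10)
    assert norm.values[1, 0] == 0.0


def test_lognormalize_depth_invariance():
    a = lognormalize(_matrix([[2, 4, 6]]))
    b = lognormalize(_matrix([[4, 8, 12]]))
    assert np.allclose(a.values, b.values)


def test_hvg_excludes_constant_genes():
    values = np.ones((10, 4))
    values[:, 1] = np.arange(10)  # the only variable gene
    top = select_hvg(_norm(values), 1)
    assert list(top) == ["g1"]


def test_hvg_all_genes_when_requested():
    values = np.random.default_rng(0).normal(size=(20, 6))
    assert set(select_hvg(_norm(values), 6)) == {f"g{j}" for j in range(6)}
    with pytest.raises(ValueError):
        select_hvg(_norm(values), 7)


def test_hvg_catches_planted_markers(clustered, small_dataset):
    _, norm, _, _, _ = clustered
    hvg = set(select_hvg(norm, 300))
    truth = small_dataset.truth.genes
    markers = truth.index[truth["marker_cluster"] > 0]
    present = [g for g in markers if g in set(norm.gene_ids)]
    assert np.mean([g in hvg for g in present]) > 0.9


def test_scale_clip_population_zscore():
    scaled = scale_clip(_norm([[0.0], [2.0]]))
    assert scaled.values[:, 0] == pytest.approx([-1.0, 1.0])


def test_scale_clip_constant_gene_zero():
    scaled = scale_clip(_norm([[3.0], [3.0], [3.0]]))
    assert (scaled.values == 0).all()


def test_scale_clip_truncates():
    values = np.zeros((300, 1))
    values[0, 0] = 1e6  # z-score ~ sqrt(299) ~ 17.3 before clipping
    scaled = scale_clip(_norm(values), clip=10.0)
    assert scaled.values.max() == pytest.approx(10.0)
    assert scaled.values.min() >= -10.0


def test_pca_rank_one_line():
    rng = np.random.default_rng(0)
    t = rng.normal(size=40)
    values = np.column_stack([t, 2 * t])  # exactly on a line
    emb = pca(_norm(values), 1)
    assert emb.variance_explained[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_orthonormal_loadings(clustered):
    _, _, emb, _, _ = clustered
    gram = emb.loadings.T @ emb.loadings
    assert np.abs(gram - np.eye(emb.n_dims)).max() < 1e-8
    assert (np.diff(emb.variance_explained) <= 1e-12).all()


def test_pca_sign_convention(clustered):
    _, _, emb, _, _ = clustered
    peak = np.abs(emb.loadings).argmax(axis=0)
    assert (emb.loadings[peak, np.arange(emb.n_dims)] > 0).all()


def test_pca_exceeding_rank_reports_achievable():
    values = np.zeros((10, 5))
    values[:, 0] = np.arange(10)  # rank 1 after scaling
    with pytest.raises(ValueError, match="rank"):
        pca(scale_clip(_norm(values)), 4)
    with pytest.raises(ValueError, match="n_dims"):
        pca(_norm(np.ones((3, 3))), 7)


def test_pca_reconstruction_error_monotone():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(40, 20))
    scaled = scale_clip(_norm(x))
    errors = []
    for k in (2, 5, 10):
        emb = pca(scaled, k)
        recon = emb.scores @ emb.loadings.T
        errors.append(np.linalg.norm(scaled.values - recon))
    assert errors[0] >= errors[1] >= errors[2]


def _blob_embedding(seed=0, n=120, sep=10.0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([
        rng.normal(0, 1, (n // 2, 5)),
        rng.normal(sep, 1, (n - n // 2, 5)),
    ])
    scaled = _norm(pts)
    return pca(scaled, 3), np.array([0] * (n // 2) + [1] * (n - n // 2))


def test_two_blobs_two_clusters():
    emb, blob = _blob_embedding()
    labels = snn_cluster(emb, ClusterConfig(n_dims=3, resolution=0.2,
                                            n_neighbors=15), seed=0)
    assert len(np.unique(labels)) == 2
    assert adjusted_rand_score(blob, labels) == 1.0


def test_snn_deterministic():
    emb, _ = _blob_embedding()
    cfg = ClusterConfig(n_dims=3, resolution=0.5, n_neighbors=10)
    a = snn_cluster(emb, cfg, seed=4)
    b = snn_cluster(emb, cfg, seed=4)
    assert np.array_equal(a, b)


def test_snn_rejects_too_many_neighbors():
    emb, _ = _blob_embedding(n=20)
    with pytest.raises(ValueError, match="n_neighbors"):
        snn_cluster(emb, ClusterConfig(n_neighbors=25), seed=0)


def test_fixture_clusters_match_truth(clustered):
    _, _, _, labels, truth = clustered
    ari = adjusted_rand_score(truth["cluster"].to_numpy(), labels)
    assert ari >= 0.9


def test_permutation_equivariance(prepared):
    """Permuting the input cells permutes labels identically (well-separated
    data; community detection is run on an isomorphic graph)."""
    m, _ = prepared
    host = m.host_view()
    rng = np.random.default_rng(0)
    perm = rng.permutation(host.n_cells)
    _, _, labels = cluster_workflow(host, SMALL_CLUSTERING, seed=5)
    _, _, labels_perm = cluster_workflow(host.subset_cells(perm),
                                         SMALL_CLUSTERING, seed=5)
    assert adjusted_rand_score(labels[perm], labels_perm) == 1.0


def _synthetic_embedding(points):
    from symcell.validation import _scores_embedding

    return _scores_embedding(np.asarray(points, dtype=float))


def test_state_split_fragments_are_merged():
    """Two nearby clusters that are oppositely state-pure collapse into
    one; a state-pure cluster without a complementary partner survives."""
    rng = np.random.default_rng(0)
    # cluster 1: balanced pair far away; clusters 2+3: split fragments
    # close together; cluster 4: sym-only, isolated (hosting-like)
    pts = np.vstack([
        rng.normal([0, 0], 0.1, (40, 2)),
        rng.normal([10, 0], 0.1, (20, 2)),
        rng.normal([10.5, 0], 0.1, (20, 2)),
        rng.normal([0, 10], 0.1, (12, 2)),
    ])
    labels = np.array([1] * 40 + [2] * 20 + [3] * 20 + [4] * 12)
    states = np.array(["s"] * 20 + ["a"] * 20        # balanced
                      + ["s"] * 20 + ["a"] * 20      # split pair
                      + ["s"] * 12)                  # hosting-like
    emb = _synthetic_embedding(pts)
    merged = merge_state_split_clusters(emb, labels, states)
    # fragments 2 and 3 now share a label; clusters 1 and 4 intact
    assert len(np.unique(merged)) == 3
    assert len(np.unique(merged[40:80])) == 1
    assert len(np.unique(merged[:40])) == 1
    assert len(np.unique(merged[80:])) == 1
    assert np.unique(merged[80:])[0] != np.unique(merged[40:80])[0]


def test_balanced_labels_unchanged_by_merge():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(30, 2))
    labels = np.array([1] * 15 + [2] * 15)
    states = np.array(["s", "a"] * 15)  # both clusters ~balanced
    emb = _synthetic_embedding(pts)
    assert np.array_equal(merge_state_split_clusters(emb, labels, states),
                          labels)


def test_find_markers_exclusive_gene():
    rng = np.random.default_rng(1)
    n = 60
    values = rng.normal(1.0, 0.05, size=(n, 10)).clip(min=0)
    labels = np.array([1] * (n // 2) + [2] * (n // 2))
    values[labels == 2, 0] = 0.0  # g0 expressed only in cluster 1
    res = find_markers(_norm(values), labels, lfc_threshold=0.2)
    top = res[1].iloc[0]
    assert top["gene_id"] == "g0" and top["padj"] < 0.05
    assert "g0" not in set(res[2].loc[res[2]["log2fc"] > 0, "gene_id"])


def test_find_markers_flat_gene_absent():
    rng = np.random.default_rng(2)
    values = rng.normal(1.0, 0.05, size=(40, 5)).clip(min=0)
    labels = np.array([1, 2] * 20)
    res = find_markers(_norm(values), labels, lfc_threshold=0.5)
    for df in res.values():
        assert df.empty  # no gene reaches the fold-change threshold


def test_planted_cluster_markers_recovered(clustered, small_dataset):
    _, norm, _, _, truth_cells = clustered
    res = find_markers(norm, truth_cells["cluster"].to_numpy())
    truth_genes = small_dataset.truth.genes
    for c, df in res.items():
        planted = set(truth_genes.index[truth_genes["marker_cluster"] == c])
        planted &= set(norm.gene_ids)
        found = set(df.loc[(df["padj"] < 0.05) & (df["log2fc"] > 0),
                           "gene_id"])
        assert len(planted & found) / len(planted) >= 0.9


def test_marker_pvalues_uniform_under_permutation(prepared):
    """With labels shuffled, Wilcoxon marker p-values are ~Uniform(0,1)."""
    m, truth = prepared
    norm = lognormalize(m.host_view())
    rng = np.random.default_rng(7)
    labels = rng.permutation(truth["cluster"].to_numpy())
    res = find_markers(norm, labels, lfc_threshold=0.0)
    pvals = np.concatenate([df["p"].to_numpy() for df in res.values()])
    ks = scipy.stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
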