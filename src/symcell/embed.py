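"""Normalization, variable-gene selection, PCA, and SNN-graph clustering.

The workflow is the standard droplet scRNA-seq embedding: depth-normalize
and log-transform counts, pick highly variable genes by standardized
variance, z-score and clip each gene, run a truncated SVD (PCA), build a
k-nearest-neighbor graph on the leading components, reweight edges by
shared-neighbor (Jaccard) overlap, and find communities with the Leiden
algorithm at a given resolution. Cross-sample integration is a joint PCA
on the merged matrix: every downstream inference re-runs PCA on
per-cluster subsets, so no anchor-based correction is layered on top (the
integration stage is pluggable by replacing this embedding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors

from ._utils import bh_adjust, logger
from .io import CountMatrix


@dataclass
class NormalizedMatrix:
    """Dense cells x genes matrix of normalized (or scaled) expression."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def subset_genes(self, gene_ids) -> "NormalizedMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes not present: {missing[:5]}")
        return NormalizedMatrix(self.values[:, idx], self.cell_ids,
                                np.asarray(gene_ids, dtype=object))


@dataclass
class Embedding:
    """PCA scores, loadings, and variance explained.

    ``scores`` is cells x PCs, ``loadings`` genes x PCs with orthonormal
    columns; ``variance_explained`` is the fraction of total variance per
    component, non-increasing. Component signs are fixed so that each
    loading column's largest-magnitude entry is positive.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    n_dims: int
    cell_ids: np.ndarray
    gene_ids: np.ndarray


@dataclass(frozen=True)
class ClusterConfig:
    """Embedding/clustering parameters.

    Defaults follow common full-dataset settings (30 dimensions, Leiden
    resolution 0.55, 2,000 variable genes, clip at 10); per-cluster
    reclustering typically uses 20-30 dimensions and resolutions between
    0.25 and 0.5.
    """

    n_dims: int = 30
    resolution: float = 0.55
    n_neighbors: int = 20
    hvg_n: int = 2000
    scale_clip: float = 10.0
    snn_prune: float = 1.0 / 15.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_dims <= 0 or self.n_neighbors <= 0 or self.hvg_n <= 0:
            raise ValueError("n_dims, n_neighbors, hvg_n must be positive")


def lognormalize(m: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Depth-normalized log expression: ``ln(1 + count * scale / total)``."""
    totals = m.cell_totals().astype(float)
    if (totals == 0).any():
        bad = m.cell_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts")
    dense = np.asarray(m.counts.todense(), dtype=float)
    values = np.log1p(dense * (scale / totals)[:, None])
    return NormalizedMatrix(values, m.cell_ids, m.gene_ids)


def select_hvg(normalized: NormalizedMatrix, hvg_n: int) -> np.ndarray:
    """Top ``hvg_n`` genes by standardized variance.

    The per-gene variance of normalized values is divided by a quadratic
    mean-variance trend fitted in log-log space; ordering is deterministic
    with an ascending gene-id tiebreak. Constant genes rank last, after
    every non-constant gene.
    """
    x = normalized.values
    n_genes = x.shape[1]
    if hvg_n > n_genes:
        raise ValueError(f"hvg_n={hvg_n} exceeds {n_genes} genes")
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    std_var = np.zeros(n_genes)
    nonconst = var > 0
    fit = nonconst & (mean > 0)
    if fit.sum() >= 3:
        lm = np.log10(mean[fit])
        lv = np.log10(var[fit])
        coef = np.polyfit(lm, lv, deg=2)
        trend = 10.0 ** np.polyval(coef, lm)
        std_var[fit] = var[fit] / trend
        std_var[nonconst & ~fit] = var[nonconst & ~fit]
    else:
        std_var[nonconst] = var[nonconst]
    order = pd.DataFrame(
        {"sv": std_var, "gene": normalized.gene_ids}
    ).sort_values(["sv", "gene"], ascending=[False, True], kind="mergesort")
    return order["gene"].to_numpy(dtype=object)[:hvg_n]


def scale_clip(normalized: NormalizedMatrix, clip: float = 10.0
               ) -> NormalizedMatrix:
    """Per-gene z-score (population sd) truncated to ``[-clip, +clip]``.

    Zero-variance genes scale to all zeros rather than NaN.
    """
    x = normalized.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population (ddof=0) convention
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / sd_safe
    z[:, sd == 0] = 0.0
    np.clip(z, -clip, clip, out=z)
    return NormalizedMatrix(z, normalized.cell_ids, normalized.gene_ids)


def pca(scaled: NormalizedMatrix, n_dims: int) -> Embedding:
    """Truncated SVD of the scaled matrix.

    Uses ARPACK with a fixed start vector for determinism; falls back to a
    full SVD when the requested dimension does not leave ARPACK room.
    Raises when ``n_dims`` exceeds the numerical rank, reporting the
    achievable rank.
    """
    x = scaled.values
    n, p = x.shape
    if n_dims > min(n, p):
        raise ValueError(
            f"n_dims={n_dims} exceeds min(cells, genes)={min(n, p)}"
        )
    if n_dims < min(n, p) - 1 and min(n, p) > 20:
        v0 = np.random.default_rng(0).standard_normal(min(n, p))
        u, s, vt = svds(x, k=n_dims, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
        total_var = float(np.sum(x * x))
    else:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        total_var = float(np.sum(s * s))
        u, s, vt = u[:, :n_dims], s[:n_dims], vt[:n_dims]
    tol = (s.max() if s.size else 0.0) * max(n, p) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < n_dims:
        raise ValueError(
            f"n_dims={n_dims} exceeds the numerical rank; achievable rank "
            f"within the requested components is {rank}"
        )
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u = u * flip
    vt = vt * flip[:, None]
    variance_explained = (s * s) / total_var if total_var > 0 else s * 0
    return Embedding(
        scores=u * s,
        loadings=vt.T,
        variance_explained=variance_explained,
        n_dims=n_dims,
        cell_ids=scaled.cell_ids,
        gene_ids=scaled.gene_ids,
    )


def _snn_graph(scores: np.ndarray, n_neighbors: int, prune: float) -> igraph.Graph:
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(scores)
    # querying the fitted points themselves puts each cell in its own
    # neighborhood (distance 0), the standard SNN convention
    knn = nn.kneighbors_graph(scores, mode="connectivity")
    knn = knn + sp.identity(n, format="csr")
    knn.data = np.ones_like(knn.data)
    shared = knn @ knn.T
    shared = sp.triu(shared, k=1).tocoo()
    k = n_neighbors
    jaccard = shared.data / (2.0 * k - shared.data)
    keep = jaccard > prune
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def snn_cluster(embedding: Embedding, cfg: ClusterConfig, seed: int = 0
                ) -> np.ndarray:
    """Leiden communities on the shared-nearest-neighbor graph.

    Returns 1-based integer labels ordered by decreasing cluster size
    (ties toward the earlier community). Identical embedding and seed give
    identical labels.
    """
    n = embedding.scores.shape[0]
    if cfg.n_neighbors >= n:
        raise ValueError(f"n_neighbors={cfg.n_neighbors} >= {n} cells")
    scores = embedding.scores[:, : min(cfg.n_dims, embedding.n_dims)]
    g = _snn_graph(scores, cfg.n_neighbors, cfg.snn_prune)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=cfg.resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)


def merge_state_split_clusters(embedding: Embedding, labels, states,
                               min_imbalance: float = 0.9) -> np.ndarray:
    """Reunite cluster fragments that split along the sample/state axis.

    A joint PCA of two samples can split one cell population into two
    near-pure per-state clusters when a state effect is strong. This step
    merges a pair of clusters when (a) each is dominated (>
    ``min_imbalance``) by one state, (b) the dominant states are opposite,
    and (c) the two are mutually nearest by PCA centroid distance. The
    rule is conservative: a genuinely state-specific population (e.g. an
    algal-hosting cluster present only in the symbiotic sample) has no
    opposite-state mutual-nearest partner and is left alone. Labels are
    renumbered by decreasing size afterwards.
    """
    labels = np.asarray(labels).copy()
    states = np.asarray(states)
    uniq_states = np.unique(states)
    if len(uniq_states) != 2:
        return labels
    uniq = np.unique(labels)
    centroids = np.vstack([embedding.scores[labels == c].mean(axis=0)
                           for c in uniq])
    frac0 = np.array([
        float((states[labels == c] == uniq_states[0]).mean()) for c in uniq
    ])
    dominant = np.where(frac0 >= min_imbalance, 0,
                        np.where(1 - frac0 >= min_imbalance, 1, -1))
    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    np.fill_diagonal(dist, np.inf)
    nearest = dist.argmin(axis=1)
    merged = {}
    for i in range(len(uniq)):
        j = nearest[i]
        if (dominant[i] >= 0 and dominant[j] >= 0
                and dominant[i] != dominant[j] and nearest[j] == i
                and i < j):
            merged[uniq[j]] = uniq[i]
    if merged:
        labels = np.array([merged.get(c, c) for c in labels])
        sizes = pd.Series(labels).value_counts()
        order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
        remap = {old: new + 1 for new, old in enumerate(order)}
        labels = np.array([remap[c] for c in labels], dtype=int)
    return labels


def cluster_workflow(m: CountMatrix, cfg: ClusterConfig, seed: int = 0
                     ) -> tuple[NormalizedMatrix, Embedding, np.ndarray]:
    """Normalize -> HVG -> scale -> PCA -> SNN Leiden, in one call.

    Returns the (full-gene) normalized matrix, the embedding on the HVG
    subset, and per-cell cluster labels.
    """
    norm = lognormalize(m)
    hvg = select_hvg(norm, min(cfg.hvg_n, m.n_genes))
    scaled = scale_clip(norm.subset_genes(hvg), cfg.scale_clip)
    n_dims = min(cfg.n_dims, scaled.values.shape[0] - 1,
                 scaled.values.shape[1] - 1)
    emb = pca(scaled, n_dims)
    labels = snn_cluster(emb, cfg, seed=seed)
    return norm, emb, labels


def find_markers(normalized: NormalizedMatrix, labels,
                 lfc_threshold: float = 0.5, min_cells: int = 3
                 ) -> dict[int, pd.DataFrame]:
    """Wilcoxon rank-sum cluster markers (each cluster vs the rest).

    Only genes whose |log2 fold change| of mean expression reaches
    ``lfc_threshold`` are tested; fold changes use the expm1-mean
    convention ``log2((mean(expm1 in) + 1) / (mean(expm1 out) + 1))``.
    P-values are BH-adjusted within each cluster. Clusters with fewer than
    ``min_cells`` cells are skipped with a warning.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters to find markers")
    x = normalized.values
    expm1 = np.expm1(x)
    results: dict[int, pd.DataFrame] = {}
    for c in uniq:
        mask = labels == c
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {c} has <{min_cells} cells; skipped")
            continue
        mean_in = expm1[mask].mean(axis=0)
        mean_out = expm1[~mask].mean(axis=0)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        tested = np.abs(lfc) >= lfc_threshold
        if not tested.any():
            results[int(c)] = pd.DataFrame(
                columns=["gene_id", "log2fc", "p", "padj"]
            )
            continue
        stat = scipy.stats.mannwhitneyu(
            x[mask][:, tested], x[~mask][:, tested], axis=0,
            alternative="two-sided", method="asymptotic",
        )
        df = pd.DataFrame(
            {
                "gene_id": normalized.gene_ids[tested],
                "log2fc": lfc[tested],
                "p": stat.pvalue,
                "padj": bh_adjust(stat.pvalue),
            }
        ).sort_values(["padj", "p", "gene_id"], kind="mergesort",
                      ignore_index=True)
        results[int(c)] = df
    logger.info(
        '{"event": "find_markers", "n_clusters": %d}' % len(results)
    )
    return results
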