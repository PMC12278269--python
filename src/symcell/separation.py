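"""Per-cluster symbiotic-state separation: the driver-gene procedure.

For one cell cluster: recluster its cells independently (fresh variable
genes, scaling, and PCA), test each of the leading principal components
for separation of symbiotic vs aposymbiotic cells with a one-way ANOVA,
pull the top positive- and negative-loading genes of each significant
component ("driver" genes), test differential expression between states
on the raw counts with a negative-binomial Wald test, and assemble a
report that tags each driver with its DE status, immune-GO membership,
and chaperone-COG membership, dropping genes without a Pfam domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import bh_adjust, logger
from .embed import (ClusterConfig, Embedding, NormalizedMatrix, lognormalize,
                    pca, scale_clip, select_hvg, snn_cluster)
from .io import CountMatrix
from .simulate import APO, COG_CHAPERONES, IMMUNE_GO_TERMS, SYM


# ---------------------------------------------------------------------------
# reclustering

def recluster_cells(m: CountMatrix, cell_index, cfg: ClusterConfig,
                    seed: int = 0) -> tuple[Embedding, np.ndarray]:
    """Re-embed and subcluster an arbitrary cell subset.

    The subset gets its own variable genes, scaling, PCA (``cfg.n_dims``)
    and Leiden subclusters at ``cfg.resolution``.
    """
    sub = m.subset_cells(cell_index)
    if sub.n_cells < 2 * cfg.n_neighbors:
        raise ValueError(
            f"subset has {sub.n_cells} cells; at least {2 * cfg.n_neighbors} "
            "are required for reclustering"
        )
    norm = lognormalize(sub)
    hvg = select_hvg(norm, min(cfg.hvg_n, sub.n_genes))
    scaled = scale_clip(norm.subset_genes(hvg), cfg.scale_clip)
    n_dims = min(cfg.n_dims, sub.n_cells - 1, len(hvg) - 1)
    emb = pca(scaled, n_dims)
    labels = snn_cluster(emb, cfg, seed=seed)
    return emb, labels


def recluster_subset(m: CountMatrix, labels, cluster_id,
                     cfg: ClusterConfig, seed: int = 0
                     ) -> tuple[Embedding, np.ndarray]:
    """Recluster the cells carrying ``cluster_id`` in ``labels``."""
    mask = np.asarray(labels) == cluster_id
    return recluster_cells(m, mask, cfg, seed=seed)


# ---------------------------------------------------------------------------
# per-PC ANOVA and driver extraction

def pc_state_anova(embedding: Embedding, states, n_pcs: int = 10,
                   alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of PC scores on symbiotic state, per component.

    Each of the first ``n_pcs`` components is tested independently at
    level ``alpha`` (no multiplicity correction across components: each of
    the 10 components is read at face value).
    """
    states = np.asarray(states)
    uniq = np.unique(states)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two states, got {list(uniq)}")
    a = embedding.scores[states == uniq[0]]
    b = embedding.scores[states == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each state needs at least 2 cells")
    n_pcs = min(n_pcs, embedding.scores.shape[1])
    res = scipy.stats.f_oneway(a[:, :n_pcs], b[:, :n_pcs], axis=0)
    F = np.atleast_1d(res.statistic)
    p = np.atleast_1d(res.pvalue)
    return pd.DataFrame(
        {
            "pc": np.arange(1, n_pcs + 1),
            "F": F,
            "p": p,
            "significant": p < alpha,
        }
    )


def top_loading_genes(embedding: Embedding, pc: int, k: int = 10
                      ) -> pd.DataFrame:
    """Top-k positive and top-k negative loading genes of one component.

    Rows are sorted by decreasing |loading| with an ascending gene-id
    tiebreak; if a direction has fewer than ``k`` genes all available are
    returned with a warning.
    """
    if not 1 <= pc <= embedding.loadings.shape[1]:
        raise ValueError(f"pc={pc} outside 1..{embedding.loadings.shape[1]}")
    loadings = embedding.loadings[:, pc - 1]
    df = pd.DataFrame({"gene_id": embedding.gene_ids, "loading": loadings})
    pos = df[df["loading"] > 0].sort_values(
        ["loading", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    neg = df[df["loading"] < 0].sort_values(
        ["loading", "gene_id"], ascending=[True, True], kind="mergesort"
    ).head(k)
    if len(pos) < k or len(neg) < k:
        warnings.warn(
            f"PC {pc}: only {len(pos)} positive / {len(neg)} negative "
            f"loading genes available (requested {k} each)"
        )
    pos = pos.assign(direction="+")
    neg = neg.assign(direction="-")
    out = pd.concat([pos, neg], ignore_index=True)
    out["abs_loading"] = out["loading"].abs()
    out = out.sort_values(["abs_loading", "gene_id"],
                          ascending=[False, True], kind="mergesort",
                          ignore_index=True)
    out["pc"] = pc
    return out[["gene_id", "pc", "direction", "loading"]]


# ---------------------------------------------------------------------------
# differential expression between states

def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, positive-count variant.

    The per-gene reference is the geometric mean over cells computed on
    positive counts only (zeros contribute nothing to the log sum but
    remain in the denominator), which keeps the estimator defined on
    sparse single-cell counts. Factors are normalized to geometric mean 1.
    """
    n_cells = counts.shape[0]
    logc = np.zeros_like(counts, dtype=float)
    np.log(counts, out=logc, where=counts > 0)
    log_geo = logc.sum(axis=0) / n_cells
    usable = (counts > 0).any(axis=0)
    sf = np.empty(n_cells)
    for j in range(n_cells):
        pos = (counts[j] > 0) & usable
        if not pos.any():
            raise ValueError(f"cell {j} has no positive counts")
        sf[j] = np.exp(np.median(np.log(counts[j, pos]) - log_geo[pos]))
    return sf / np.exp(np.mean(np.log(sf)))


def de_between_states(m: CountMatrix, states, method: str = "nb_wald",
                      contrast: tuple[str, str] = (SYM, APO)
                      ) -> pd.DataFrame:
    """Two-group differential expression on raw counts.

    The default is a negative-binomial Wald test: median-of-ratios size
    factors over the subset, gene-wise method-of-moments dispersion pooled
    within groups (floored at 1e-8), and a Wald z on the log ratio of the
    normalized group means. ``log2fc`` is the symbiotic-over-aposymbiotic
    contrast. ``method="wilcoxon"`` bounds sensitivity with a rank-sum
    test on log-normalized values. Genes with all-zero counts in the
    subset are dropped (count reported in ``DataFrame.attrs['n_dropped']``).
    """
    states = np.asarray(states)
    g1, g0 = contrast
    mask1, mask0 = states == g1, states == g0
    if mask1.sum() < 3 or mask0.sum() < 3:
        raise ValueError("need at least 3 cells per state")

    counts = np.asarray(m.counts.todense(), dtype=float)
    expressed = counts.sum(axis=0) > 0
    n_dropped = int((~expressed).sum())
    counts = counts[:, expressed]
    gene_ids = m.gene_ids[expressed]

    if method == "wilcoxon":
        norm = lognormalize(m.subset_genes(expressed))
        x1, x0 = norm.values[mask1], norm.values[mask0]
        mean1 = np.expm1(x1).mean(axis=0)
        mean0 = np.expm1(x0).mean(axis=0)
        lfc = np.log2((mean1 + 1.0) / (mean0 + 1.0))
        res = scipy.stats.mannwhitneyu(
            x1, x0, axis=0, alternative="two-sided", method="asymptotic"
        )
        p = np.atleast_1d(res.pvalue)
    elif method == "nb_wald":
        sf = _size_factors(counts)
        q = counts / sf[:, None]
        n1, n0 = int(mask1.sum()), int(mask0.sum())
        mu1 = q[mask1].mean(axis=0)
        mu0 = q[mask0].mean(axis=0)
        # pooled within-group residual variance -> method-of-moments
        # dispersion on the common scale
        var1 = q[mask1].var(axis=0, ddof=1)
        var0 = q[mask0].var(axis=0, ddof=1)
        pooled_var = ((n1 - 1) * var1 + (n0 - 1) * var0) / (n1 + n0 - 2)
        pooled_mu = (n1 * mu1 + n0 * mu0) / (n1 + n0)
        mean_inv_sf = float(np.mean(1.0 / sf))
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (pooled_var - pooled_mu * mean_inv_sf) / pooled_mu**2
        alpha = np.clip(np.nan_to_num(alpha, nan=1e-8), 1e-8, 20.0)
        delta = 0.5 * (1.0 / n1 + 1.0 / n0)  # symmetric continuity shift
        a1, a0 = mu1 + delta, mu0 + delta
        lnfc = np.log(a1) - np.log(a0)
        inv_sf1 = float(np.sum(1.0 / sf[mask1]))
        inv_sf0 = float(np.sum(1.0 / sf[mask0]))
        var_mean1 = (a1 * inv_sf1 + alpha * a1**2 * n1) / n1**2
        var_mean0 = (a0 * inv_sf0 + alpha * a0**2 * n0) / n0**2
        se = np.sqrt(var_mean1 / a1**2 + var_mean0 / a0**2)
        z = lnfc / se
        p = 2.0 * scipy.stats.norm.sf(np.abs(z))
        lfc = lnfc / np.log(2.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": lfc,
            "p": p,
            "padj": bh_adjust(p),
            "test": method,
        }
    ).sort_values(["padj", "p", "gene_id"], kind="mergesort",
                  ignore_index=True)
    out.attrs["n_dropped"] = n_dropped
    logger.info(
        '{"event": "de_between_states", "method": "%s", "n_dropped": %d}'
        % (method, n_dropped)
    )
    return out


# ---------------------------------------------------------------------------
# driver report

@dataclass
class PCSeparationReport:
    """Per-cluster record of state-separating components and their drivers."""

    cluster_id: object
    pc_stats: pd.DataFrame
    drivers: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def flagged(self, min_sig_pcs: int = 1, min_de_immune: int = 5) -> bool:
        """State-effect call: enough significant PCs and enough drivers
        that are both differentially expressed and immune-tagged."""
        return (self.summary["n_significant_pcs"] >= min_sig_pcs
                and self.summary["n_de_immune_drivers"] >= min_de_immune)


def build_driver_report(anova: pd.DataFrame,
                        drivers_by_pc: dict[int, pd.DataFrame],
                        de: pd.DataFrame,
                        annotations: pd.DataFrame,
                        cluster_id=None,
                        immune_terms=IMMUNE_GO_TERMS,
                        chaperone_cog: str = COG_CHAPERONES,
                        de_alpha: float = 0.05) -> PCSeparationReport:
    """Join per-PC drivers with DE status and annotation tags.

    Drivers are de-duplicated by gene across significant components (a
    gene driving several PCs appears once, all PCs listed, keeping the
    loading of largest magnitude). Genes without an annotated Pfam domain
    — including genes absent from the annotation table, which are logged —
    are removed from the final table. The summary counts significant PCs,
    drivers, DE drivers, immune-GO-tagged drivers and chaperone-COG
    drivers.
    """
    sig_pcs = anova.loc[anova["significant"], "pc"].tolist()
    immune_terms = set(immune_terms)

    rows = []
    for pc in sig_pcs:
        if pc not in drivers_by_pc:
            raise ValueError(f"no drivers supplied for significant PC {pc}")
        rows.append(drivers_by_pc[pc])
    if rows:
        stacked = pd.concat(rows, ignore_index=True)
        stacked["abs_loading"] = stacked["loading"].abs()
        best = stacked.sort_values(
            ["gene_id", "abs_loading"], ascending=[True, False],
            kind="mergesort",
        ).drop_duplicates("gene_id")
        pcs = stacked.groupby("gene_id")["pc"].apply(
            lambda s: ",".join(str(v) for v in sorted(set(s)))
        )
        drivers = best.set_index("gene_id")
        drivers["pcs"] = pcs
    else:
        drivers = pd.DataFrame(
            columns=["pc", "direction", "loading", "abs_loading", "pcs"]
        )
        drivers.index.name = "gene_id"

    de_idx = de.set_index("gene_id")
    drivers["is_de"] = (
        de_idx["padj"].reindex(drivers.index) < de_alpha
    ).fillna(False).astype(bool)
    drivers["log2fc"] = de_idx["log2fc"].reindex(drivers.index)

    ann = annotations.reindex(drivers.index)
    n_unannotated = int(ann["pfam"].isna().sum())
    if n_unannotated:
        logger.info(
            '{"event": "driver_report", "n_missing_annotation": %d}'
            % n_unannotated
        )
    go = ann["go"].fillna("")
    drivers["immune_go"] = go.map(
        lambda s: bool(immune_terms & set(str(s).split(";")))
    )
    drivers["cog_chaperone"] = ann["cog"].fillna("") == chaperone_cog
    drivers["pfam"] = ann["pfam"].fillna(False).astype(bool)

    kept = drivers[drivers["pfam"]].drop(columns=["abs_loading", "pc"])
    kept = kept.sort_values(["pcs", "gene_id"], kind="mergesort")

    summary = {
        "cluster_id": cluster_id,
        "n_significant_pcs": len(sig_pcs),
        "significant_pcs": [int(pc) for pc in sig_pcs],
        "n_drivers": int(len(kept)),
        "n_removed_no_pfam": int(len(drivers) - len(kept)),
        "n_de_drivers": int(kept["is_de"].sum()),
        "n_immune_drivers": int(kept["immune_go"].sum()),
        "n_de_immune_drivers": int((kept["is_de"] & kept["immune_go"]).sum()),
        "n_chaperone_drivers": int(kept["cog_chaperone"].sum()),
    }
    return PCSeparationReport(
        cluster_id=cluster_id, pc_stats=anova, drivers=kept, summary=summary
    )


def state_separation_report(m: CountMatrix, cell_index, states,
                            annotations: pd.DataFrame,
                            cfg: ClusterConfig | None = None,
                            seed: int = 0, cluster_id=None,
                            n_pcs: int = 10, alpha: float = 0.05,
                            k: int = 10, de_alpha: float = 0.05,
                            de_method: str = "nb_wald",
                            immune_terms=IMMUNE_GO_TERMS
                            ) -> PCSeparationReport:
    """Run the full per-cluster procedure on one cell subset.

    Reclusters the subset, tests the leading PCs for state separation,
    extracts drivers of the significant PCs, runs DE between states, and
    assembles the annotated report.
    """
    cfg = cfg or ClusterConfig(resolution=0.4)
    cell_index = np.asarray(cell_index)
    states = np.asarray(states)
    if cell_index.dtype == bool:
        sub_states = states[cell_index]
    else:
        sub_states = states[cell_index]
    emb, _ = recluster_cells(m, cell_index, cfg, seed=seed)
    anova = pc_state_anova(emb, sub_states, n_pcs=n_pcs, alpha=alpha)
    drivers_by_pc = {
        int(pc): top_loading_genes(emb, int(pc), k=k)
        for pc in anova.loc[anova["significant"], "pc"]
    }
    de = de_between_states(m.subset_cells(cell_index), sub_states,
                           method=de_method)
    return build_driver_report(
        anova, drivers_by_pc, de, annotations, cluster_id=cluster_id,
        immune_terms=immune_terms, de_alpha=de_alpha,
    )
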