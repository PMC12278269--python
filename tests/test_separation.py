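"""Per-PC ANOVA, driver extraction, NB Wald DE, and the driver report."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from symcell.embed import ClusterConfig
from symcell.io import CountMatrix
from symcell.separation import (build_driver_report, de_between_states,
                                pc_state_anova, recluster_subset,
                                state_separation_report, top_loading_genes)
from symcell.simulate import SimConfig, generate_dataset
from symcell.validation import _scores_embedding, oneway_f_oracle

from conftest import majority_map


# ---------------------------------------------------------------------------
# ANOVA

def test_anova_worked_example():
    scores = np.array([1.0, 2, 3, 7, 8, 9])[:, None]
    states = np.array(["sym"] * 3 + ["apo"] * 3)
    res = pc_state_anova(_scores_embedding(scores), states)
    assert res["F"][0] == pytest.approx(54.0, abs=1e-10)
    assert res["p"][0] == pytest.approx(0.00182, abs=5e-5)
    assert bool(res["significant"][0])


def test_anova_matches_closed_form_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n1, n0 = rng.integers(3, 30, 2)
        x, y = rng.normal(0, 1, n1), rng.normal(0.5, 2, n0)
        scores = np.concatenate([x, y])[:, None]
        states = np.array(["s"] * n1 + ["a"] * n0)
        res = pc_state_anova(_scores_embedding(scores), states)
        f_ref, p_ref = oneway_f_oracle(x, y)
        assert res["F"][0] == pytest.approx(f_ref, abs=1e-10 * max(1, f_ref))
        assert res["p"][0] == pytest.approx(p_ref, abs=1e-10)


def test_anova_identical_distributions():
    scores = np.array([1.0, 2, 3, 1, 2, 3])[:, None]
    states = np.array(["s"] * 3 + ["a"] * 3)
    res = pc_state_anova(_scores_embedding(scores), states)
    assert res["F"][0] == pytest.approx(0.0, abs=1e-12)
    assert not bool(res["significant"][0])


def test_anova_requires_two_states():
    scores = np.ones((4, 1))
    with pytest.raises(ValueError, match="two states"):
        pc_state_anova(_scores_embedding(scores), np.array(["s"] * 4))


def test_anova_permutation_null_rate():
    from symcell.validation import anova_permutation_rate

    rate = anova_permutation_rate(seed=0, n_perms=500)
    assert 0.03 <= rate <= 0.07


# ---------------------------------------------------------------------------
# driver extraction

def _loadings_embedding(loadings):
    loadings = np.asarray(loadings, dtype=float)
    n_genes, k = loadings.shape
    return dataclasses.replace(
        _scores_embedding(np.zeros((5, k))),
        loadings=loadings,
        gene_ids=np.array([chr(97 + i) for i in range(n_genes)], dtype=object),
    )


def test_top_loading_both_directions():
    emb = _loadings_embedding(np.array([[0.9], [-0.8], [0.1], [-0.05]]))
    out = top_loading_genes(emb, 1, k=1)
    assert set(zip(out["gene_id"], out["direction"])) == {("a", "+"),
                                                          ("b", "-")}
    assert list(out["gene_id"]) == ["a", "b"]  # sorted by |loading|


def test_top_loading_short_side_warns():
    emb = _loadings_embedding(np.array([[0.9], [0.5], [0.3], [-0.2], [0.1]]))
    with pytest.warns(UserWarning, match="negative"):
        out = top_loading_genes(emb, 1, k=10)
    assert len(out) == 5


def test_top_loading_pc_bounds():
    emb = _loadings_embedding(np.array([[0.9], [-0.8]]))
    with pytest.raises(ValueError):
        top_loading_genes(emb, 2)


# ---------------------------------------------------------------------------
# differential expression

def _two_state_matrix(counts1, counts0):
    dense = np.vstack([counts1, counts0])
    states = np.array(["symbiotic"] * len(counts1)
                      + ["aposymbiotic"] * len(counts0))
    m = CountMatrix(
        sp.csr_matrix(dense),
        np.array([f"BC{i}" for i in range(dense.shape[0])], dtype=object),
        np.array([f"g{j}" for j in range(dense.shape[1])], dtype=object),
        np.array(["host"] * dense.shape[1], dtype=object),
    )
    return m, states


def test_de_equal_counts_null_gene():
    ones = np.full((6, 2), 3)
    m, states = _two_state_matrix(ones[:3], ones[3:])
    res = de_between_states(m, states)
    assert res["log2fc"].abs().max() == pytest.approx(0.0, abs=1e-12)
    assert (res["p"] > 0.99).all()


def test_de_requires_three_cells_per_state():
    m, states = _two_state_matrix(np.ones((2, 3), dtype=int),
                                  np.ones((4, 3), dtype=int))
    with pytest.raises(ValueError, match="3 cells"):
        de_between_states(m, states)


def test_de_drops_all_zero_genes():
    dense = np.ones((8, 4), dtype=int)
    dense[:, 2] = 0
    m, states = _two_state_matrix(dense[:4], dense[4:])
    res = de_between_states(m, states)
    assert "g2" not in set(res["gene_id"])
    assert res.attrs["n_dropped"] == 1


def test_de_recovers_planted_sign_and_genes(small_config):
    """Planted immune genes: negative estimated LFC and >=80% recall at
    BH-adjusted p < 0.05 (median over seeds)."""
    recalls, sign_rates = [], []
    for seed in (1, 2, 3):
        cfg = dataclasses.replace(small_config, seed=seed, doublet_rate=0.0)
        ds = generate_dataset(cfg)
        truth = ds.truth.cells
        mask = (truth["cluster"] == cfg.effect_cluster_id).to_numpy()
        host = ds.matrix.host_view().subset_cells(mask)
        res = de_between_states(host, truth["state"].to_numpy()[mask])
        imm = ds.truth.immune_genes()
        sub = res.set_index("gene_id").reindex(imm).dropna(subset=["p"])
        recalls.append((sub["padj"] < 0.05).mean())
        sign_rates.append((sub["log2fc"] < 0).mean())
    assert np.median(recalls) >= 0.8
    assert np.median(sign_rates) >= 0.95


def test_de_null_cluster_clean(small_config):
    clean = []
    for seed in (1, 2, 3):
        cfg = dataclasses.replace(small_config, seed=seed, doublet_rate=0.0)
        ds = generate_dataset(cfg)
        truth = ds.truth.cells
        mask = (truth["cluster"] == cfg.null_cluster_id).to_numpy()
        host = ds.matrix.host_view().subset_cells(mask)
        res = de_between_states(host, truth["state"].to_numpy()[mask])
        clean.append(int((res["padj"] < 0.05).sum()) == 0)
        assert (res["p"] < 0.05).mean() < 0.12  # raw p near nominal
    assert np.median(clean) == 1


def test_de_wilcoxon_alternative_agrees_on_planted(small_config):
    cfg = dataclasses.replace(small_config, seed=5, doublet_rate=0.0)
    ds = generate_dataset(cfg)
    truth = ds.truth.cells
    mask = (truth["cluster"] == cfg.effect_cluster_id).to_numpy()
    host = ds.matrix.host_view().subset_cells(mask)
    res = de_between_states(host, truth["state"].to_numpy()[mask],
                            method="wilcoxon")
    imm = ds.truth.immune_genes()
    sub = res.set_index("gene_id").reindex(imm).dropna(subset=["p"])
    assert (sub["padj"] < 0.05).mean() >= 0.8


# ---------------------------------------------------------------------------
# reclustering and the report

def test_recluster_subset_only_contains_cluster(clustered):
    host, _, _, labels, truth = clustered
    emb, sub = recluster_subset(host, labels, 1,
                                ClusterConfig(resolution=0.3, hvg_n=300),
                                seed=3)
    assert len(emb.cell_ids) == int((labels == 1).sum())
    assert set(emb.cell_ids) <= set(host.cell_ids)
    emb2, sub2 = recluster_subset(host, labels, 1,
                                  ClusterConfig(resolution=0.3, hvg_n=300),
                                  seed=3)
    assert np.array_equal(sub, sub2)


def test_recluster_too_small_cluster_errors(clustered):
    host, _, _, labels, _ = clustered
    tiny = np.where(np.arange(host.n_cells) < 10, 99, labels)
    with pytest.raises(ValueError, match="cells"):
        recluster_subset(host, tiny, 99, ClusterConfig(n_neighbors=20))


def test_effect_cluster_state_dominated_subcluster(clustered, small_config):
    """Reclustering the effect cluster yields a subcluster composed almost
    entirely of symbiotic-state cells (the planted analogue of a
    symbiosis-specific gastrodermal cell state)."""
    host, _, _, labels, truth = clustered
    mapping = majority_map(labels, truth["cluster"].to_numpy(dtype=int))
    effect_labels = [c for c, t in mapping.items()
                     if t == small_config.effect_cluster_id]
    mask = np.isin(labels, effect_labels)
    emb, sub = recluster_subset(host, np.where(mask, 0, -1), 0,
                                ClusterConfig(resolution=0.4, hvg_n=300),
                                seed=3)
    states = truth["state"].to_numpy()[mask]
    purity = max(
        (states[sub == c] == "symbiotic").mean()
        for c in np.unique(sub) if (sub == c).sum() >= 10
    )
    assert purity >= 0.9


def _report_inputs():
    anova = pd.DataFrame({
        "pc": [1, 2, 3],
        "F": [9.0, 8.0, 0.1],
        "p": [0.001, 0.002, 0.9],
        "significant": [True, True, False],
    })
    d1 = pd.DataFrame({"gene_id": ["a", "b"], "pc": 1,
                       "direction": ["+", "-"], "loading": [0.9, -0.7]})
    d2 = pd.DataFrame({"gene_id": ["b", "c"], "pc": 2,
                       "direction": ["+", "-"], "loading": [0.5, -0.4]})
    de = pd.DataFrame({"gene_id": ["a", "b", "c"],
                       "log2fc": [-1.2, 0.3, 2.0],
                       "p": [1e-5, 0.2, 1e-4],
                       "padj": [1e-4, 0.4, 1e-3],
                       "test": "nb_wald"})
    ann = pd.DataFrame(
        {
            "pfam": [True, True, False],
            "cog": ["O", "", ""],
            "go": ["GO:0006955", "", "GO:0070555"],
        },
        index=pd.Index(["a", "b", "c"], name="gene_id"),
    )
    return anova, {1: d1, 2: d2}, de, ann


def test_driver_report_dedup_and_tags():
    anova, drivers, de, ann = _report_inputs()
    rep = build_driver_report(anova, drivers, de, ann, cluster_id="X")
    # three unique drivers; c lacks a Pfam domain and is removed
    assert rep.summary["n_significant_pcs"] == 2
    assert rep.summary["n_drivers"] == 2
    assert rep.summary["n_removed_no_pfam"] == 1
    b_row = rep.drivers.loc["b"]
    assert b_row["pcs"] == "1,2"
    assert b_row["loading"] == pytest.approx(-0.7)  # largest |loading| kept
    assert rep.summary["n_de_drivers"] == 1  # only 'a'
    assert rep.summary["n_immune_drivers"] == 1
    assert rep.summary["n_chaperone_drivers"] == 1
    # containment invariants
    kept = set(rep.drivers.index)
    assert set(rep.drivers.index[rep.drivers["is_de"]]) <= kept
    assert set(rep.drivers.index[rep.drivers["immune_go"]]) <= kept


def test_driver_report_no_significant_pcs():
    anova, drivers, de, ann = _report_inputs()
    anova = anova.assign(significant=False)
    rep = build_driver_report(anova, {}, de, ann)
    assert rep.drivers.empty
    assert rep.summary["n_significant_pcs"] == 0
    assert len(rep.pc_stats) == 3  # per-PC stats retained


def test_fixture_effect_cluster_flagged_null_not(clustered, small_dataset,
                                                 small_config):
    host, _, _, labels, truth = clustered
    mapping = majority_map(labels, truth["cluster"].to_numpy(dtype=int))
    states = truth["state"].to_numpy()
    cfg = ClusterConfig(resolution=0.4, hvg_n=300)

    effect_mask = np.isin(labels, [c for c, t in mapping.items()
                                   if t == small_config.effect_cluster_id])
    rep = state_separation_report(host, effect_mask, states,
                                  small_dataset.genes, cfg=cfg, seed=7)
    assert rep.summary["n_significant_pcs"] >= 1
    assert rep.summary["n_de_immune_drivers"] >= 5
    assert rep.flagged()

    null_mask = np.isin(labels, [c for c, t in mapping.items()
                                 if t == small_config.null_cluster_id])
    rep0 = state_separation_report(host, null_mask, states,
                                   small_dataset.genes, cfg=cfg, seed=7)
    assert not rep0.flagged()
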