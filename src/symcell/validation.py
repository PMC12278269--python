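"""Independent oracles and end-to-end validation studies.

The oracles here deliberately avoid the code paths the package uses:
closed-form ANOVA sums with ``scipy.stats.f.sf`` against ``f_oneway``,
exact integer hypergeometric enumeration against ``fisher_exact``, and a
dense LAPACK SVD against the ARPACK-based PCA. The studies replay the
planted-truth recovery and null-calibration experiments on the synthetic
generator's default conditions.
"""

from __future__ import annotations

import dataclasses
import hashlib
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import stage_seed
from .embed import ClusterConfig, NormalizedMatrix, cluster_workflow, \
    merge_state_split_clusters, pca, scale_clip
from .genesets import mwu_go_enrichment
from .io import CountMatrix
from .partition import classify_hosting, symbiont_fraction
from .pipeline import RunConfig, run
from .qc import QCThresholds, qc_filter, remove_flagged_doublets
from .separation import de_between_states, pc_state_anova, \
    state_separation_report
from .simulate import SimConfig, generate_dataset


# ---------------------------------------------------------------------------
# oracles

def oneway_f_oracle(*groups) -> tuple[float, float]:
    """Closed-form one-way ANOVA from sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_values) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), float(scipy.stats.f.sf(f, dfb, dfw))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums, in exact integer arithmetic, the probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed one (with the standard 1+1e-7 relative tolerance for ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    thresh = p_obs * (1.0 + 1e-7)
    total = sum(
        w for x in range(lo, hi + 1)
        if (w := comb(r1, x) * comb(r2, c1 - x)) <= thresh
    )
    return total / denom


def enumerate_small_tables(max_n: int):
    """All 2x2 nonnegative-integer tables with grand total <= max_n."""
    for n in range(1, max_n + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    yield a, b, c, n - a - b - c


def anova_oracle_gap(seed: int = 0, n_trials: int = 200) -> float:
    """Max |p_impl - p_oracle| of the per-PC ANOVA over random inputs.

    Includes the worked three-vs-three example whose closed form gives
    F = 54 exactly.
    """
    rng = np.random.default_rng(seed)
    gap = 0.0
    cases = [(np.array([1.0, 2, 3]), np.array([7.0, 8, 9]))]
    for _ in range(n_trials):
        n1, n0 = rng.integers(3, 40, 2)
        cases.append((rng.normal(0, 1, n1), rng.normal(0.3, 1.2, n0)))
    for x, y in cases:
        scores = np.concatenate([x, y])[:, None]
        emb = _scores_embedding(scores)
        states = np.array(["s"] * len(x) + ["a"] * len(y))
        res = pc_state_anova(emb, states, n_pcs=1)
        f_ref, p_ref = oneway_f_oracle(x, y)
        gap = max(gap, abs(res["p"][0] - p_ref), abs(res["F"][0] - f_ref) /
                  max(1.0, f_ref))
    return gap


def fisher_oracle_gap(max_margin_total: int = 30) -> float:
    """Max |p| gap of ``fisher_exact`` vs enumeration on all small tables."""
    gap = 0.0
    for a, b, c, d in enumerate_small_tables(max_margin_total):
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")
        gap = max(gap, abs(p - fisher_two_sided_oracle(a, b, c, d)))
    return gap


def pca_oracle_gap(seed: int = 0, n_trials: int = 5, n_dims: int = 10
                   ) -> float:
    """Max score deviation (up to sign) vs a dense full SVD, 50x30 inputs."""
    rng = np.random.default_rng(seed)
    gap = 0.0
    for _ in range(n_trials):
        x = rng.normal(0, 1, (50, 30))
        scaled = scale_clip(NormalizedMatrix(
            x, np.array([f"c{i}" for i in range(50)], dtype=object),
            np.array([f"g{i}" for i in range(30)], dtype=object)))
        emb = pca(scaled, n_dims)
        u, s, vt = np.linalg.svd(scaled.values, full_matrices=False)
        ref = u[:, :n_dims] * s[:n_dims]
        for j in range(n_dims):
            sign = np.sign(ref[:, j] @ emb.scores[:, j]) or 1.0
            gap = max(gap, np.max(np.abs(emb.scores[:, j] - sign * ref[:, j])))
    return gap


def _scores_embedding(scores: np.ndarray):
    """Wrap raw per-cell scores as a minimal Embedding for the ANOVA."""
    from .embed import Embedding

    n, k = scores.shape
    return Embedding(
        scores=scores,
        loadings=np.eye(k),
        variance_explained=np.ones(k) / k,
        n_dims=k,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"g{i}" for i in range(k)], dtype=object),
    )


# ---------------------------------------------------------------------------
# planted-truth recovery on the default study conditions

def _prepare(cfg: SimConfig):
    """Simulate, drop doublets, QC; return matrix, states, truth rows."""
    ds = generate_dataset(cfg)
    m = remove_flagged_doublets(ds.matrix,
                                ds.cells["is_doublet"].to_numpy())
    m, _ = qc_filter(m, QCThresholds())
    truth = ds.truth.cells.reindex(m.cell_ids)
    return ds, m, truth


def _majority_map(detected: np.ndarray, truth_clusters: np.ndarray) -> dict:
    """Map each detected cluster label to its majority truth cluster."""
    out = {}
    for c in np.unique(detected):
        vals, counts = np.unique(truth_clusters[detected == c],
                                 return_counts=True)
        out[int(c)] = int(vals[np.argmax(counts)])
    return out


def recovery_study(n_seeds: int = 10, base_seed: int = 1,
                   config: SimConfig | None = None) -> dict:
    """Planted-truth recovery over repeated simulations.

    For each seed: simulate the default two-state experiment, run the
    real pipeline stages (doublet removal, QC, symbiont partitioning,
    host-gene clustering), locate the detected clusters corresponding to
    the planted effect and null clusters, and score (a) hosting-cell
    classification accuracy against truth, (b) whether the effect cluster
    is flagged (>= 1 significant PC and >= 5 drivers that are DE and
    immune-tagged), and (c) whether the null cluster shows zero genes at
    BH-adjusted p < 0.05.
    """
    base_cfg = config or SimConfig()
    accuracies, effect_flagged, null_clean, n_hosting = [], [], [], []
    for i in range(n_seeds):
        cfg = dataclasses.replace(
            base_cfg, seed=stage_seed(base_seed, f"recovery{i}")
        )
        ds, m, truth = _prepare(cfg)
        fractions = symbiont_fraction(m)
        calls = classify_hosting(fractions)
        accuracies.append(
            float((calls.to_numpy() ==
                   truth["is_hosting"].to_numpy(dtype=bool)).mean())
        )
        n_hosting.append(int(calls.sum()))

        host = m.host_view()
        _, emb, labels = cluster_workflow(
            host, ClusterConfig(), seed=stage_seed(cfg.seed, "cluster")
        )
        states = truth["state"].to_numpy()
        labels = merge_state_split_clusters(emb, labels, states)
        truth_clusters = truth["cluster"].to_numpy(dtype=int)
        mapping = _majority_map(labels, truth_clusters)

        effect_mask = np.isin(
            labels,
            [c for c, t in mapping.items() if t == cfg.effect_cluster_id],
        )
        report = state_separation_report(
            host, effect_mask, states, ds.genes,
            cfg=ClusterConfig(resolution=0.4),
            seed=stage_seed(cfg.seed, "separation"),
            cluster_id="effect",
        )
        effect_flagged.append(report.flagged())

        null_mask = np.isin(
            labels,
            [c for c, t in mapping.items() if t == cfg.null_cluster_id],
        )
        de_null = de_between_states(host.subset_cells(null_mask),
                                    states[null_mask])
        null_clean.append(int((de_null["padj"] < 0.05).sum()) == 0)
    return {
        "n_seeds": n_seeds,
        "hosting_accuracy_mean": float(np.mean(accuracies)),
        "hosting_accuracy_min": float(np.min(accuracies)),
        "n_hosting_mean": float(np.mean(n_hosting)),
        "effect_flag_rate": float(np.mean(effect_flagged)),
        "null_clean_rate": float(np.mean(null_clean)),
    }


# ---------------------------------------------------------------------------
# statistical calibration under nulls

def anova_permutation_rate(seed: int = 0, n_cells: int = 200,
                           n_pcs: int = 10, n_perms: int = 1000,
                           alpha: float = 0.05) -> float:
    """Fraction of PCs called significant under label permutation."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(0, 1, (n_cells, n_pcs))
    emb = _scores_embedding(scores)
    states = np.array(["s"] * (n_cells // 2) + ["a"] * (n_cells - n_cells // 2))
    hits = 0
    for _ in range(n_perms):
        perm = rng.permutation(states)
        res = pc_state_anova(emb, perm, n_pcs=n_pcs, alpha=alpha)
        hits += int(res["significant"].sum())
    return hits / (n_perms * n_pcs)


def mwu_null_rate(seed: int = 0, n_genes: int = 1000, n_terms: int = 200,
                  term_size: int = 20, alpha: float = 0.05) -> float:
    """Fraction of random terms with p < alpha on i.i.d. gene scores."""
    rng = np.random.default_rng(seed)
    scores = pd.Series(rng.normal(0, 1, n_genes),
                       index=[f"g{i}" for i in range(n_genes)])
    rows = []
    for t in range(n_terms):
        members = rng.choice(scores.index.to_numpy(), term_size,
                             replace=False)
        rows.append(pd.DataFrame({"gene_id": members, "term": f"T{t}"}))
    term_map = pd.concat(rows, ignore_index=True)
    res = mwu_go_enrichment(scores, term_map, min_term_size=5)
    return float((res["p"] < alpha).mean())


def fisher_null_rate(seed: int = 0, n_background: int = 600,
                     group_size: int = 150, n_terms: int = 200,
                     term_size: int = 25, alpha: float = 0.05) -> float:
    """Fraction of terms with p < alpha for a uniformly drawn group."""
    from .orthologs import fisher_enrichment

    rng = np.random.default_rng(seed)
    background = [f"OG{i}" for i in range(n_background)]
    group = set(rng.choice(background, group_size, replace=False))
    rows = []
    for t in range(n_terms):
        members = rng.choice(background, term_size, replace=False)
        rows.append(pd.DataFrame({"element": members, "term": f"T{t}"}))
    term_map = pd.concat(rows, ignore_index=True)
    res = fisher_enrichment(group, background, term_map)
    return float((res["p"] < alpha).mean())


def mwu_fdr_study(seed: int = 0, n_replicates: int = 500,
                  n_genes: int = 600, n_terms: int = 40,
                  n_true_terms: int = 8, term_size: int = 15,
                  shift: float = 1.5, fdr: float = 0.1) -> dict:
    """Empirical FDR of BH-at-0.1 over replicated mixed-null experiments.

    Each replicate plants ``n_true_terms`` genuinely shifted terms among
    null terms; the empirical FDR is the fraction of discovered terms
    that are null, pooled over replicates.
    """
    rng = np.random.default_rng(seed)
    false_disc = 0
    total_disc = 0
    gene_ids = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    for _ in range(n_replicates):
        values = rng.normal(0, 1, n_genes)
        rows = []
        true_terms = set()
        for t in range(n_terms):
            members = rng.choice(n_genes, term_size, replace=False)
            if t < n_true_terms:
                values[members] += shift
                true_terms.add(f"T{t}")
            rows.append(pd.DataFrame(
                {"gene_id": gene_ids[members], "term": f"T{t}"}))
        scores = pd.Series(values, index=gene_ids)
        res = mwu_go_enrichment(scores, pd.concat(rows, ignore_index=True),
                                min_term_size=5, fdr=fdr)
        disc = res.loc[res["significant"], "term"]
        total_disc += len(disc)
        false_disc += int((~disc.isin(true_terms)).sum())
    return {
        "empirical_fdr": false_disc / max(total_disc, 1),
        "n_discoveries": total_disc,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# determinism

def _tree_digest(directory: Path) -> dict[str, str]:
    out = {}
    for path in sorted(directory.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(directory))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return out


def determinism_check(seed: int = 1, out_root=None,
                      sim: SimConfig | None = None) -> dict:
    """Run the full pipeline twice with one seed; compare output bytes."""
    import tempfile

    root = Path(out_root) if out_root else Path(tempfile.mkdtemp())
    cfg = RunConfig(sim=sim or SimConfig(), seed=seed)
    d1 = run(cfg, root / "run1")
    d2 = run(RunConfig(sim=sim or SimConfig(), seed=seed), root / "run2")
    h1, h2 = _tree_digest(d1), _tree_digest(d2)
    return {
        "identical": h1 == h2,
        "n_files": len(h1),
        "mismatched": sorted(k for k in h1 if h1.get(k) != h2.get(k)),
    }
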