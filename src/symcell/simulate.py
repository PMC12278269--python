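"""Synthetic host+symbiont count matrices with planted ground truth.

The generator emulates the structure of a dual-genome (coral host + algal
symbiont) droplet scRNA-seq experiment with one symbiotic and one
aposymbiotic sample:

* a handful of transcriptomic cell clusters, each with a sparse set of
  strongly up-regulated marker genes on top of a shared log-normal
  baseline program;
* a minority population of algal-hosting cells, confined to one cluster
  and to the symbiotic sample, in which a Beta-distributed share of the
  sequencing budget is reallocated from host to symbiont genes;
* one "effect" gastrodermis-like cluster whose symbiotic-state cells
  down-regulate a planted immune gene set and up-regulate nutrient-cycling
  marker genes;
* one "null" immune-cell-like cluster with no state effect at all;
* flagged doublets formed by summing two cells' counts.

Counts are negative binomial: ``variance = mu + mu**2 / nb_dispersion``
(``nb_dispersion`` is the NB size parameter), sampled as a gamma-Poisson
mixture. Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import HOST, SYMBIONT, CountMatrix, read_matrix, write_matrix

SYM = "symbiotic"
APO = "aposymbiotic"

#: GO identifiers used to tag the planted immune gene set: immune response,
#: NF-kappaB signaling, Toll-like receptor signaling, interleukin response,
#: and TGF-beta receptor signaling.
IMMUNE_GO_TERMS = (
    "GO:0006955",
    "GO:0007249",
    "GO:0002224",
    "GO:0070555",
    "GO:0007179",
)
#: GO identifiers for the planted nutrient-cycling/lipid-metabolism markers.
NUTRIENT_GO_TERMS = ("GO:0006807", "GO:0006629")
#: COG category "posttranslational modification, protein turnover, chaperones".
COG_CHAPERONES = "O"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated two-sample experiment.

    Defaults are the conditions used throughout validation: two states of
    3,000 cells each, six equally sized clusters, 2,000 host and 300
    symbiont genes, a 40-gene immune set down-regulated by 1.5 log2 units
    in symbiotic effect-cluster cells, and a bimodal symbiont read share
    (Beta(70, 30), mean 0.7) in hosting cells against a 0.1% leak
    elsewhere.
    """

    n_cells_per_state: int = 3000
    n_host_genes: int = 2000
    n_symbiont_genes: int = 300
    n_clusters: int = 6
    cluster_proportions: tuple[float, ...] | None = None
    library_size_log_mean: float = math.log(2000.0)
    library_size_log_sd: float = 0.35
    nb_dispersion: float = 10.0
    hosting_cluster_id: int = 1
    hosting_cell_fraction: float = 0.05
    symbiont_read_fraction_alpha: float = 70.0
    symbiont_read_fraction_beta: float = 30.0
    symbiont_leak: float = 1e-3
    effect_cluster_id: int = 2
    immune_geneset_size: int = 40
    immune_lfc: float = -1.5
    marker_geneset_size: int = 10
    marker_lfc: float = 1.5
    null_cluster_id: int = 3
    cluster_marker_genes: int = 25
    cluster_marker_fold: float = 8.0
    doublet_rate: float = 0.06
    pfam_rate: float = 0.85
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        return np.asarray(self.cluster_proportions, dtype=float)

    def validate(self) -> None:
        for name in ("n_cells_per_state", "n_host_genes", "n_symbiont_genes",
                     "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        p = self.proportions()
        if len(p) != self.n_clusters:
            raise ValueError("cluster_proportions length != n_clusters")
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("cluster_proportions must be a probability vector")
        for name in ("hosting_cell_fraction", "doublet_rate", "symbiont_leak",
                     "pfam_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("hosting_cluster_id", "effect_cluster_id",
                     "null_cluster_id"):
            if not 1 <= getattr(self, name) <= self.n_clusters:
                raise ValueError(
                    f"{name}={getattr(self, name)} not in 1..{self.n_clusters}"
                )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        reserved = (self.n_clusters * self.cluster_marker_genes
                    + self.immune_geneset_size + self.marker_geneset_size)
        if reserved > self.n_host_genes:
            raise ValueError(
                f"gene sets need {reserved} genes but only "
                f"{self.n_host_genes} host genes are available"
            )


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth records for every emitted cell and gene."""

    cells: pd.DataFrame  # indexed by barcode
    genes: pd.DataFrame  # indexed by gene_id
    config: SimConfig

    def immune_genes(self) -> np.ndarray:
        return self.genes.index[self.genes["is_immune"]].to_numpy()

    def nutrient_marker_genes(self) -> np.ndarray:
        return self.genes.index[self.genes["is_nutrient_marker"]].to_numpy()


class SimulatedDataset(NamedTuple):
    matrix: CountMatrix
    cells: pd.DataFrame  # per-cell metadata: state, is_doublet
    genes: pd.DataFrame  # gene annotation: origin, pfam, cog, go
    truth: GroundTruth


def _barcode(i: int) -> str:
    """Deterministic 12-mer barcode from a cell index (base-4 over ACGT)."""
    letters = "ACGT"
    digits = []
    for _ in range(12):
        digits.append(letters[i % 4])
        i //= 4
    return "".join(reversed(digits)) + "-1"


def _gene_annotation(cfg: SimConfig, rng: np.random.Generator,
                     host_ids, sym_ids, immune_idx, marker_idx) -> pd.DataFrame:
    n = cfg.n_host_genes
    pfam = rng.random(n) < cfg.pfam_rate
    pfam[immune_idx] = True
    pfam[marker_idx] = True

    cog = np.array([""] * n, dtype=object)
    cog_draw = rng.choice(
        ["", COG_CHAPERONES, "J", "C", "E"], size=n,
        p=[0.70, 0.05, 0.09, 0.08, 0.08],
    )
    cog[:] = cog_draw
    # chaperone category is enriched among the immune set (HSPs, cathepsins)
    cog[immune_idx] = np.where(
        rng.random(len(immune_idx)) < 0.4, COG_CHAPERONES, cog[immune_idx]
    )

    go = [set() for _ in range(n)]
    for j, gi in enumerate(immune_idx):
        go[gi].add(IMMUNE_GO_TERMS[0])
        go[gi].add(IMMUNE_GO_TERMS[1 + j % (len(IMMUNE_GO_TERMS) - 1)])
    for gi in marker_idx:
        go[gi].update(NUTRIENT_GO_TERMS)
    background_terms = [f"GO:81000{k:02d}" for k in range(25)]
    for term in background_terms:
        members = rng.random(n) < 0.03
        for gi in np.flatnonzero(members):
            go[gi].add(term)

    host = pd.DataFrame(
        {
            "origin": HOST,
            "pfam": pfam,
            "cog": cog,
            "go": [";".join(sorted(s)) for s in go],
        },
        index=pd.Index(host_ids, name="gene_id"),
    )
    sym = pd.DataFrame(
        {
            "origin": SYMBIONT,
            "pfam": rng.random(len(sym_ids)) < cfg.pfam_rate,
            "cog": "",
            "go": "",
        },
        index=pd.Index(sym_ids, name="gene_id"),
    )
    return pd.concat([host, sym])


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Sample one experiment; identical config implies identical output."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    host_ids = np.array([f"g{i + 1:05d}" for i in range(cfg.n_host_genes)],
                        dtype=object)
    sym_ids = np.array([f"Bpsy{i + 1:05d}" for i in range(cfg.n_symbiont_genes)],
                       dtype=object)

    # --- gene programs -----------------------------------------------------
    m = cfg.cluster_marker_genes
    marker_blocks = [np.arange(c * m, (c + 1) * m) for c in range(cfg.n_clusters)]
    cursor = cfg.n_clusters * m
    immune_idx = np.arange(cursor, cursor + cfg.immune_geneset_size)
    cursor += cfg.immune_geneset_size
    nutrient_idx = np.arange(cursor, cursor + cfg.marker_geneset_size)

    base_log = rng.normal(0.0, 1.0, cfg.n_host_genes)
    # planted effect genes get a moderately expressed baseline so the effect
    # is detectable rather than drowned in zeros
    base_log[immune_idx] = rng.normal(0.5, 0.5, len(immune_idx))
    base_log[nutrient_idx] = rng.normal(0.5, 0.5, len(nutrient_idx))
    weights = np.exp(base_log)

    profiles = np.tile(weights, (cfg.n_clusters, 1))
    for c, block in enumerate(marker_blocks):
        profiles[c, block] *= cfg.cluster_marker_fold
    profiles /= profiles.sum(axis=1, keepdims=True)

    # symbiotic-state variant of the effect cluster's program
    effect_profile = profiles[cfg.effect_cluster_id - 1].copy()
    effect_profile[immune_idx] *= 2.0 ** cfg.immune_lfc
    effect_profile[nutrient_idx] *= 2.0 ** cfg.marker_lfc
    effect_profile /= effect_profile.sum()

    sym_weights = np.exp(rng.normal(0.0, 1.0, cfg.n_symbiont_genes))
    sym_profile = sym_weights / sym_weights.sum()

    # --- cells -------------------------------------------------------------
    props = cfg.proportions()
    state_blocks = []
    for state in (SYM, APO):
        n = cfg.n_cells_per_state
        clusters = rng.choice(
            np.arange(1, cfg.n_clusters + 1), size=n, p=props
        )
        library = rng.lognormal(
            cfg.library_size_log_mean, cfg.library_size_log_sd, n
        )
        hosting = np.zeros(n, dtype=bool)
        if state == SYM and cfg.hosting_cell_fraction > 0:
            in_hc = clusters == cfg.hosting_cluster_id
            hosting = in_hc & (rng.random(n) < cfg.hosting_cell_fraction)
        share = np.full(n, cfg.symbiont_leak)
        if hosting.any():
            share[hosting] = rng.beta(
                cfg.symbiont_read_fraction_alpha,
                cfg.symbiont_read_fraction_beta,
                int(hosting.sum()),
            )
        host_prof = profiles[clusters - 1]
        if state == SYM:
            is_effect = clusters == cfg.effect_cluster_id
            if is_effect.any():
                host_prof = host_prof.copy()
                host_prof[is_effect] = effect_profile
        mu_host = (library * (1.0 - share))[:, None] * host_prof
        mu_sym = (library * share)[:, None] * sym_profile[None, :]
        mu = np.concatenate([mu_host, mu_sym], axis=1)
        lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
        counts = rng.poisson(lam).astype(np.int64)
        state_blocks.append(
            (state, clusters, library, hosting, share, counts)
        )

    counts = np.concatenate([b[5] for b in state_blocks], axis=0)
    state = np.concatenate(
        [np.full(cfg.n_cells_per_state, b[0], dtype=object)
         for b in state_blocks]
    )
    clusters = np.concatenate([b[1] for b in state_blocks])
    library = np.concatenate([b[2] for b in state_blocks])
    hosting = np.concatenate([b[3] for b in state_blocks])
    share = np.concatenate([b[4] for b in state_blocks])

    # --- doublets: sums of two uniformly chosen same-state cells -----------
    n_singlets = counts.shape[0]
    n_doublets = int(round(cfg.doublet_rate * n_singlets))
    doublet_rows = []
    d_state, d_cluster = [], []
    for _ in range(n_doublets):
        s = SYM if rng.random() < 0.5 else APO
        pool = np.flatnonzero(state == s)
        i, j = rng.choice(pool, size=2, replace=False)
        doublet_rows.append(counts[i] + counts[j])
        d_state.append(s)
        d_cluster.append(clusters[i])
    if n_doublets:
        counts = np.concatenate([counts, np.stack(doublet_rows)], axis=0)

    n_total = counts.shape[0]
    barcodes = np.array([_barcode(i) for i in range(n_total)], dtype=object)
    state_all = np.concatenate([state, np.array(d_state, dtype=object)])
    cluster_all = np.concatenate([clusters, np.array(d_cluster, dtype=int)])
    is_doublet = np.zeros(n_total, dtype=bool)
    is_doublet[n_singlets:] = True
    hosting_all = np.concatenate([hosting, np.zeros(n_doublets, dtype=bool)])
    share_all = np.concatenate([share, np.full(n_doublets, np.nan)])
    library_all = np.concatenate([library, np.full(n_doublets, np.nan)])

    gene_ids = np.concatenate([host_ids, sym_ids])
    origin = np.array(
        [HOST] * cfg.n_host_genes + [SYMBIONT] * cfg.n_symbiont_genes,
        dtype=object,
    )
    matrix = CountMatrix(sp.csr_matrix(counts), barcodes, gene_ids, origin)

    cells = pd.DataFrame(
        {"state": state_all, "is_doublet": is_doublet},
        index=pd.Index(barcodes, name="barcode"),
    )
    genes = _gene_annotation(cfg, rng, host_ids, sym_ids, immune_idx,
                             nutrient_idx)

    marker_cluster = np.zeros(cfg.n_host_genes, dtype=int)
    for c, block in enumerate(marker_blocks):
        marker_cluster[block] = c + 1
    state_lfc = np.zeros(cfg.n_host_genes)
    state_lfc[immune_idx] = cfg.immune_lfc
    state_lfc[nutrient_idx] = cfg.marker_lfc
    truth_genes = pd.DataFrame(
        {
            "origin": origin,
            "is_immune": np.concatenate(
                [np.isin(np.arange(cfg.n_host_genes), immune_idx),
                 np.zeros(cfg.n_symbiont_genes, dtype=bool)]
            ),
            "is_nutrient_marker": np.concatenate(
                [np.isin(np.arange(cfg.n_host_genes), nutrient_idx),
                 np.zeros(cfg.n_symbiont_genes, dtype=bool)]
            ),
            "marker_cluster": np.concatenate(
                [marker_cluster, np.zeros(cfg.n_symbiont_genes, dtype=int)]
            ),
            "state_log2fc": np.concatenate(
                [state_lfc, np.zeros(cfg.n_symbiont_genes)]
            ),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth_cells = pd.DataFrame(
        {
            "state": state_all,
            "cluster": cluster_all,
            "is_hosting": hosting_all,
            "is_doublet": is_doublet,
            "symbiont_share": share_all,
            "library_size": library_all,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    truth = GroundTruth(cells=truth_cells, genes=truth_genes, config=cfg)
    return SimulatedDataset(matrix, cells, genes, truth)


def write_fixture(dataset: SimulatedDataset, directory) -> dict[str, Path]:
    """Write a dataset as plain-text files that round-trip losslessly.

    Emits the MTX triplet plus cell metadata, gene annotation, and the two
    ground-truth tables, and a JSON record of the generating configuration.
    """
    if dataset.matrix.n_cells == 0:
        raise ValueError("refusing to write an empty dataset (0 cells)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_matrix(dataset.matrix, directory,
                         features_extra=dataset.genes)
    extra = {
        "cells": directory / "cells.tsv",
        "truth_cells": directory / "truth_cells.tsv",
        "truth_genes": directory / "truth_genes.tsv",
        "config": directory / "sim_config.json",
    }
    dataset.cells.to_csv(extra["cells"], sep="\t")
    dataset.truth.cells.to_csv(extra["truth_cells"], sep="\t")
    dataset.truth.genes.to_csv(extra["truth_genes"], sep="\t")
    cfg = asdict(dataset.truth.config)
    extra["config"].write_text(json.dumps(cfg, sort_keys=True, indent=1) + "\n")
    paths.update(extra)
    return paths


def read_fixture(directory) -> SimulatedDataset:
    """Load a dataset previously written by :func:`write_fixture`."""
    directory = Path(directory)
    matrix = read_matrix(directory / "matrix.mtx", directory / "features.tsv",
                         directory / "barcodes.tsv")
    cells = pd.read_csv(directory / "cells.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(directory / "features.tsv", sep="\t",
                        index_col="gene_id", keep_default_na=False)
    genes["pfam"] = genes["pfam"].astype(str).isin(("True", "1", "true"))
    truth_cells = pd.read_csv(directory / "truth_cells.tsv", sep="\t",
                              index_col=0)
    truth_genes = pd.read_csv(directory / "truth_genes.tsv", sep="\t",
                              index_col=0, keep_default_na=False)
    for col in ("is_immune", "is_nutrient_marker"):
        truth_genes[col] = truth_genes[col].astype(str).isin(
            ("True", "1", "true"))
    truth_cells["is_hosting"] = truth_cells["is_hosting"].astype(bool)
    truth_cells["is_doublet"] = truth_cells["is_doublet"].astype(bool)
    raw = json.loads((directory / "sim_config.json").read_text())
    if raw.get("cluster_proportions") is not None:
        raw["cluster_proportions"] = tuple(raw["cluster_proportions"])
    cfg = SimConfig(**raw)
    truth = GroundTruth(cells=truth_cells, genes=truth_genes, config=cfg)
    return SimulatedDataset(matrix, cells, genes, truth)
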