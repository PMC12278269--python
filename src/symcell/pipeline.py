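"""End-to-end orchestration of the analysis stages from one configuration.

Stage order: load or simulate -> doublet-flag removal -> QC -> symbiont
partitioning -> host-gene embedding and clustering -> marker genes ->
gene-set scoring and GO enrichment -> per-cluster state separation ->
co-expression -> optional cross-species DEO comparison. Every output is a
TSV or JSON file; a manifest records the package version, seed, resolved
parameters, and per-stage row counts, and suffices to re-execute an
identical run. A single global seed fans out to per-stage seeds by stable
hashing of stage names, so adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import logger, stage_seed
from .coexpr import coexpression_score
from .embed import ClusterConfig, cluster_workflow, find_markers, \
    merge_state_split_clusters
from .genesets import GeneSet, cell_geneset_fraction, flag_cells, \
    mwu_go_enrichment
from .io import CountMatrix, read_matrix
from .orthologs import fisher_enrichment, map_orthologs, venn_partition
from .partition import assign_hosting_cluster, classify_hosting, \
    symbiont_fraction
from .qc import QCThresholds, qc_filter, remove_flagged_doublets
from .separation import de_between_states, state_separation_report
from .simulate import IMMUNE_GO_TERMS, SimConfig, generate_dataset, \
    write_fixture


@dataclass(frozen=True)
class Thresholds:
    """The decision thresholds used across stages."""

    symbiont_fraction: float = 0.5
    geneset_fraction: float = 0.045
    pc_alpha: float = 0.05
    de_alpha: float = 0.05
    go_fdr: float = 0.1


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Either ``sim`` is set (synthetic mode) or ``input_dir`` points at an
    MTX triplet plus ``cells.tsv`` metadata written in the fixture layout.
    """

    sim: SimConfig | None = None
    input_dir: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    subset_clustering: ClusterConfig = field(
        default_factory=lambda: ClusterConfig(resolution=0.4)
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    immune_terms: tuple[str, ...] = IMMUNE_GO_TERMS
    coexpression_genes: tuple[str, ...] = ()
    ortholog_table: str | None = None
    deo_term_map: str | None = None
    deo_genes_a: tuple[str, ...] = ()
    min_cluster_cells: int = 60
    min_cells_per_state: int = 3
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            sim = dict(kwargs["sim"])
            if sim.get("cluster_proportions") is not None:
                sim["cluster_proportions"] = tuple(sim["cluster_proportions"])
            kwargs["sim"] = SimConfig(**sim)
        if "qc" in kwargs:
            kwargs["qc"] = QCThresholds(**kwargs["qc"])
        if "clustering" in kwargs:
            kwargs["clustering"] = ClusterConfig(**kwargs["clustering"])
        if "subset_clustering" in kwargs:
            kwargs["subset_clustering"] = ClusterConfig(
                **kwargs["subset_clustering"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        for key in ("immune_terms", "coexpression_genes", "deo_genes_a"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> int:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return len(df)


def run(config: RunConfig, out_dir) -> Path:
    """Execute all stages; returns the run directory.

    A stage failure aborts the run with the stage name and cause; partial
    outputs are retained next to a ``FAILED`` marker file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _jsonable(config),
        "stages": {},
    }
    stage = "setup"
    try:
        # -- load or simulate ---------------------------------------------
        stage = "input"
        if config.sim is not None:
            sim_cfg = dataclasses.replace(
                config.sim, seed=stage_seed(config.seed, "simulate")
            )
            dataset = generate_dataset(sim_cfg)
            write_fixture(dataset, out / "fixture")
            m, cells, gene_ann = dataset.matrix, dataset.cells, dataset.genes
            truth = dataset.truth
        elif config.input_dir is not None:
            d = Path(config.input_dir)
            m = read_matrix(d / "matrix.mtx", d / "features.tsv",
                            d / "barcodes.tsv")
            cells = pd.read_csv(d / "cells.tsv", sep="\t", index_col=0)
            gene_ann = pd.read_csv(d / "features.tsv", sep="\t",
                                   index_col="gene_id", keep_default_na=False)
            if "pfam" in gene_ann.columns:
                gene_ann["pfam"] = gene_ann["pfam"].astype(str).isin(
                    ("True", "1", "true"))
            truth = None
        else:
            raise ValueError("config needs either 'sim' or 'input_dir'")
        manifest["stages"]["input"] = {"n_cells": m.n_cells,
                                       "n_genes": m.n_genes}

        # -- doublets and QC ----------------------------------------------
        stage = "qc"
        if "is_doublet" in cells.columns:
            flags = cells["is_doublet"].reindex(m.cell_ids).fillna(False)
            m = remove_flagged_doublets(m, flags.to_numpy(dtype=bool))
        m, qc_report = qc_filter(m, config.qc)
        states = cells["state"].reindex(m.cell_ids)
        manifest["stages"]["qc"] = dataclasses.asdict(qc_report)

        # -- symbiont partition -------------------------------------------
        stage = "partition"
        fractions = symbiont_fraction(m)
        hosting = classify_hosting(fractions,
                                   config.thresholds.symbiont_fraction)
        manifest["stages"]["partition"] = {
            "n_hosting": int(hosting.sum()),
        }

        # -- embedding and clustering on host genes ------------------------
        stage = "cluster"
        host = m.host_view()
        norm, emb, labels = cluster_workflow(
            host, config.clustering, seed=stage_seed(config.seed, "cluster")
        )
        labels = merge_state_split_clusters(emb, labels, states.to_numpy())
        hosting_cluster = assign_hosting_cluster(hosting, labels)
        part_df = pd.DataFrame(
            {
                "symbiont_fraction": fractions,
                "is_hosting": hosting,
                "cluster": labels,
            },
            index=pd.Index(m.cell_ids, name="barcode"),
        )
        part_df["state"] = states.to_numpy()
        _write_tsv(part_df, out / "cells.tsv")
        manifest["stages"]["cluster"] = {
            "n_clusters": int(labels.max()),
            "hosting_cluster": hosting_cluster.cluster_id,
            "n_hosting_in_cluster": hosting_cluster.n_hosting_in_cluster,
            "n_hosting_total": hosting_cluster.n_hosting_total,
        }

        # -- cluster markers ----------------------------------------------
        stage = "markers"
        markers = find_markers(norm, labels)
        marker_rows = []
        for c, df in sorted(markers.items()):
            top = df.head(10).assign(cluster=c)
            marker_rows.append(top)
        if marker_rows:
            _write_tsv(pd.concat(marker_rows, ignore_index=True),
                       out / "markers.tsv", index=False)
        manifest["stages"]["markers"] = {"n_clusters_tested": len(markers)}

        # -- gene-set scoring and GO enrichment ----------------------------
        stage = "genesets"
        go_col = gene_ann["go"].fillna("") if "go" in gene_ann.columns else None
        enrichment_rows = 0
        if go_col is not None:
            immune_genes = tuple(
                g for g, terms in go_col.items()
                if set(str(terms).split(";")) & set(config.immune_terms)
            )
            if immune_genes:
                immune_set = GeneSet("immune", immune_genes,
                                     tuple(config.immune_terms))
                set_fraction = cell_geneset_fraction(m, immune_set)
                flagged = flag_cells(set_fraction,
                                     config.thresholds.geneset_fraction)
                gs_df = pd.DataFrame(
                    {"fraction_immune": set_fraction, "flagged": flagged}
                )
                _write_tsv(gs_df, out / "geneset_cells.tsv")
            # whole-dataset DE supplies the per-gene enrichment score
            de_all = de_between_states(host, states.to_numpy())
            de_all_idx = de_all.set_index("gene_id")
            score = (-np.log10(np.maximum(de_all_idx["p"], 1e-300))
                     * np.sign(de_all_idx["log2fc"]))
            term_map = (
                go_col.str.split(";").explode().rename("term").reset_index()
            )
            term_map = term_map[term_map["term"] != ""]
            term_map = term_map[term_map["gene_id"].isin(score.index)]
            if term_map["term"].nunique() >= 2:
                enrichment = mwu_go_enrichment(
                    score, term_map, fdr=config.thresholds.go_fdr
                )
                enrichment_rows = _write_tsv(
                    enrichment, out / "go_enrichment.tsv", index=False
                )
        manifest["stages"]["genesets"] = {"n_terms": enrichment_rows}

        # -- per-cluster state separation ----------------------------------
        stage = "state_separation"
        summaries = []
        state_arr = states.to_numpy()
        for c in range(1, int(labels.max()) + 1):
            mask = labels == c
            by_state = pd.Series(state_arr[mask]).value_counts()
            if (mask.sum() < max(config.min_cluster_cells,
                                 2 * config.subset_clustering.n_neighbors)
                    or len(by_state) < 2
                    or by_state.min() < config.min_cells_per_state):
                continue
            report = state_separation_report(
                host, mask, state_arr, gene_ann,
                cfg=config.subset_clustering,
                seed=stage_seed(config.seed, f"separation:{c}"),
                cluster_id=c,
                alpha=config.thresholds.pc_alpha,
                de_alpha=config.thresholds.de_alpha,
                immune_terms=config.immune_terms,
            )
            _write_tsv(report.drivers, out / f"drivers_cluster{c}.tsv")
            _write_tsv(report.pc_stats, out / f"pc_stats_cluster{c}.tsv",
                       index=False)
            summaries.append(report.summary)
        (out / "state_separation.json").write_text(
            json.dumps(summaries, sort_keys=True, indent=1) + "\n"
        )
        manifest["stages"]["state_separation"] = {
            "n_clusters_analyzed": len(summaries),
            "n_flagged": sum(
                1 for s in summaries
                if s["n_significant_pcs"] >= 1 and s["n_de_immune_drivers"] >= 5
            ),
        }

        # -- co-expression --------------------------------------------------
        stage = "coexpression"
        trio = list(config.coexpression_genes)
        if not trio and truth is not None:
            trio = list(truth.nutrient_marker_genes()[:3])
        trio = [g for g in trio if g in set(norm.gene_ids)]
        if trio:
            coex = coexpression_score(norm, trio)
            _write_tsv(coex, out / "coexpression.tsv")
            manifest["stages"]["coexpression"] = {"genes": trio}
        else:
            manifest["stages"]["coexpression"] = {"skipped": True}

        # -- cross-species DEO comparison -----------------------------------
        stage = "cross_species"
        if config.ortholog_table is not None:
            table = pd.read_csv(config.ortholog_table, sep="\t", dtype=str)
            de_all = de_between_states(host, state_arr)
            de_b = de_all.loc[de_all["padj"] < config.thresholds.de_alpha,
                              "gene_id"]
            og_a = map_orthologs(list(config.deo_genes_a), table, "a")
            og_b = map_orthologs(list(de_b), table, "b")
            background = set(table["orthogroup"])
            part = venn_partition(og_a, og_b, background)
            result = {"sizes": part.sizes()}
            if config.deo_term_map is not None:
                tmap = pd.read_csv(config.deo_term_map, sep="\t", dtype=str)
                for name, group in (("shared", part.shared),
                                    ("unique_a", part.unique_a),
                                    ("unique_b", part.unique_b)):
                    enr = fisher_enrichment(group, background, tmap,
                                            fdr=config.thresholds.go_fdr)
                    _write_tsv(enr, out / f"deo_enrichment_{name}.tsv",
                               index=False)
            (out / "deo_partition.json").write_text(
                json.dumps(result, sort_keys=True, indent=1) + "\n"
            )
            manifest["stages"]["cross_species"] = result["sizes"]
        else:
            logger.info('{"event": "cross_species_skipped"}')
            manifest["stages"]["cross_species"] = {"skipped": True}

        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1, default=str) + "\n"
        )
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc!r}\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj
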