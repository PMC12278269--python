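"""Cross-species differentially-expressed-ortholog (DEO) comparison.

Two species' differential-expression gene lists are mapped through an
ortholog table (gene_a, orthogroup, gene_b) into orthogroup space,
partitioned into shared / species-unique sets, and each set is tested for
GO-term over-representation with two-sided Fisher exact tests over a
common orthogroup background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import bh_adjust, logger

ORTHOLOG_COLUMNS = ("gene_a", "orthogroup", "gene_b")


def validate_ortholog_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (gene_a, orthogroup, gene_b) table invariants.

    Rows may be many-to-many, but a given gene may belong to only one
    orthogroup, and no identifier may be empty.
    """
    if table.empty:
        raise ValueError("ortholog table is empty")
    for col in ORTHOLOG_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"ortholog table is missing column '{col}'")
        if (table[col].astype(str).str.len() == 0).any():
            raise ValueError(f"ortholog table has empty ids in '{col}'")
    for col in ("gene_a", "gene_b"):
        per_gene = table.groupby(col)["orthogroup"].nunique()
        multi = per_gene[per_gene > 1]
        if len(multi):
            raise ValueError(
                f"{col} genes mapped to multiple orthogroups: "
                f"{multi.index.tolist()[:5]}"
            )
    return table


def map_orthologs(de_genes, table: pd.DataFrame, species: str) -> set[str]:
    """Orthogroups hit by at least one DE gene of the given species.

    ``species`` selects the ``gene_a`` or ``gene_b`` column ("a"/"b").
    Genes without an orthogroup are dropped; the dropped count is logged.
    """
    validate_ortholog_table(table)
    species = species.lower()
    if species not in ("a", "b"):
        raise ValueError(f"species must be 'a' or 'b', got {species!r}")
    col = f"gene_{species}"
    de_genes = list(de_genes)
    mapping = table.set_index(col)["orthogroup"]
    mapping = mapping[~mapping.index.duplicated()]
    hits = mapping.reindex(de_genes)
    n_dropped = int(hits.isna().sum())
    if n_dropped:
        logger.info(
            '{"event": "map_orthologs", "species": "%s", "n_dropped": %d}'
            % (species, n_dropped)
        )
    return set(hits.dropna())


@dataclass(frozen=True)
class DEOPartition:
    """Venn partition of two species' DEO sets over a shared background."""

    shared: frozenset
    unique_a: frozenset
    unique_b: frozenset
    background: frozenset

    def sizes(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
            "background": len(self.background),
        }


def venn_partition(set_a, set_b, background) -> DEOPartition:
    """Split two DEO sets into shared and species-unique orthogroups."""
    a, b, bg = set(set_a), set(set_b), set(background)
    outside = (a | b) - bg
    if outside:
        raise ValueError(
            f"elements outside the background: {sorted(outside)[:5]}"
        )
    return DEOPartition(
        shared=frozenset(a & b),
        unique_a=frozenset(a - b),
        unique_b=frozenset(b - a),
        background=frozenset(bg),
    )


def fisher_enrichment(group, background, term_map: pd.DataFrame,
                      min_term_size: int = 5, fdr: float = 0.1
                      ) -> pd.DataFrame:
    """Per-term two-sided Fisher exact over-representation.

    For each term the 2x2 table crosses group membership with term
    membership over the background; the two-sided p sums hypergeometric
    outcomes no more probable than the observed table. BH adjustment runs
    across terms. ``term_map`` has columns ``element`` (orthogroup or
    gene) and ``term``.
    """
    group, bg = set(group), set(background)
    if not bg:
        raise ValueError("background is empty")
    if not group <= bg:
        raise ValueError("group must be a subset of the background")
    tm = term_map[["element", "term"]]
    tm = tm[tm["element"].isin(bg)]

    rows = []
    for term, members in tm.groupby("term")["element"]:
        term_set = set(members)
        if len(term_set) < min_term_size:
            continue
        a = len(group & term_set)
        b = len(group) - a
        c = len(term_set) - a
        d = len(bg) - a - b - c
        odds, p = scipy.stats.fisher_exact([[a, b], [c, d]],
                                           alternative="two-sided")
        rows.append(
            {
                "term": term,
                "n_term": len(term_set),
                "n_in_group": a,
                "odds_ratio": float(odds),
                "p": float(p),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "n_term", "n_in_group", "odds_ratio", "p",
                     "fdr", "significant"]
        )
    out = pd.DataFrame(rows).sort_values("term", ignore_index=True)
    out["fdr"] = bh_adjust(out["p"])
    out["significant"] = out["fdr"] < fdr
    return out.sort_values(["p", "term"], ignore_index=True, kind="mergesort")
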