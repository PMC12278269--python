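"""Gene-set read-fraction scoring and rank-based GO enrichment.

Two complementary tools: a per-cell score that asks what fraction of a
cell's sequencing budget went to a set of genes (e.g. immune-pathway GO
terms), with strict-threshold flagging; and a Mann-Whitney U enrichment
that asks, for each GO term, whether the per-gene scores of its members
are shifted relative to all other genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import bh_adjust
from .io import CountMatrix

DEFAULT_FLAG_THRESHOLD = 0.045


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: tuple[str, ...]
    source_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")


def cell_geneset_fraction(m: CountMatrix, geneset: GeneSet,
                          restrict_origin: str | None = "host") -> pd.Series:
    """Per-cell fraction of counts falling in the gene set.

    By default both numerator and denominator are restricted to host-origin
    genes (scores are computed after the matrix has conceptually been
    subset to the host genome); pass ``restrict_origin=None`` to use all
    genes, in which case fractions over a partition of the gene universe
    sum to one per cell.
    """
    if restrict_origin is not None:
        m = m.subset_genes(m.gene_origin == restrict_origin)
    in_set = np.isin(m.gene_ids, np.asarray(geneset.gene_ids, dtype=object))
    if not in_set.any():
        raise ValueError(
            f"gene set {geneset.name!r} has no genes in the matrix"
        )
    totals = m.cell_totals().astype(float)
    if (totals == 0).any():
        bad = m.cell_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts")
    set_counts = np.asarray(m.counts[:, in_set].sum(axis=1)).ravel()
    return pd.Series(set_counts / totals, index=m.cell_ids,
                     name=f"fraction_{geneset.name}")


def flag_cells(fractions: pd.Series,
               threshold: float = DEFAULT_FLAG_THRESHOLD) -> pd.Series:
    """Strict "over threshold" flag: exactly 4.5% is not flagged."""
    fr = np.asarray(fractions, dtype=float)
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    return pd.Series(fr > threshold, index=fractions.index, name="flagged")


def mwu_go_enrichment(gene_scores: pd.Series, term_map: pd.DataFrame,
                      min_term_size: int = 5, fdr: float = 0.1
                      ) -> pd.DataFrame:
    """Mann-Whitney U enrichment of per-gene scores over GO terms.

    For each term, member-gene scores are compared against all non-member
    scores with a two-sided U test (normal approximation with tie
    correction); p-values are BH-adjusted across terms, and the direction
    ("over"/"under") comes from the sign of the median difference. Terms
    with fewer than ``min_term_size`` scored members are dropped; a term
    covering the whole gene universe is rejected. The test depends only on
    ranks, so any strictly monotone transform of the scores leaves the
    result unchanged.

    Parameters
    ----------
    gene_scores
        Finite per-gene scores indexed by gene id, typically the signed
        significance ``-log10(p) * sign(log2FC)`` of a state contrast.
    term_map
        Two columns, ``gene_id`` and ``term``; one row per membership.
    """
    scores = pd.Series(gene_scores).astype(float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("gene scores must be finite")
    tm = term_map[["gene_id", "term"]]
    tm = tm[tm["gene_id"].isin(scores.index)]
    values = scores.to_numpy()
    positions = pd.Series(np.arange(len(scores)), index=scores.index)

    rows = []
    for term, members in tm.groupby("term")["gene_id"]:
        idx = positions[members.unique()].to_numpy()
        if len(idx) < min_term_size:
            continue
        if len(idx) >= len(scores):
            raise ValueError(
                f"term {term!r} covers the entire gene universe"
            )
        in_mask = np.zeros(len(scores), dtype=bool)
        in_mask[idx] = True
        inside, outside = values[in_mask], values[~in_mask]
        res = scipy.stats.mannwhitneyu(
            inside, outside, alternative="two-sided", method="asymptotic"
        )
        diff = np.median(inside) - np.median(outside)
        rows.append(
            {
                "term": term,
                "n_genes": len(idx),
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "direction": "over" if diff >= 0 else "under",
            }
        )
    if len(rows) < 2:
        raise ValueError("need at least 2 terms after the size filter")
    out = pd.DataFrame(rows).sort_values("term", ignore_index=True)
    out["fdr"] = bh_adjust(out["p"])
    out["significant"] = out["fdr"] < fdr
    return out.sort_values(["p", "term"], ignore_index=True, kind="mergesort")
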