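"""Per-cell symbiont read fractions and algal-hosting cell classification.

A cell aligned against the concatenated host+symbiont genomes is called
*algal-hosting* when strictly more than half of its total counts come from
symbiont-genome genes. Fractions are computed on the full dual-genome
matrix, before any subsetting to host genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SYMBIONT, CountMatrix

DEFAULT_HOSTING_THRESHOLD = 0.5


def symbiont_fraction(m: CountMatrix) -> pd.Series:
    """Fraction of each cell's counts assigned to symbiont-origin genes.

    Raises if any cell has zero total counts (the fraction is undefined);
    the error names the offending barcode.
    """
    totals = m.cell_totals()
    if (totals == 0).any():
        bad = m.cell_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts")
    sym_counts = np.asarray(
        m.counts[:, m.gene_origin == SYMBIONT].sum(axis=1)
    ).ravel()
    return pd.Series(sym_counts / totals, index=m.cell_ids,
                     name="symbiont_fraction")


def classify_hosting(fractions: pd.Series,
                     threshold: float = DEFAULT_HOSTING_THRESHOLD) -> pd.Series:
    """Strictly-greater-than threshold call: "over 50%" means > 0.5."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    fr = np.asarray(fractions, dtype=float)
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    return pd.Series(fr > threshold, index=fractions.index, name="is_hosting")


@dataclass(frozen=True)
class HostingClusterResult:
    """Which cluster concentrates the hosting cells, with counts.

    ``cluster_id`` is None when there are no hosting cells at all; ``tied``
    marks a tie broken toward the lower cluster label.
    """

    cluster_id: object
    n_hosting_in_cluster: int
    n_hosting_total: int
    tied: bool = False


def assign_hosting_cluster(calls: pd.Series, cluster_labels) -> HostingClusterResult:
    """Locate the cluster containing the most hosting cells.

    ``calls`` is the boolean output of :func:`classify_hosting`;
    ``cluster_labels`` aligns with it positionally or by index.
    """
    calls = pd.Series(calls)
    labels = pd.Series(np.asarray(cluster_labels), index=calls.index)
    hosting_labels = labels[calls.to_numpy(dtype=bool)]
    n_total = int(len(hosting_labels))
    if n_total == 0:
        return HostingClusterResult(None, 0, 0)
    counts = hosting_labels.value_counts()
    best = counts[counts == counts.max()]
    winner = sorted(best.index)[0]
    return HostingClusterResult(
        cluster_id=winner,
        n_hosting_in_cluster=int(counts.max()),
        n_hosting_total=n_total,
        tied=len(best) > 1,
    )
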