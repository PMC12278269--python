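"""Cell and gene quality-control filtering and doublet-flag removal.

The filters mirror the common droplet scRNA-seq cleanup: genes detected in
fewer than 3 cells are discarded, then cells expressing fewer than 200 or
more than 3,000 genes are discarded. "Expressed"/"detected" means a count
of at least 1. Detected-gene numbers for the cell filter are computed on
host and symbiont genes jointly, because filtering happens before the
matrix is subset to host genes. Doublet detection itself is out of scope:
flags from an external caller are consumed and flagged cells dropped.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._utils import logger
from .io import CountMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Filtering thresholds; defaults are the standard droplet values."""

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 3000

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError(
                "min_genes_per_cell must be < max_genes_per_cell "
                f"({self.min_genes_per_cell} >= {self.max_genes_per_cell})"
            )
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be nonnegative")


@dataclass
class QCReport:
    """Counts of what the filter removed, emitted as a JSON line."""

    n_genes_in: int
    n_cells_in: int
    n_genes_removed: int
    n_cells_removed_low: int
    n_cells_removed_high: int
    n_genes_out: int
    n_cells_out: int

    def to_json(self) -> str:
        return json.dumps({"event": "qc_filter", **asdict(self)}, sort_keys=True)


def qc_filter(m: CountMatrix, thresholds: QCThresholds | None = None
              ) -> tuple[CountMatrix, QCReport]:
    """Apply the gene filter, then the cell filter.

    Returns the filtered matrix and a report of removed counts. Retained
    counts are never altered, only membership changes. Raises if every cell
    would be removed.
    """
    t = thresholds or QCThresholds()
    detected = m.counts.copy()
    detected.data = np.ones_like(detected.data)

    cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= t.min_cells_per_gene
    m_genes = m.subset_genes(keep_genes)

    genes_per_cell = np.asarray(
        (m_genes.counts > 0).sum(axis=1)
    ).ravel()
    keep_low = genes_per_cell >= t.min_genes_per_cell
    keep_high = genes_per_cell <= t.max_genes_per_cell
    keep_cells = keep_low & keep_high
    if not keep_cells.any():
        raise ValueError(
            "QC filtering would remove every cell "
            f"(thresholds {t.min_genes_per_cell}-{t.max_genes_per_cell} "
            "detected genes)"
        )
    out = m_genes.subset_cells(keep_cells)
    report = QCReport(
        n_genes_in=m.n_genes,
        n_cells_in=m.n_cells,
        n_genes_removed=int((~keep_genes).sum()),
        n_cells_removed_low=int((~keep_low).sum()),
        n_cells_removed_high=int((~keep_high).sum()),
        n_genes_out=out.n_genes,
        n_cells_out=out.n_cells,
    )
    logger.info(report.to_json())
    return out, report


def remove_flagged_doublets(m: CountMatrix, flags) -> CountMatrix:
    """Drop cells whose doublet flag is True, preserving cell order."""
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != m.n_cells:
        raise ValueError(
            f"{len(flags)} doublet flags for {m.n_cells} cells"
        )
    return m.subset_cells(~flags)
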