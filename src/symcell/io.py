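"""Sparse count-matrix container and 10x-style MTX triplet I/O.

A dataset is three text files: a MatrixMarket coordinate matrix written
features x barcodes (the 10x convention, 1-based indices), a barcodes TSV,
and a features TSV whose ``origin`` column assigns every gene to the host
or the symbiont genome. Counts are stored in memory as cells x genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

HOST = "host"
SYMBIONT = "symbiont"

#: columns the features table must carry; extra annotation columns are kept.
REQUIRED_FEATURE_COLUMNS = ("gene_id", "origin")


@dataclass
class CountMatrix:
    """Cells x genes nonnegative integer counts with genome-of-origin labels.

    Parameters
    ----------
    counts
        Sparse ``cells x genes`` matrix of nonnegative integers.
    cell_ids
        Barcode strings, one per row; duplicates are rejected.
    gene_ids
        Gene identifiers, one per column.
    gene_origin
        Per-gene label, ``"host"`` or ``"symbiont"``.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_origin: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_origin = np.asarray(self.gene_origin, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} barcodes for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes or len(self.gene_origin) != n_genes:
            raise ValueError("gene_ids/gene_origin length does not match matrix")
        if len(set(self.cell_ids)) != n_cells:
            dup = pd.Series(self.cell_ids).value_counts()
            dup = dup[dup > 1].index.tolist()
            raise ValueError(f"duplicated barcodes: {dup[:5]}")
        bad = set(self.gene_origin) - {HOST, SYMBIONT}
        if bad:
            raise ValueError(f"unknown gene origins: {sorted(bad)}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, index) -> "CountMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            self.counts[index],
            self.cell_ids[index],
            self.gene_ids,
            self.gene_origin,
        )

    def subset_genes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            self.counts[:, index],
            self.cell_ids,
            self.gene_ids[index],
            self.gene_origin[index],
        )

    def host_view(self) -> "CountMatrix":
        """Subset to host-genome genes (the clustering universe)."""
        return self.subset_genes(self.gene_origin == HOST)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def read_matrix(mtx_path, features_path, barcodes_path) -> CountMatrix:
    """Read a features x barcodes MTX triplet into a cells x genes matrix.

    The features TSV must have a header with at least ``gene_id`` and
    ``origin`` columns; any further columns (GO terms, Pfam flags, ...) are
    ignored here and consumed by the annotation loaders.
    """
    mtx_path, features_path, barcodes_path = (
        Path(mtx_path), Path(features_path), Path(barcodes_path)
    )
    mat = scipy.io.mmread(str(mtx_path))
    data = mat.data if sp.issparse(mat) else np.asarray(mat).ravel()
    if data.size and not np.all(np.equal(np.mod(data, 1), 0)):
        raise ValueError(f"{mtx_path} contains non-integer values")
    counts = sp.csr_matrix(mat.T.astype(np.int64))  # -> cells x genes

    features = pd.read_csv(features_path, sep="\t", dtype=str)
    for col in REQUIRED_FEATURE_COLUMNS:
        if col not in features.columns:
            raise ValueError(
                f"features file {features_path} is missing required column "
                f"'{col}'"
            )
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)

    if counts.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix is {mat.shape[0]} features x {mat.shape[1]} barcodes but "
            f"features file has {len(features)} rows and barcodes file "
            f"{len(barcodes)} rows"
        )
    return CountMatrix(
        counts,
        barcodes.to_numpy(dtype=object),
        features["gene_id"].to_numpy(dtype=object),
        features["origin"].to_numpy(dtype=object),
    )


def write_matrix(m: CountMatrix, directory,
                 features_extra: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the MTX + features + barcodes triplet; returns the paths.

    ``features_extra`` (indexed by gene_id) adds annotation columns to the
    features TSV, e.g. Pfam flags and GO terms from a gene annotation table.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "features": directory / "features.tsv",
        "barcodes": directory / "barcodes.tsv",
    }
    scipy.io.mmwrite(
        str(paths["matrix"]), sp.coo_matrix(m.counts.T), field="integer"
    )
    features = pd.DataFrame({"gene_id": m.gene_ids, "origin": m.gene_origin})
    if features_extra is not None:
        extra = features_extra.reindex(features["gene_id"])
        for col in extra.columns:
            if col not in features.columns:
                features[col] = extra[col].to_numpy()
    features.to_csv(paths["features"], sep="\t", index=False)
    pd.Series(m.cell_ids).to_csv(
        paths["barcodes"], sep="\t", index=False, header=False
    )
    return paths
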