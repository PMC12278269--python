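"""Marker-gene co-expression scoring with a fixed per-cell maximum.

Each gene's per-cell normalized expression is rescaled so its maximum
across cells equals a cap (10 by default), and a joint co-expression
score summarizes a small marker set per cell. The joint score is the
minimum of the scaled values (a cell only scores high when every marker
is high); the mean is emitted alongside as a softer alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .embed import NormalizedMatrix


def scale_max(values, cap: float = 10.0) -> np.ndarray:
    """Rescale nonnegative values so the maximum equals ``cap``.

    An all-zero vector stays all zeros (no division is attempted). The
    operation is idempotent on its own output.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("values must be nonnegative")
    vmax = v.max() if v.size else 0.0
    if vmax == 0:
        return np.zeros_like(v)
    return v * (cap / vmax)


def coexpression_score(normalized: NormalizedMatrix, genes,
                       cap: float = 10.0) -> pd.DataFrame:
    """Per-cell scaled expression and joint co-expression of a gene set.

    Returns one row per cell with the capped per-gene values, the joint
    minimum (invariant to gene order) and the joint mean. Missing genes
    raise a KeyError listing the absent ids.
    """
    genes = list(genes)
    idx = pd.Index(normalized.gene_ids).get_indexer(genes)
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"genes absent from the matrix: {missing}")
    scaled = np.column_stack(
        [scale_max(normalized.values[:, i], cap) for i in idx]
    )
    out = pd.DataFrame(
        scaled, columns=[f"scaled_{g}" for g in genes],
        index=pd.Index(normalized.cell_ids, name="barcode"),
    )
    out["joint_min"] = scaled.min(axis=1)
    out["joint_mean"] = scaled.mean(axis=1)
    return out
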