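"""Shared small helpers: seeding, BH adjustment, logging."""

from __future__ import annotations

import hashlib
import logging

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("symcell")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global seed by stable hashing.

    Adding a new stage never perturbs the streams of existing stages, and
    the result is platform-independent and below 2**31.
    """
    digest = hashlib.blake2s(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
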