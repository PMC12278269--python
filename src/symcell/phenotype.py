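"""Phenotype metrics: absorptance spectra, symbiont densities, rank tests.

Small, exactly specified computations around the organismal measurements:
absorptance from reflectance (A = 1 - R, with the chlorophyll-a peak read
at 675 nm), surface-area-normalized symbiont density fold change between
states, and the Kruskal-Wallis rank-sum comparison used when normality
fails.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

PAR_RANGE = (400.0, 700.0)
CHL_A_PEAK_NM = 675.0


def _validate_spectrum(spectrum: pd.DataFrame) -> pd.DataFrame:
    for col in ("wavelength", "reflectance"):
        if col not in spectrum.columns:
            raise ValueError(f"spectrum is missing column '{col}'")
    wl = spectrum["wavelength"].to_numpy(dtype=float)
    r = spectrum["reflectance"].to_numpy(dtype=float)
    if not (np.diff(wl) > 0).all():
        raise ValueError("wavelengths must be strictly increasing")
    if ((r < 0) | (r > 1)).any():
        raise ValueError("reflectance values must lie in [0, 1]")
    return spectrum


def absorptance(spectrum: pd.DataFrame) -> pd.DataFrame:
    """Elementwise absorptance A = 1 - R over the measured wavelengths."""
    _validate_spectrum(spectrum)
    out = spectrum[["wavelength"]].copy()
    out["absorptance"] = 1.0 - spectrum["reflectance"].to_numpy(dtype=float)
    return out


def a675(spectrum: pd.DataFrame) -> float:
    """Chlorophyll-a peak absorptance, 1 - R at the wavelength nearest 675 nm."""
    _validate_spectrum(spectrum)
    wl = spectrum["wavelength"].to_numpy(dtype=float)
    nearest = int(np.argmin(np.abs(wl - CHL_A_PEAK_NM)))
    return float(1.0 - spectrum["reflectance"].to_numpy(dtype=float)[nearest])


def par_mean_reflectance(spectrum: pd.DataFrame) -> float:
    """Unweighted mean reflectance over the PAR region (400-700 nm)."""
    _validate_spectrum(spectrum)
    wl = spectrum["wavelength"].to_numpy(dtype=float)
    mask = (wl >= PAR_RANGE[0]) & (wl <= PAR_RANGE[1])
    if not mask.any():
        raise ValueError("no samples inside the PAR region (400-700 nm)")
    return float(spectrum["reflectance"].to_numpy(dtype=float)[mask].mean())


def density_fold_change(mean_sym: float, mean_apo: float) -> float:
    """Ratio of mean symbiont densities (cells/cm^2), symbiotic over apo."""
    if mean_apo <= 0:
        raise ValueError("aposymbiotic mean density must be positive")
    return float(mean_sym) / float(mean_apo)


def rank_sum_compare(group_a, group_b) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p for two groups.

    A rank-based test is used because symbiont-density replicates are
    small and typically violate normality. The statistic depends only on
    ranks, so it is invariant to strictly monotone transforms.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if np.unique(np.concatenate([a, b])).size == 1:
        raise ValueError("all values are tied across both groups")
    h, p = scipy.stats.kruskal(a, b)
    return float(h), float(p)
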