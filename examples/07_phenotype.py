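"""Phenotype metrics: absorptance spectra and symbiont density contrast.

Absorptance is A = 1 - R per wavelength, with the chlorophyll-a peak
read at 675 nm; symbiont densities (cells per cm^2 of skeletal surface)
are compared as a fold change and with the Kruskal-Wallis rank-sum test.
"""

import numpy as np
import pandas as pd

from symcell import (a675, absorptance, density_fold_change,
                     par_mean_reflectance, rank_sum_compare)

# a stylized symbiotic-fragment reflectance spectrum: low reflectance
# overall (pigmented tissue) with a chlorophyll-a absorption dip at 675 nm
wl = np.arange(400, 751, 5)
r = 0.25 - 0.10 * np.exp(-((wl - 675.0) ** 2) / (2 * 15.0**2))
spectrum = pd.DataFrame({"wavelength": wl, "reflectance": r})

print(f"PAR-mean reflectance: {100 * par_mean_reflectance(spectrum):.1f}%")
print(f"A675 (chlorophyll-a peak absorptance): {100 * a675(spectrum):.1f}%")
print(f"max absorptance: {absorptance(spectrum)['absorptance'].max():.3f}")

# density contrast between states, ten fragments each
rng = np.random.default_rng(0)
sym = rng.normal(13_678, 6_204, 10).clip(min=100)
apo = np.abs(rng.normal(30, 43, 10))
fold = density_fold_change(sym.mean(), apo.mean())
h, p = rank_sum_compare(sym, apo)
print(f"\nsymbiont density fold change (sym/apo): {fold:.0f}")
print(f"Kruskal-Wallis H = {h:.2f}, p = {p:.2e}")
# A several-hundred-fold density difference with a tiny rank-sum p is
# the signature of a successful menthol-bleaching contrast.
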