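"""Generate a synthetic water ensemble and inspect its density expansion.

Builds 40 thermally spread conformers of the 3-atom water surrogate,
projects each bond-aware density onto the orthonormal Fourier basis, and
checks that the coefficient vectors still integrate to the 8 valence
electrons — the constant basis function alone carries the particle number.
"""

import numpy as np

import densfunc as df
from densfunc.basis import DensityCoefficients

water = df.toy_water()
dataset = df.make_dataset(water, n=40, density_mode="bonded", seed=1)

counts = [
    df.integrate_density(DensityCoefficients(u, dataset.basis))
    for u in dataset.coefficients
]
print(f"records:            {len(dataset)}")
print(f"basis functions:    {dataset.basis.size} "
      f"({dataset.basis.per_dim} per dimension)")
print(f"electron count:     {np.mean(counts):.4f} +/- {np.std(counts):.1e} "
      "(target 8 valence electrons)")
print(f"energy span (low):  {dataset.e_low.max():.2f} kcal/mol above the minimum")
print(f"mean |high - low|:  {np.abs(dataset.delta).mean():.2f} kcal/mol "
      "(the correction a Delta map must learn)")
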