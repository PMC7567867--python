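"""Learn densities from potentials, then energies from densities.

Fits the Hohenberg-Kohn map (Gaussian nuclear potential -> density
coefficients, one kernel regression per coefficient against a shared Gram
matrix) on 50 water conformers, then compares two routes to high-level
energies on held-out geometries:

* a direct map trained on 50 high-level labels, and
* a Delta-correction map trained on only 10 high-minus-low differences,
  added onto the cheap low-level energy.

The correction surface is far smoother than the total energy surface, so
the 10-sample Delta route competes with (here: beats) the 50-sample direct
route — the economics that make delta learning attractive when high-level
labels are expensive.
"""

import numpy as np

import densfunc as df
from densfunc.krr import KernelSpec, kmeans_select, predict_krr
from densfunc.maps import fit_hk_map_from_dataset, predict_density_from_descriptor
from densfunc.protocols import cv_energy_map, median_heuristic_sigma

water = df.toy_water()
dataset = df.make_dataset(water, n=102, density_mode="bonded", seed=3)
pool, test = np.arange(50), np.arange(50, 102)

hk = fit_hk_map_from_dataset(
    dataset.subset(pool),
    KernelSpec(median_heuristic_sigma(dataset.descriptors[pool])),
)
u_ml = np.array([predict_density_from_descriptor(hk, d)
                 for d in dataset.descriptors])

direct = cv_energy_map(u_ml[pool], dataset.e_high[pool], "high", seed=0)
subset = pool[kmeans_select(u_ml[pool], 10, seed=0)]
delta = cv_energy_map(u_ml[subset], dataset.delta[subset], "delta", seed=0)

mae_direct = np.mean(np.abs(
    predict_krr(direct.model, u_ml[test]) - dataset.e_high[test]))
mae_delta = np.mean(np.abs(
    dataset.e_low[test] + predict_krr(delta.model, u_ml[test])
    - dataset.e_high[test]))

print(f"direct high-level map, 50 training samples: MAE {mae_direct:.3f} kcal/mol")
print(f"Delta-corrected route, 10 training samples: MAE {mae_delta:.3f} kcal/mol")
print("(both evaluated on 52 held-out geometries through HK-predicted densities)")
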