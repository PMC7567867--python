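"""Molecular dynamics on learned/cheap surfaces with periodic corrections.

Propagates 100 fs of microcanonical dynamics for the water surrogate three
ways: on the accurate (high-level) surface, on the cheap (low-level)
surface, and with an impulse multiple-time-step integrator that runs on the
cheap surface and applies the accurate-minus-cheap force difference as
symmetric kicks every three steps.  Forces are central finite differences
with eps = 0.001 A; the timestep is 0.5 fs.
"""

import numpy as np

import densfunc as df
from densfunc.dynamics import (
    IntegratorParams,
    MDState,
    langevin_trajectory,
    nve_trajectory,
    respa_trajectory,
)

water = df.toy_water()
rng = np.random.default_rng(4)
x0 = water.template.coords + 0.05 * rng.standard_normal((3, 3))
masses = water.template.masses()
params = IntegratorParams(dt=0.5, n_inner=3)

state = lambda: MDState(x0.copy(), np.zeros((3, 3)), masses)
accurate = nve_trajectory(water.high_energy_fn(), state(), params, 201)
cheap = nve_trajectory(water.low_energy_fn(), state(), params, 201)
mixed = respa_trajectory(water.low_energy_fn(), water.high_energy_fn(),
                         state(), params, 201)

dev_cheap = np.max(np.abs(cheap.positions - accurate.positions))
dev_mixed = np.max(np.abs(mixed.positions - accurate.positions))
drift = np.max(np.abs(accurate.e_tot - accurate.e_tot[0]))
print(f"NVE total-energy fluctuation over 100 fs: {drift:.2e} kcal/mol")
print(f"cheap-surface deviation from accurate:   {dev_cheap:.4f} A")
print(f"RESPA(3) deviation from accurate:        {dev_mixed:.4f} A "
      f"({dev_cheap / dev_mixed:.0f}x closer)")

thermo = IntegratorParams(dt=0.5, temperature=350.0, friction=0.413, seed=0)
traj = langevin_trajectory(water.low_energy_fn(), state(), thermo, 4000)
from densfunc.units import KB_KCAL_MOL_K

temps = 2 * traj.e_kin[1000:] / (9 * KB_KCAL_MOL_K)
print(f"Langevin mean temperature (target 350 K): {np.mean(temps):.0f} K")
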