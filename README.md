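# densfunc

Machine-learned density functionals for molecules: predict electron
densities from nuclear geometry, predict energies from densities, and
correct a cheap level of electronic-structure theory toward an expensive
one — then run geometry optimization and molecular dynamics on the learned
surfaces.

The package is aimed at method developers who want to prototype
density-based Δ-learning pipelines at desk scale. Real electronic-structure
labels (semilocal DFT for the cheap level, coupled cluster for the
expensive one) are replaced by bundled analytic surrogate systems with the
same statistical structure — deterministic low/high energy surfaces a few
kcal·mol⁻¹ apart, analytic valence densities — so every stage of the
pipeline runs in seconds to minutes on one CPU.

## The model

A molecule's Hamiltonian is characterized by its external nuclear
potential, smeared with Gaussians of width γ and sampled on a cubic grid:

    v(r) = Σ_α Z_α exp(−‖r − R_α‖² / 2γ²)

The *Hohenberg–Kohn (HK) map* regresses the valence density's expansion
coefficients in an orthonormal Fourier basis directly from this descriptor,
one kernel ridge regression (KRR) per coefficient, all sharing one Gram
matrix:

    n[v](r) = Σ_l u⁽ˡ⁾[v] φ_l(r),    u⁽ˡ⁾[v] = Σ_i β_i⁽ˡ⁾ k(v, v_i)

A second KRR maps coefficient vectors **u** to energies with a Gaussian
kernel, E_ML[n] = Σ_i α_i k(u, u_i). The *Δ correction* is the same kind of
map trained on high-minus-low energy differences with a **zero prior
mean**, so the corrected total energy

    E_Δ(u) = E_low + ΔE_ML(u)

falls back to the cheap result far from the training data. Because the
correction landscape is much smoother than the total energy landscape, a Δ
map needs far fewer expensive labels than a direct high-level map.

Around this core the package provides point-group detection and
symmetry augmentation of training sets (energies are group invariants, so
a group of order g multiplies a dataset g-fold for free), k-means training
set selection, Kabsch alignment, finite-difference forces, velocity-Verlet
/ Langevin (BAOAB) / impulse multiple-time-step (r-RESPA) integrators, and
L-BFGS geometry optimization on any learned or analytic surface.

## A worked example

`examples/02_hk_map_and_delta_learning.py` fits the HK map on 50 surrogate
water conformers and compares a direct high-level energy map (50 training
labels) against the Δ-corrected route (10 training labels), both evaluated
on 52 held-out geometries through HK-predicted densities:

```
direct high-level map, 50 training samples: MAE 0.114 kcal/mol
Delta-corrected route, 10 training samples: MAE 0.068 kcal/mol
(both evaluated on 52 held-out geometries through HK-predicted densities)
```

With one fifth of the expensive labels the Δ route is already more
accurate — density-prediction error enters the direct map at the full
energy scale but enters the Δ map only at the (much smaller) correction
scale.

The other examples cover dataset generation and density bookkeeping (`01`),
symmetry augmentation — a hexagonal ring's 24 operations turn 1000
conformers into 24,000 samples, and an order-4 ring group turns 1004 into
4004 after deduplication (`03`) — multiple-time-step MD that tracks the
accurate surface ~25× closer than cheap-surface dynamics (`04`), and
conformer search on the Δ-corrected surface when the two levels of theory
disagree about the global minimum (`05`).

A thin CLI mirrors the library for shell use:

```bash
densfunc gen-data --system toy-water --n 100 --seed 1 --out water.h5
densfunc fit-hk --dataset water.h5 --sigma 40 --out hk.h5
densfunc fit-energy --dataset water.h5 --label delta --sigma 1 --out delta.h5
densfunc md --system toy-water --ensemble langevin --steps 2000 --out traj.csv
```

## Layout

- `src/densfunc/core.py`, `io.py`, `units.py` — conformers, grids, energy
  records; XYZ and Gaussian-cube readers/writers; unit conventions
  (Å, kcal·mol⁻¹, amu, fs internally).
- `potential.py`, `basis.py` — the Gaussian potential descriptor and the
  orthonormal Fourier density basis (projection, reconstruction,
  integrals).
- `krr.py` — the KRR engine, fivefold cross-validation, shuffled
  learning-curve evaluation, k-means selection.
- `maps.py`, `protocols.py` — HK map, energy maps, Δ-corrected totals,
  dataset combination; the small-data evaluation protocols.
- `symmetry.py` — point-group detection, augmentation with deduplication,
  Kabsch alignment.
- `dynamics.py` — forces, integrators, geometry optimization.
- `synthetic.py` — the surrogate systems (toy-water, toy-ethanol,
  toy-ring, a hydroxyl fragment) with analytic surfaces and densities.
- `archive.py`, `cli.py` — HDF5 persistence and the command-line wrapper.

See `docs/methods.md` for the modeling choices, parameter defaults and
their rationale, and known limitations.
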