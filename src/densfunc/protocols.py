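"""Small-data evaluation protocols on the synthetic surrogate.

These functions bundle the experiment designs used to validate the learned
functionals at desk scale:

* the repeated-shuffle learning-curve protocol for small datasets (shuffle
  the data, hold out everything beyond the training pool, pick smaller
  subsets by k-means);
* the Δ-vs-direct comparison through the full pipeline — the energy maps
  consume *HK-map-predicted* densities, so density-prediction error
  propagates at full energy scale into the direct map but only at
  correction scale into the Δ map, which is what makes delta learning
  sample-efficient;
* density-input sensitivity (SAD vs bond-aware coefficients);
* dataset combination, where a small fragment molecule sharing a coordinate
  with a larger one supplies extra coverage.

Kernel widths and regularization are selected per map by fivefold
cross-validation on the training set over a multiplicative grid around the
median-pairwise-distance heuristic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .krr import KernelSpec, kfold_cv_score, kmeans_select, predict_krr
from .maps import (
    EnergyMap,
    MolecularDataset,
    combine_datasets,
    fit_energy_map,
    fit_hk_map,
    predict_density_from_descriptor,
)
from .synthetic import ToySystem, make_dataset, toy_ethanol, toy_hydroxyl_fragment, toy_water

#: CV grid: multiples of the median-heuristic sigma, and ridge strengths.
SIGMA_FACTORS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
LAMBDA_GRID = (1e-10, 1e-8, 1e-6)


def median_heuristic_sigma(X) -> float:
    """Median pairwise Euclidean distance — the standard kernel-width
    starting point."""
    d = pdist(np.atleast_2d(np.asarray(X, float)))
    med = float(np.median(d))
    return med if med > 0 else 1.0


def cv_energy_map(
    coefficients,
    labels,
    label_kind: str,
    seed: int = 0,
    sigma_factors=SIGMA_FACTORS,
    lambda_grid=LAMBDA_GRID,
) -> EnergyMap:
    """Fit an energy map with (σ, λ) chosen by fivefold CV on the training
    set."""
    med = median_heuristic_sigma(coefficients)
    prior = "zero" if label_kind == "delta" else "train_mean"
    best, _ = kfold_cv_score(
        coefficients,
        labels,
        [med * f for f in sigma_factors],
        list(lambda_grid),
        folds=5,
        seed=seed,
        prior_mean_mode=prior,
    )
    return fit_energy_map(
        coefficients, labels, label_kind,
        KernelSpec(sigma=best["sigma"]), lam=best["lambda"],
    )


def delta_direct_comparison(
    system: ToySystem | None = None,
    n_seeds: int = 20,
    n_total: int = 102,
    train_size: int = 50,
    delta_subset: int = 10,
    density_mode: str = "bonded",
    base_seed: int = 0,
):
    """Mean test MAEs of the Δ map (small training subset) and the direct
    high-level map (full pool), both consuming HK-predicted densities.

    Per seed: sample ``n_total`` conformers, split ``train_size`` /
    remainder, fit the HK map on the pool, fit the direct map on all pool
    geometries and the Δ map on a k-means-selected subset, evaluate both on
    the held-out set against the high-level labels.
    """
    if system is None:
        system = toy_water()
    direct_maes, delta_maes = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        ds = make_dataset(system, n_total, density_mode=density_mode, seed=seed)
        rng = np.random.default_rng(10_000 + seed)
        perm = rng.permutation(n_total)
        pool, test = perm[:train_size], perm[train_size:]
        hk = fit_hk_map(
            ds.descriptors[pool],
            ds.coefficients[pool],
            KernelSpec(median_heuristic_sigma(ds.descriptors[pool])),
            basis=ds.basis, gridspec=ds.gridspec, gamma=ds.gamma,
        )
        u_ml = np.array(
            [predict_density_from_descriptor(hk, d) for d in ds.descriptors]
        )
        direct = cv_energy_map(u_ml[pool], ds.e_high[pool], "high", seed=seed)
        sub = pool[kmeans_select(u_ml[pool], delta_subset, seed=seed)]
        delta = cv_energy_map(u_ml[sub], ds.delta[sub], "delta", seed=seed)
        pred_direct = predict_krr(direct.model, u_ml[test])
        pred_delta = ds.e_low[test] + predict_krr(delta.model, u_ml[test])
        direct_maes.append(float(np.mean(np.abs(pred_direct - ds.e_high[test]))))
        delta_maes.append(float(np.mean(np.abs(pred_delta - ds.e_high[test]))))
    return {
        "direct_mae": float(np.mean(direct_maes)),
        "delta_mae": float(np.mean(delta_maes)),
        "direct_maes": np.array(direct_maes),
        "delta_maes": np.array(delta_maes),
        "train_size": train_size,
        "delta_subset": delta_subset,
        "test_size": n_total - train_size,
    }


def density_sensitivity_comparison(
    system: ToySystem | None = None,
    n_seeds: int = 10,
    n_total: int = 80,
    train_size: int = 30,
    base_seed: int = 0,
):
    """Test MAE of direct high-level maps trained on SAD vs bond-aware
    density coefficients for identical conformers and labels."""
    if system is None:
        system = toy_water()
    maes = {"sad": [], "bonded": []}
    for s in range(n_seeds):
        seed = base_seed + s
        conformers = system.sample_conformers(n_total, seed=seed)
        rng = np.random.default_rng(20_000 + seed)
        perm = rng.permutation(n_total)
        tr, te = perm[:train_size], perm[train_size:]
        for mode in ("sad", "bonded"):
            ds = make_dataset(
                system, n_total, density_mode=mode, seed=seed,
                conformers=[c.with_coords(c.coords) for c in conformers],
            )
            emap = cv_energy_map(ds.coefficients[tr], ds.e_high[tr], "high",
                                 seed=seed)
            pred = predict_krr(emap.model, ds.coefficients[te])
            maes[mode].append(float(np.mean(np.abs(pred - ds.e_high[te]))))
    return {
        "sad_mae": float(np.mean(maes["sad"])),
        "bonded_mae": float(np.mean(maes["bonded"])),
        "sad_maes": np.array(maes["sad"]),
        "bonded_maes": np.array(maes["bonded"]),
    }


def combined_dataset_benefit(
    n_seeds: int = 10,
    n_large: int = 70,
    large_train: int = 10,
    n_fragment: int = 60,
    base_seed: int = 0,
):
    """Δ-map test MAE on a larger molecule, trained on its own records alone
    vs combined with a fragment that shares its corrected coordinate.

    The large molecule is the ethanol-like system with its correction
    restricted to the shared O-H bond; the fragment is the coincident
    C-O-H piece sampled with a wider spread, improving coverage of the
    shared coordinate at equal large-molecule budget.
    """
    from .basis import FourierBasisSpec
    from .core import GridSpec

    large = toy_ethanol(torsion_correction=False, oh_bond_correction=True)
    fragment = toy_hydroxyl_fragment()
    grid = GridSpec.centered(11.0, 32)
    basis = FourierBasisSpec(7, 11.0)
    only_maes, comb_maes = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        ds_l = make_dataset(large, n_large, gridspec=grid, basis=basis, seed=seed)
        ds_f = make_dataset(
            fragment, n_fragment, gridspec=grid, basis=basis,
            seed=seed + 500, spread=1.3,
        )
        rng = np.random.default_rng(30_000 + seed)
        perm = rng.permutation(n_large)
        tr, te = perm[:large_train], perm[large_train:]
        only = cv_energy_map(ds_l.coefficients[tr], ds_l.delta[tr], "delta",
                             seed=seed)
        comb = combine_datasets(ds_l.subset(tr), ds_f)
        cmap = cv_energy_map(comb.coefficients, comb.delta, "delta", seed=seed)
        p_only = predict_krr(only.model, ds_l.coefficients[te])
        p_comb = predict_krr(cmap.model, ds_l.coefficients[te])
        only_maes.append(float(np.mean(np.abs(p_only - ds_l.delta[te]))))
        comb_maes.append(float(np.mean(np.abs(p_comb - ds_l.delta[te]))))
    return {
        "large_only_mae": float(np.mean(only_maes)),
        "combined_mae": float(np.mean(comb_maes)),
        "large_only_maes": np.array(only_maes),
        "combined_maes": np.array(comb_maes),
    }


def minima_discrimination(seed: int = 0, grid_points: int = 32):
    """Conformer search on the Δ-corrected surface of the ethanol-like
    double-well system.

    The low level ranks the gauche well global; the high level ranks anti
    global.  A Δ map is trained on ensembles covering both wells (with the
    four optimized low/high-level minima included, as a practitioner would
    include known stationary points), and geometry optimizations started
    from both low-level minima probe which well the corrected surface calls
    global.  Two numerical choices matter here.  The Δ map uses the
    median-heuristic kernel width with a fixed ridge λ = 1e-4, stronger
    than interpolation-grade fits: a quasi-Newton optimizer exploits any
    ringing between training points, so an optimization surface trades a
    little fit bias for smoothness.  And every geometry is rigidly aligned
    to the template frame before its density is computed — the physical
    energy is invariant under rigid motions but the density descriptor is
    not, so without alignment an optimizer can drift the whole molecule out
    of the training frame at zero physical cost and ride the model into its
    extrapolation region.
    """
    from .basis import FourierBasisSpec, project_density
    from .core import Conformer
    from .dynamics import optimize_geometry
    from .symmetry import align_to_reference
    from .synthetic import dihedral_angles, zmatrix_to_cartesian

    system = toy_ethanol()
    grid = system.default_gridspec(grid_points)
    basis = FourierBasisSpec(7, grid.box_length)
    driving = (3, 2, 1, 0)  # hydroxyl torsion H-O-C-C

    def torsion(X):
        return float(dihedral_angles(np.asarray(X, float), [driving])[0])

    def start_at(phi):
        q = system.q_template.copy()
        q[5] = phi
        return system.template.with_coords(
            zmatrix_to_cartesian(system.zmatrix, q)
        )

    # oracle minima of each exact surface
    def exact_min(fn, phi):
        return optimize_geometry(fn, start_at(phi), force_tol=1e-6)

    high_anti = exact_min(system.high_energy_fn(), np.pi)
    high_gauche = exact_min(system.high_energy_fn(), 1.0)
    low_anti = exact_min(system.low_energy_fn(), np.pi)
    low_gauche = exact_min(system.low_energy_fn(), 1.0)

    conformers = []
    for center, s in ((1.0, seed + 1), (np.pi, seed + 2)):
        basin = toy_ethanol()
        basin.q_template = system.q_template.copy()
        basin.q_template[5] = center
        conformers += basin.sample_conformers(35, seed=s, spread=0.7)
    rng = np.random.default_rng(seed + 99)
    for m in (high_anti, high_gauche, low_anti, low_gauche):
        conformers.append(m.conformer.with_coords(m.conformer.coords))
        for _ in range(8):
            conformers.append(
                Conformer.from_species(
                    system.species,
                    m.conformer.coords + 0.05 * rng.standard_normal((6, 3)),
                )
            )
    conformers, _ = align_to_reference(conformers, system.template)
    ds = make_dataset(system, len(conformers), gridspec=grid, basis=basis,
                      conformers=conformers)
    delta_map = fit_energy_map(
        ds.coefficients, ds.delta, "delta",
        KernelSpec(median_heuristic_sigma(ds.coefficients)), lam=1e-4,
    )

    def corrected_surface(X):
        conf = Conformer.from_species(system.species, np.asarray(X, float))
        (aligned,), _ = align_to_reference([conf], system.template)
        u = project_density(system.bonded_density(aligned, grid), grid, basis)
        return system.low_energy(X) + predict_krr(delta_map.model, u.u)

    opt_anti = optimize_geometry(corrected_surface, low_anti.conformer,
                                 force_tol=5e-5, max_iter=400)
    opt_gauche = optimize_geometry(corrected_surface, low_gauche.conformer,
                                   force_tol=5e-5, max_iter=400)

    def wrap(a, b):
        return float(abs((a - b + np.pi) % (2 * np.pi) - np.pi))

    return {
        "corrected_anti_energy": opt_anti.energy,
        "corrected_gauche_energy": opt_gauche.energy,
        "corrected_ranks_anti_global": bool(opt_anti.energy < opt_gauche.energy),
        "low_ranks_gauche_global": bool(low_gauche.energy < low_anti.energy),
        "high_ranks_anti_global": bool(high_anti.energy < high_gauche.energy),
        "anti_torsion_error": wrap(torsion(opt_anti.conformer.coords),
                                   torsion(high_anti.conformer.coords)),
        "gauche_torsion_error": wrap(torsion(opt_gauche.conformer.coords),
                                     torsion(high_gauche.conformer.coords)),
        "high_anti_torsion": torsion(high_anti.conformer.coords),
        "low_anti_torsion": torsion(low_anti.conformer.coords),
    }
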