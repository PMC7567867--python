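"""Point-group detection, dataset augmentation with dedup, and Kabsch
alignment."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import densfunc as df
from densfunc.core import Conformer, EnergyRecord
from densfunc.symmetry import (
    align_to_reference,
    augment_dataset,
    detect_point_group,
    match_point_sets,
    mirror_through_heavy_atom_plane,
)
from densfunc.synthetic import ring_rotamer_minima


def asym4():
    return Conformer.from_species(
        ["C", "H", "O", "H"],
        [[0, 0, 0], [1.1, 0, 0], [0, 1.3, 0.2], [0.4, -0.2, 0.9]],
    )


class TestDetection:
    def test_water_c2v_order_four(self, water):
        group = detect_point_group(water.template.centered())
        assert group.order == 4
        assert group.closure_verified
        dets = sorted(round(np.linalg.det(op.matrix)) for op in group.operations)
        assert dets == [-1, -1, 1, 1]  # E, C2, two mirror planes

    def test_benzene_geometry_has_24_operations(self):
        benzene = df.toy_ring("benzene").template.centered()
        group = detect_point_group(benzene)
        assert group.order == 24

    def test_fully_asymmetric_set_only_identity(self):
        group = detect_point_group(asym4().centered())
        assert group.order == 1
        assert group.operations[0].is_identity

    def test_planar_molecule_contains_plane_reflection_brute_force(self):
        """The molecular-plane reflection is found, verified against a
        brute-force search over reflections through centroid planes spanned
        by atom pairs."""
        conf = Conformer.from_species(
            ["C", "O", "H", "H"],
            [[0, 0, 0], [1.23, 0, 0], [-0.6, 0.94, 0], [-0.6, -0.94, 0]],
        ).centered()
        group = detect_point_group(conf)
        reflections = [op.matrix for op in group.operations
                       if round(np.linalg.det(op.matrix)) == -1]
        # brute force: reflections through planes spanned by atom pairs
        coords = conf.coords
        found_by_brute_force = []
        for i, j in itertools.combinations(range(4), 2):
            n = np.cross(coords[i], coords[j])
            if np.linalg.norm(n) < 1e-8:
                continue
            n = n / np.linalg.norm(n)
            M = np.eye(3) - 2 * np.outer(n, n)
            if match_point_sets(coords, coords @ M.T, conf.species, 1e-3) is not None:
                found_by_brute_force.append(M)
        assert found_by_brute_force, "brute force must find the molecular plane"
        for M in found_by_brute_force:
            assert any(np.max(np.abs(M - R)) < 1e-6 for R in reflections)

    def test_group_closure_under_composition(self, water):
        group = detect_point_group(water.template.centered())
        mats = [op.matrix for op in group.operations]
        for a, b in itertools.product(mats, mats):
            prod = a @ b
            assert any(np.max(np.abs(prod - m)) < 1e-6 for m in mats)


class TestHeavyAtomMirror:
    def test_involution(self, ethanol):
        conf = ethanol.sample_conformers(1, spread=0.5, seed=3)[0]
        op = mirror_through_heavy_atom_plane(conf)
        twice = op.apply(op.apply(conf.coords))
        assert np.max(np.abs(twice - conf.coords)) < 1e-10

    def test_planar_conformer_maps_to_itself(self):
        ring = df.toy_ring("benzene")
        op = mirror_through_heavy_atom_plane(ring.template)
        assert np.max(np.abs(op.apply(ring.template.coords)
                             - ring.template.coords)) < 1e-10

    def test_doubles_non_planar_training_set(self, ethanol):
        """n distinct non-planar conformers augment to exactly 2n samples."""
        conformers = ethanol.sample_conformers(10, seed=5)
        for i, c in enumerate(conformers):
            c.energy = EnergyRecord(float(i), float(i) + 1.0)
        op = mirror_through_heavy_atom_plane(conformers[0])
        group = df.SymmetryGroup(
            [df.SymmetryOperation(np.eye(3), np.arange(6)), op]
        )
        augmented = augment_dataset(conformers, group)
        assert len(augmented) == 20

    def test_collinear_heavy_atoms_rejected(self):
        conf = Conformer.from_species(
            ["C", "C", "C", "H"],
            [[0, 0, 0], [1.4, 0, 0], [2.8, 0, 0], [0, 1, 0]],
        )
        with pytest.raises(ValueError, match="collinear"):
            mirror_through_heavy_atom_plane(conf)


class TestAugmentation:
    def test_identity_only_group_leaves_dataset_unchanged(self, water):
        conformers = water.sample_conformers(5, seed=0)
        group = df.SymmetryGroup([df.SymmetryOperation(np.eye(3), np.arange(3))])
        out = augment_dataset(conformers, group)
        assert len(out) == 5
        for a, b in zip(out, conformers):
            assert np.allclose(a.coords, b.coords)

    def test_orbit_size_bound_with_generic_conformers(self):
        """Generic (asymmetric) geometries meet the |group| x n bound with
        equality."""
        benzene = df.toy_ring("benzene")
        group = detect_point_group(benzene.template.centered())
        conformers = benzene.sample_conformers(20, seed=1)
        out = augment_dataset(conformers, group)
        assert len(out) == 24 * 20

    def test_rotamer_minima_collapse_in_orbit(self):
        """The four planar rotamer minima map onto one another under the
        order-4 planar group: 4 inputs x 4 operations dedup to 4 samples."""
        minima = ring_rotamer_minima()
        ring = df.toy_ring()
        for m in minima:
            m.energy = EnergyRecord(float(ring.low_energy(m)))
        group = detect_point_group(minima[0].centered())
        assert group.order == 4
        out = augment_dataset(minima, group)
        assert len(out) == 4

    def test_conflicting_duplicate_labels_raise(self):
        minima = ring_rotamer_minima()
        minima[0].energy = EnergyRecord(0.0)
        minima[1].energy = EnergyRecord(5.0)  # image of minima[0] under C2
        minima[2].energy = EnergyRecord(1.0)
        minima[3].energy = EnergyRecord(2.0)
        group = detect_point_group(minima[0].centered())
        with pytest.raises(ValueError, match="conflicting"):
            augment_dataset(minima, group)

    def test_augmentation_invariance_of_trained_model(self, water):
        """A model trained on the symmetry-augmented set gives equal
        energies for a conformer and its image under a group operation."""
        from densfunc.krr import KernelSpec, fit_krr, predict_krr
        from densfunc.potential import gaussian_potential

        grid = df.GridSpec.symmetric(9.0, 16)
        # symmetric frame: C2 axis along z, molecule in the xz-plane
        theta = np.radians(104.45 / 2)
        r = 0.9584
        base = Conformer.from_species(
            ["O", "H", "H"],
            [[0, 0, 0.0], [r * np.sin(theta), 0, -r * np.cos(theta)],
             [-r * np.sin(theta), 0, -r * np.cos(theta)]],
        )
        group = detect_point_group(base)
        assert group.order == 4
        # operations act about the shared aligned frame's origin (the grid
        # center), not per-conformer centroids, so lattice-compatible
        # operations permute descriptor values exactly
        for op in group.operations:
            op.center = np.zeros(3)
        rng = np.random.default_rng(8)
        conformers = []
        for i in range(10):
            c = base.with_coords(base.coords + 0.05 * rng.standard_normal((3, 3)))
            c.energy = EnergyRecord(float(water.low_energy(c.coords @ np.eye(3))))
            conformers.append(c)
        augmented = augment_dataset(conformers, group)
        X = np.array([gaussian_potential(c, grid, 0.6).values for c in augmented])
        y = np.array([c.energy.e_low for c in augmented])
        model = fit_krr(X, y, KernelSpec(10.0), lam=1e-10)
        query = base.with_coords(base.coords + 0.03 * rng.standard_normal((3, 3)))
        image = query.with_coords(group.operations[1].apply(query.coords))
        p1 = predict_krr(model, gaussian_potential(query, grid, 0.6).values)
        p2 = predict_krr(model, gaussian_potential(image, grid, 0.6).values)
        assert p2 == pytest.approx(p1, rel=1e-6)


class TestAlignment:
    def test_rotated_translated_copy_has_zero_rmsd(self, rng):
        ref = asym4()
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = ref.with_coords(ref.coords @ R.T + np.array([1.0, -2.0, 0.5]))
        aligned, rmsds = align_to_reference([moved], ref, atom_subset=range(4))
        assert rmsds[0] < 1e-8
        assert np.max(np.abs(aligned[0].coords - ref.coords)) < 1e-8

    def test_reference_aligns_to_itself(self):
        ref = asym4()
        aligned, rmsds = align_to_reference([ref], ref)
        assert rmsds[0] < 1e-12
        assert np.max(np.abs(aligned[0].coords - ref.coords)) < 1e-12

    def test_subset_alignment_applies_to_all_atoms(self, rng):
        ref = Conformer.from_species(
            ["C", "C", "C", "H", "H"], rng.standard_normal((5, 3))
        )
        R = Rotation.from_euler("zyx", [0.5, 0.2, -0.4]).as_matrix()
        moved = ref.with_coords(ref.coords @ R.T + 3.0)
        aligned, rmsds = align_to_reference([moved], ref, atom_subset=[0, 1, 2])
        assert rmsds[0] < 1e-8
        # hydrogens follow the carbon-subset transform
        assert np.max(np.abs(aligned[0].coords - ref.coords)) < 1e-8

    def test_kabsch_matches_euler_grid_oracle(self, rng):
        """Brute-force minimization over Euler angles (30^3 grid + local
        polish) agrees with the Kabsch RMSD to 1e-3 A."""
        from scipy.optimize import minimize

        P = rng.standard_normal((5, 3))
        R0 = Rotation.from_euler("xyz", [1.0, -0.4, 0.7]).as_matrix()
        Q = P @ R0.T + 0.15 * rng.standard_normal((5, 3))
        ref = Conformer.from_species(["C"] * 5, Q)
        conf = Conformer.from_species(["C"] * 5, P)
        _, rmsds = align_to_reference([conf], ref)
        kabsch_rmsd = rmsds[0]

        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)

        def rmsd_of_angles(angles):
            M = Rotation.from_euler("xyz", angles).as_matrix()
            return np.sqrt(np.mean(np.sum((Pc @ M.T - Qc) ** 2, axis=1)))

        grid = np.linspace(-np.pi, np.pi, 30)
        angles = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        mats = Rotation.from_euler("xyz", angles).as_matrix()
        rotated = np.einsum("nij,kj->nki", mats, Pc)
        all_rmsd = np.sqrt(np.mean(np.sum((rotated - Qc) ** 2, axis=2), axis=1))
        best = angles[np.argmin(all_rmsd)]
        res = minimize(rmsd_of_angles, best, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12})
        assert res.fun == pytest.approx(kabsch_rmsd, abs=1e-3)
        assert res.fun >= kabsch_rmsd - 1e-9  # Kabsch is the true optimum

    def test_small_subset_rejected(self):
        ref = asym4()
        with pytest.raises(ValueError):
            align_to_reference([ref], ref, atom_subset=[0, 1])
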