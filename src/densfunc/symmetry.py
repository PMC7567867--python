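"""Point-group symmetry handling for molecular datasets.

Point-group operations let a training set be multiplied by the group order
without any additional electronic-structure labels: energies are invariants,
while descriptors and densities of the transformed copies are simply
recomputed from the transformed coordinates.

Detection enumerates candidate rotation/reflection axes from principal axes,
atom directions, pair midpoints/differences, and pair cross products (ring
normals), keeps every orthogonal transform that maps the species-labelled
point set onto itself within tolerance, polishes each by an orthogonal
Procrustes fit, and closes the set under composition.  This covers the rigid
point groups of small molecules (≤ 64 atoms); explicit operation lists may
be supplied instead for anything more exotic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class SymmetryOperation:
    """Orthogonal transform (det ±1) plus the species-preserving atom
    permutation it induces on the reference geometry.  ``center`` is the
    point the transform acts about (defaults to the nuclear centroid of the
    coordinates it is applied to)."""

    matrix: np.ndarray
    atom_map: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(3, 3)
        self.atom_map = np.asarray(self.atom_map, int).ravel()
        if np.max(np.abs(self.matrix.T @ self.matrix - np.eye(3))) > 1e-8:
            raise ValueError("symmetry matrix is not orthogonal")
        if sorted(self.atom_map) != list(range(self.atom_map.size)):
            raise ValueError("atom_map is not a permutation")

    @property
    def is_identity(self) -> bool:
        return (
            np.max(np.abs(self.matrix - np.eye(3))) < 1e-8
            and np.array_equal(self.atom_map, np.arange(self.atom_map.size))
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform coordinates about ``center`` (or their centroid)."""
        coords = np.asarray(coords, float)
        c = self.center if self.center is not None else coords.mean(axis=0)
        return (coords - c) @ self.matrix.T + c


@dataclass
class SymmetryGroup:
    """A set of symmetry operations containing the identity."""

    operations: list[SymmetryOperation]
    closure_verified: bool = False

    @property
    def order(self) -> int:
        return len(self.operations)


def _species_blocks(species) -> dict[str, np.ndarray]:
    blocks: dict[str, list[int]] = {}
    for i, s in enumerate(species):
        blocks.setdefault(s, []).append(i)
    return {s: np.array(idx) for s, idx in blocks.items()}


def match_point_sets(
    ref_coords: np.ndarray, new_coords: np.ndarray, species, tol: float
) -> np.ndarray | None:
    """Species-preserving permutation π with ‖new_i − ref_{π(i)}‖ ≤ tol for
    every atom, found by optimal assignment; ``None`` when no such map
    exists."""
    n = len(species)
    perm = np.full(n, -1, dtype=int)
    for idx in _species_blocks(species).values():
        d = np.linalg.norm(
            new_coords[idx][:, None, :] - ref_coords[idx][None, :, :], axis=2
        )
        rows, cols = linear_sum_assignment(d)
        if d[rows, cols].max() > tol:
            return None
        perm[idx[rows]] = idx[cols]
    return perm


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _reflection_matrix(normal: np.ndarray) -> np.ndarray:
    a = normal / np.linalg.norm(normal)
    return np.eye(3) - 2.0 * np.outer(a, a)


def _candidate_axes(coords: np.ndarray) -> list[np.ndarray]:
    cands: list[np.ndarray] = []

    def push(v):
        norm = np.linalg.norm(v)
        if norm > 1e-6:
            cands.append(v / norm)

    # principal axes of the gyration tensor
    _, vecs = np.linalg.eigh(coords.T @ coords)
    for v in vecs.T:
        push(v)
    for x in coords:
        push(x)
    for i, j in itertools.combinations(range(len(coords)), 2):
        push(coords[i] + coords[j])
        push(coords[i] - coords[j])
        push(np.cross(coords[i], coords[j]))
    # deduplicate directions (axes are unsigned)
    unique: list[np.ndarray] = []
    for v in cands:
        if all(abs(v @ u) < 1.0 - 1e-6 for u in unique):
            unique.append(v)
    return unique


def _procrustes_refine(
    coords: np.ndarray, perm: np.ndarray, candidate: np.ndarray
) -> np.ndarray:
    """Best orthogonal Q (any det) with Q·x_i ≈ x_{perm(i)}.

    For planar (or otherwise rank-deficient) point sets the permutation does
    not constrain the action along the null directions — e.g. the molecular
    plane reflection of a planar molecule permutes atoms exactly like the
    identity.  There the candidate matrix supplies the sign of the action,
    so σh-type operations survive the polish.
    """
    A, B = coords, coords[perm]
    U, s, Vt = np.linalg.svd(B.T @ A)
    V = Vt.T
    D = np.ones(3)
    thresh = 1e-8 * max(s[0], 1.0)
    for i in range(3):
        if s[i] <= thresh:
            proj = float((candidate @ V[:, i]) @ U[:, i])
            D[i] = -1.0 if proj < 0 else 1.0
    return U @ np.diag(D) @ Vt


def detect_point_group(conformer, tol: float = 1e-3, max_order: int = 6) -> SymmetryGroup:
    """Detect the rigid point group of a conformer (centered internally).

    Candidate proper/improper rotations up to order ``max_order`` about the
    enumerated axes, plus reflections and the inversion, are screened
    against the species-labelled point set; survivors are polished and
    closed under composition.
    """
    coords = np.asarray(conformer.coords, float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    coords = coords - coords.mean(axis=0)
    species = conformer.species
    n = len(species)

    def try_matrix(Q, found, seen):
        new = Q @ coords.T
        perm = match_point_sets(coords, new.T, species, tol)
        if perm is None:
            return
        Qr = _procrustes_refine(coords, perm, Q)
        for M in seen:
            if np.max(np.abs(M - Qr)) < 1e-6:
                return
        seen.append(Qr)
        found.append(SymmetryOperation(Qr, perm))

    found: list[SymmetryOperation] = [
        SymmetryOperation(np.eye(3), np.arange(n))
    ]
    seen: list[np.ndarray] = [np.eye(3)]
    try_matrix(-np.eye(3), found, seen)
    for axis in _candidate_axes(coords):
        try_matrix(_reflection_matrix(axis), found, seen)
        sigma = _reflection_matrix(axis)
        for order in range(2, max_order + 1):
            for k in range(1, order):
                R = _rotation_matrix(axis, 2.0 * np.pi * k / order)
                try_matrix(R, found, seen)
                try_matrix(sigma @ R, found, seen)

    # close under composition
    changed = True
    while changed and len(found) < 200:
        changed = False
        for a, b in itertools.product(list(found), list(found)):
            Q = a.matrix @ b.matrix
            if any(np.max(np.abs(M - Q)) < 1e-6 for M in seen):
                continue
            perm = match_point_sets(coords, (Q @ coords.T).T, species, 3 * tol)
            if perm is None:
                continue
            Qr = _procrustes_refine(coords, perm, Q)
            if any(np.max(np.abs(M - Qr)) < 1e-6 for M in seen):
                continue
            seen.append(Qr)
            found.append(SymmetryOperation(Qr, perm))
            changed = True
    return SymmetryGroup(found, closure_verified=True)


def mirror_through_heavy_atom_plane(conformer, tol: float = 1e-3) -> SymmetryOperation:
    """Reflection through the least-squares plane of the non-hydrogen atoms.

    For a non-planar conformer this produces a genuinely new geometry with
    identical energy, doubling a training set at zero labelling cost; for a
    planar one it maps the conformer onto itself.
    """
    heavy = np.array([i for i, s in enumerate(conformer.species) if s != "H"])
    if heavy.size < 3:
        raise ValueError("need at least three non-hydrogen atoms to define a plane")
    hv = conformer.coords[heavy]
    center = hv.mean(axis=0)
    _, svals, Vt = np.linalg.svd(hv - center)
    if svals[1] < 1e-6:
        raise ValueError("heavy atoms are collinear; plane is undefined")
    normal = Vt[2]
    matrix = _reflection_matrix(normal)
    reflected = (conformer.coords - center) @ matrix.T + center
    perm = match_point_sets(conformer.coords, reflected, conformer.species, tol)
    if perm is None:
        perm = np.arange(conformer.n_atoms)
    return SymmetryOperation(matrix, perm, center=center)


def _axis_signature(coords: np.ndarray) -> np.ndarray:
    """Cheap permutation-invariant signature of a centered point set:
    per-axis sorted coordinates.  Equal (within tolerance) for duplicate
    point sets; differs for rotated copies."""
    return np.sort(coords, axis=0).ravel()


def augment_dataset(conformers, group: SymmetryGroup, dedup_tol: float = 1e-4):
    """Replace each conformer by its orbit under the group, removing
    geometric duplicates.

    Duplicates are species-matched point sets agreeing within ``dedup_tol``
    after centroid removal; their energy labels must agree within 1e-9
    (energies are group invariants), otherwise the input is inconsistent and
    an error is raised.  Output preserves generation order (conformer-major,
    operation-minor) keeping the first member of each duplicate set.
    """
    conformers = list(conformers)
    if not conformers:
        return []
    images = []  # (conformer, centered coords, radius-invariant, signature)
    for c in conformers:
        for op in group.operations:
            coords = op.apply(c.coords)
            out = c.with_coords(coords)
            cc = coords - coords.mean(axis=0)
            images.append((out, cc, float(np.linalg.norm(cc, axis=1).sum()),
                           _axis_signature(cc)))
    n_atoms = conformers[0].n_atoms
    inv_tol = 2.0 * n_atoms * dedup_tol + 1e-9
    order = sorted(range(len(images)), key=lambda i: images[i][2])
    invs = [images[i][2] for i in order]
    species = conformers[0].species

    def is_duplicate(i, j) -> bool:
        if np.max(np.abs(images[i][3] - images[j][3])) > 2.0 * dedup_tol:
            return False
        return match_point_sets(
            images[i][1], images[j][1], species, dedup_tol
        ) is not None

    # union duplicates within the invariant window
    parent = list(range(len(images)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(order)):
        i = order[a]
        b = a + 1
        while b < len(order) and invs[b] - invs[a] <= inv_tol:
            j = order[b]
            if find(i) != find(j) and is_duplicate(i, j):
                ri, rj = find(i), find(j)
                # representative = smallest generation index
                if ri < rj:
                    parent[rj] = ri
                else:
                    parent[ri] = rj
            b += 1

    kept: list = []
    rep_energy: dict[int, object] = {}
    for idx, (conf, _, _, _) in enumerate(images):
        root = find(idx)
        if root == idx:
            kept.append(conf)
            rep_energy[root] = conf.energy
        else:
            ea, eb = rep_energy[root], conf.energy
            if (ea is None) != (eb is None):
                raise ValueError("duplicate geometries with inconsistent labels")
            if ea is not None:
                if abs(ea.e_low - eb.e_low) > 1e-9 or (
                    (ea.e_high is None) != (eb.e_high is None)
                    or (ea.e_high is not None and abs(ea.e_high - eb.e_high) > 1e-9)
                ):
                    raise ValueError(
                        "duplicate geometries carry conflicting energy labels"
                    )
    return kept


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) minimizing ‖P R^T − Q‖ for centered P, Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def align_to_reference(conformers, reference, atom_subset=None):
    """Rigidly align conformers to a reference by Kabsch superposition of an
    atom subset (e.g. the carbon skeleton); the fitted transform is applied
    to all atoms.  Returns ``(aligned_conformers, subset_rmsds)``."""
    if atom_subset is None:
        atom_subset = np.arange(reference.n_atoms)
    subset = np.asarray(atom_subset, int)
    if subset.size < 3:
        raise ValueError("alignment subset must contain at least three atoms")
    ref_sub = reference.coords[subset]
    ref_c = ref_sub.mean(axis=0)
    aligned, rmsds = [], []
    for conf in conformers:
        sub = conf.coords[subset]
        c = sub.mean(axis=0)
        R = kabsch_rotation(sub - c, ref_sub - ref_c)
        new_coords = (conf.coords - c) @ R.T + ref_c
        aligned.append(conf.with_coords(new_coords))
        rmsds.append(
            float(np.sqrt(np.mean(np.sum(
                (new_coords[subset] - ref_sub) ** 2, axis=1))))
        )
    return aligned, np.array(rmsds)
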