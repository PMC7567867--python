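"""Synthetic molecular systems with analytic energy surfaces and densities.

These surrogates stand in for external electronic-structure labels so the
full pipeline — descriptors, density projection, learned maps, dynamics —
can be exercised end to end at desk scale.  Each :class:`ToySystem` bundles:

* a deterministic *low-level* surface (harmonic bonds/angles plus cosine
  torsions, minimum at the template geometry);
* a *high-level* surface equal to the low-level one plus a smooth, bounded
  correction: sign-asymmetric ``a·tanh(d/w)·exp(−(d/2w)²)`` terms in bond
  displacement (short bonds corrected down, stretched bonds up) and optional
  cosine terms in a torsion.  Correction magnitudes are calibrated so a
  thermally sampled ensemble shows a mean |high − low| of 1–3 kcal·mol⁻¹ —
  the error regime of a semilocal functional against coupled cluster;
* analytic densities: superposition of atomic Gaussians (SAD) and a
  bond-aware variant adding bond-midpoint Gaussians whose amplitude decays
  smoothly with bond stretch (renormalized to the valence electron count).

Labels carry no stochastic noise: like real electronic-structure output,
they are deterministic functions of geometry; the only randomness is the
seeded conformer sampling.

Bundled systems: ``toy_water`` (3 atoms, C2v), ``toy_ethanol`` (6 atoms,
non-planar, a double-well driving torsion on which the two surfaces disagree
about the global minimum — gauche for the low level, anti for the high
level), and ``toy_ring`` (planar ring; a benzene-like variant with the full
order-24 hexagonal group, and a resorcinol-like variant with an order-4
planar group and four rotamer minima mapped onto one another by it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .basis import FourierBasisSpec, project_density
from .core import Conformer, EnergyRecord, GridSpec
from .maps import MolecularDataset
from .potential import gaussian_potential

#: Thermal energy scale (kcal·mol⁻¹) setting sampling widths at spread = 1.
SAMPLING_ENERGY_SCALE = 2.0


# ---------------------------------------------------------------------------
# batched internal-coordinate geometry


def bond_lengths(X: np.ndarray, pairs) -> np.ndarray:
    X = np.asarray(X, float)
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    return np.linalg.norm(X[..., j, :] - X[..., i, :], axis=-1)


def bend_angles(X: np.ndarray, triples) -> np.ndarray:
    """Angles (rad) at the middle atom of each (i, j, k) triple."""
    X = np.asarray(X, float)
    i = np.array([t[0] for t in triples])
    j = np.array([t[1] for t in triples])
    k = np.array([t[2] for t in triples])
    v1 = X[..., i, :] - X[..., j, :]
    v2 = X[..., k, :] - X[..., j, :]
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def dihedral_angles(X: np.ndarray, quads) -> np.ndarray:
    """Signed dihedrals (rad) for each (i, j, k, l) quad."""
    X = np.asarray(X, float)
    i = np.array([q[0] for q in quads])
    j = np.array([q[1] for q in quads])
    k = np.array([q[2] for q in quads])
    l = np.array([q[3] for q in quads])
    b1 = X[..., j, :] - X[..., i, :]
    b2 = X[..., k, :] - X[..., j, :]
    b3 = X[..., l, :] - X[..., k, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------
# energy terms


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_force: float  # kcal·mol⁻¹·Å⁻²
    r0: float  # Å


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int  # vertex
    k: int
    k_force: float  # kcal·mol⁻¹·rad⁻²
    theta0: float  # rad


@dataclass(frozen=True)
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    #: cosine series: V = Σ a·(1 + cos(n φ − δ)) over (n, a, δ) entries
    series: tuple = ()


@dataclass(frozen=True)
class BondCorrection:
    """Odd, bounded high−low term in the displacement of one bond:
    a·tanh(d/w)·exp(−(d/2w)²)."""

    bond_index: int
    amplitude: float
    width: float


@dataclass(frozen=True)
class TorsionCorrection:
    """Smooth high−low term in one torsion: a·(1 + cos(n φ − δ))."""

    torsion_index: int
    amplitude: float
    n: int = 1
    phase: float = 0.0


# ---------------------------------------------------------------------------
# the system


@dataclass
class ToySystem:
    name: str
    species: tuple[str, ...]
    template_coords: np.ndarray
    bonds: tuple[BondTerm, ...]
    angles: tuple[AngleTerm, ...] = ()
    torsions: tuple[TorsionTerm, ...] = ()
    bond_corrections: tuple[BondCorrection, ...] = ()
    torsion_corrections: tuple[TorsionCorrection, ...] = ()
    density_widths: dict = field(
        default_factory=lambda: {"H": 0.35, "C": 0.50, "O": 0.45}
    )
    bond_density_weight: float = 0.4
    bond_gauss_width: float = 0.40
    #: amplitude decay length of the bond-midpoint density term, Å
    bond_decay_length: float = 0.3
    #: bond-displacement range over which the midpoint density is monotone
    bond_stretch_range: tuple = (-0.15, 0.25)
    #: mean |high−low| band the sampled ensemble is calibrated into
    correction_band: tuple = (1.0, 3.0)
    #: sampling machinery (see sample_conformers)
    zmatrix: tuple | None = None
    q_template: np.ndarray | None = None
    sample_scales: np.ndarray | None = None
    cartesian_jitter: float = 0.03

    def __post_init__(self) -> None:
        self.template_coords = np.asarray(self.template_coords, float)
        self._raw_low_at_template = float(
            self._raw_low(self.template_coords[None])[0]
        )

    # -- template ----------------------------------------------------------

    @property
    def template(self) -> Conformer:
        return Conformer.from_species(
            self.species, self.template_coords.copy(), label=self.name
        )

    def _coords(self, conformer_or_positions) -> np.ndarray:
        if isinstance(conformer_or_positions, Conformer):
            if conformer_or_positions.species != tuple(self.species):
                raise ValueError(
                    f"species mismatch: system {self.name} expects "
                    f"{self.species}"
                )
            return conformer_or_positions.coords
        return np.asarray(conformer_or_positions, float)

    # -- energy surfaces ---------------------------------------------------

    def _raw_low(self, X: np.ndarray) -> np.ndarray:
        e = np.zeros(X.shape[:-2])
        if self.bonds:
            r = bond_lengths(X, [(b.i, b.j) for b in self.bonds])
            k = np.array([b.k_force for b in self.bonds])
            r0 = np.array([b.r0 for b in self.bonds])
            e = e + 0.5 * np.sum(k * (r - r0) ** 2, axis=-1)
        if self.angles:
            th = bend_angles(X, [(a.i, a.j, a.k) for a in self.angles])
            k = np.array([a.k_force for a in self.angles])
            t0 = np.array([a.theta0 for a in self.angles])
            e = e + 0.5 * np.sum(k * (th - t0) ** 2, axis=-1)
        if self.torsions:
            phi = dihedral_angles(X, [(t.i, t.j, t.k, t.l) for t in self.torsions])
            for idx, term in enumerate(self.torsions):
                for n, a, delta in term.series:
                    e = e + a * (1.0 + np.cos(n * phi[..., idx] - delta))
        return e

    def _correction(self, X: np.ndarray) -> np.ndarray:
        e = np.zeros(X.shape[:-2])
        for corr in self.bond_corrections:
            b = self.bonds[corr.bond_index]
            d = bond_lengths(X, [(b.i, b.j)])[..., 0] - b.r0
            w = corr.width
            e = e + corr.amplitude * np.tanh(d / w) * np.exp(-((d / (2 * w)) ** 2))
        for corr in self.torsion_corrections:
            t = self.torsions[corr.torsion_index]
            phi = dihedral_angles(X, [(t.i, t.j, t.k, t.l)])[..., 0]
            e = e + corr.amplitude * (1.0 + np.cos(corr.n * phi - corr.phase))
        return e

    def low_energy(self, conformer_or_positions) -> float | np.ndarray:
        """Low-level surface, kcal·mol⁻¹, zero at the template geometry."""
        X = self._coords(conformer_or_positions)
        single = X.ndim == 2
        Xb = X[None] if single else X
        e = self._raw_low(Xb) - self._raw_low_at_template
        return float(e[0]) if single else e

    def high_energy(self, conformer_or_positions) -> float | np.ndarray:
        """High-level surface: low level plus the smooth correction."""
        X = self._coords(conformer_or_positions)
        single = X.ndim == 2
        Xb = X[None] if single else X
        e = self._raw_low(Xb) - self._raw_low_at_template + self._correction(Xb)
        return float(e[0]) if single else e

    def delta_energy(self, conformer_or_positions) -> float | np.ndarray:
        X = self._coords(conformer_or_positions)
        single = X.ndim == 2
        e = self._correction(X[None] if single else X)
        return float(e[0]) if single else e

    def low_energy_fn(self):
        return lambda X: self.low_energy(X)

    def high_energy_fn(self):
        return lambda X: self.high_energy(X)

    # -- densities ---------------------------------------------------------

    def _gaussian_field(self, centers, amplitudes, widths, gridspec: GridSpec):
        ax, ay, az = gridspec.axis_coords()
        n = gridspec.points_per_dim
        fld = np.zeros((n, n, n))
        for (cx, cy, cz), amp, w in zip(centers, amplitudes, widths):
            norm = amp / (2.0 * np.pi * w * w) ** 1.5
            inv = 1.0 / (2.0 * w * w)
            gx = np.exp(-((ax - cx) ** 2) * inv)
            gy = np.exp(-((ay - cy) ** 2) * inv)
            gz = np.exp(-((az - cz) ** 2) * inv)
            fld += norm * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        return fld.ravel()

    def sad_density(self, conformer: Conformer, gridspec: GridSpec) -> np.ndarray:
        """Superposition-of-atomic-densities field (flattened grid values),
        integrating to the valence electron count."""
        widths = [self.density_widths[s] for s in conformer.species]
        if any(w <= 0 for w in widths):
            raise ValueError("density widths must be positive")
        return self._gaussian_field(
            conformer.coords, conformer.charges, widths, gridspec
        )

    def bonded_density(self, conformer: Conformer, gridspec: GridSpec) -> np.ndarray:
        """SAD plus bond-midpoint Gaussians with a smooth bond-length
        dependent amplitude, renormalized to the valence electron count —
        a stand-in for a self-consistent density that actually describes
        the chemical bonds."""
        vals = self.sad_density(conformer, gridspec)
        if self.bond_density_weight != 0.0:
            pairs = [(b.i, b.j) for b in self.bonds]
            r = bond_lengths(conformer.coords, pairs)
            mids = 0.5 * (
                conformer.coords[[p[0] for p in pairs]]
                + conformer.coords[[p[1] for p in pairs]]
            )
            amps = self.bond_density_weight * np.exp(
                -(r - np.array([b.r0 for b in self.bonds])) / self.bond_decay_length
            )
            vals = vals + self._gaussian_field(
                mids, amps, [self.bond_gauss_width] * len(pairs), gridspec
            )
        total = vals.sum() * gridspec.voxel_volume
        return vals * (conformer.n_valence_electrons / total)

    def density(self, conformer, gridspec, mode: str = "bonded") -> np.ndarray:
        if mode == "sad":
            return self.sad_density(conformer, gridspec)
        if mode == "bonded":
            return self.bonded_density(conformer, gridspec)
        raise ValueError(f"unknown density mode {mode!r}")

    # -- sampling ----------------------------------------------------------

    def sample_conformers(self, n: int, spread: float = 1.0, seed: int = 0):
        """Seeded thermal-style ensemble around the template.

        Z-matrix systems perturb their internal coordinates with Gaussian
        displacements scaled by ``spread`` and per-coordinate widths derived
        from the force constants; ring systems use Cartesian jitter.
        """
        if n < 1 or spread < 0:
            raise ValueError("need n >= 1 and spread >= 0")
        rng = np.random.default_rng(seed)
        out = []
        if self.zmatrix is not None:
            for m in range(n):
                q = self.q_template + spread * self.sample_scales * \
                    rng.standard_normal(self.q_template.size)
                coords = zmatrix_to_cartesian(self.zmatrix, q)
                out.append(
                    Conformer.from_species(self.species, coords,
                                           label=f"{self.name}-{m}")
                )
        else:
            for m in range(n):
                coords = self.template_coords + spread * self.cartesian_jitter * \
                    rng.standard_normal(self.template_coords.shape)
                out.append(
                    Conformer.from_species(self.species, coords,
                                           label=f"{self.name}-{m}")
                )
        return out

    # -- defaults ----------------------------------------------------------

    def default_gridspec(self, points_per_dim: int = 32, margin: float = 3.0) -> GridSpec:
        """Cubic grid centered on the template's bounding box with enough
        margin for descriptor and density tails."""
        lo = self.template_coords.min(axis=0)
        hi = self.template_coords.max(axis=0)
        center = 0.5 * (lo + hi)
        box = float((hi - lo).max()) + 2.0 * margin + 2.0
        origin = center - 0.5 * box
        return GridSpec(box, points_per_dim, tuple(origin))


# ---------------------------------------------------------------------------
# Z-matrix construction (NeRF)


def zmatrix_to_cartesian(zmatrix, q: np.ndarray) -> np.ndarray:
    """Build Cartesians from a Z-matrix.

    Each entry is a tuple of (reference atoms, coordinate indices into q):
    atom 0 → (); atom 1 → (j, iq_bond); atom 2 → (j, iq_bond, k, iq_angle);
    atom i ≥ 3 → (j, iq_bond, k, iq_angle, l, iq_torsion).
    """
    n = len(zmatrix)
    X = np.zeros((n, 3))
    for i, entry in enumerate(zmatrix):
        if i == 0:
            continue
        if i == 1:
            j, iq = entry
            X[1] = X[j] + np.array([q[iq], 0.0, 0.0])
            continue
        if len(entry) == 4:
            j, iqb, k, iqa = entry
            b, theta = q[iqb], q[iqa]
            u = X[k] - X[j]
            u = u / np.linalg.norm(u)
            p = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(p) < 1e-8:
                p = np.array([0.0, 1.0, 0.0])
            p = p / np.linalg.norm(p)
            X[i] = X[j] + b * (math.cos(theta) * u + math.sin(theta) * p)
            continue
        j, iqb, k, iqa, l, iqt = entry
        b, theta, phi = q[iqb], q[iqa], q[iqt]
        bc = X[j] - X[k]
        bc = bc / np.linalg.norm(bc)
        ab = X[k] - X[l]
        nvec = np.cross(ab, bc)
        nvec = nvec / np.linalg.norm(nvec)
        m = np.cross(nvec, bc)
        d = np.array(
            [
                -b * math.cos(theta),
                b * math.sin(theta) * math.cos(phi),
                b * math.sin(theta) * math.sin(phi),
            ]
        )
        X[i] = X[j] + d[0] * bc + d[1] * m + d[2] * nvec
    return X


# ---------------------------------------------------------------------------
# bundled systems


def toy_water(correction_amplitude: float = 8.0) -> ToySystem:
    """3-atom bent molecule (C2v): two equal bonds, one angle; the high−low
    correction is an odd, long-length-scale function of each bond
    displacement (near-linear over the thermal spread, so the correction
    surface is much smoother than the total surface — the regime in which
    delta learning pays off)."""
    r0, theta0 = 0.9584, math.radians(104.45)
    kb, ka = 600.0, 75.0
    zmat = ((), (0, 0), (0, 1, 1, 2))
    q = np.array([r0, r0, theta0])
    coords = zmatrix_to_cartesian(zmat, q)
    scale = math.sqrt(SAMPLING_ENERGY_SCALE)
    sys = ToySystem(
        name="toy-water",
        species=("O", "H", "H"),
        template_coords=coords,
        bonds=(BondTerm(0, 1, kb, r0), BondTerm(0, 2, kb, r0)),
        angles=(AngleTerm(1, 0, 2, ka, theta0),),
        bond_corrections=(
            BondCorrection(0, correction_amplitude, 0.3),
            BondCorrection(1, correction_amplitude, 0.3),
        ),
        zmatrix=zmat,
        q_template=q,
        sample_scales=np.array(
            [scale / math.sqrt(kb), scale / math.sqrt(kb), scale / math.sqrt(ka)]
        ),
    )
    return sys


def _ethanol_driving_torsion_minimum(a1, a3, lo, hi):
    res = minimize_scalar(
        lambda p: a1 * (1 + math.cos(p)) + a3 * (1 + math.cos(3 * p)),
        bounds=(lo, hi),
        method="bounded",
    )
    return float(res.x)


def toy_ethanol(
    torsion_correction: bool = True, oh_bond_correction: bool = False
) -> ToySystem:
    """6-atom non-planar surrogate with a double-well driving torsion
    (hydroxyl rotation): the low-level surface has its global minimum at
    gauche, the correction re-ranks the wells so the high-level global
    minimum is anti — the two levels of theory genuinely disagree.

    By default the high−low correction acts on the soft driving torsion
    only, keeping the correction a single-length-scale function of the
    density (the bond-displacement corrections live in ``toy_water``);
    ``oh_bond_correction`` adds an odd O-H stretch term instead, the
    configuration used by the dataset-combination experiments."""
    a1, a3 = -0.4, 1.2
    r_cc, r_co, r_oh, r_ch = 1.52, 1.43, 0.96, 1.09
    k_cc, k_co, k_oh, k_ch = 350.0, 400.0, 600.0, 400.0
    th_cco, th_coh, th_cch = map(math.radians, (109.0, 108.5, 109.5))
    ka = 70.0
    phi_g = _ethanol_driving_torsion_minimum(a1, a3, 0.3, 2.0)  # gauche well
    zmat = (
        (),             # C0
        (0, 0),         # C1: r_CC
        (1, 1, 0, 2),   # O2: r_CO, angle O-C1-C0
        (2, 3, 1, 4, 0, 5),  # H3: r_OH, angle H-O-C1, torsion H-O-C1-C0
        (0, 6, 1, 7, 2, 8),  # H4 on C0
        (0, 9, 1, 10, 2, 11),  # H5 on C0
    )
    q = np.array(
        [
            r_cc, r_co, th_cco,
            r_oh, th_coh, phi_g,
            r_ch, th_cch, math.radians(60.0),
            r_ch, th_cch, math.radians(-60.0),
        ]
    )
    coords = zmatrix_to_cartesian(zmat, q)
    s = math.sqrt(SAMPLING_ENERGY_SCALE)
    scales = np.array(
        [
            s / math.sqrt(k_cc), s / math.sqrt(k_co), s / math.sqrt(ka),
            s / math.sqrt(k_oh), s / math.sqrt(ka), 1.2,
            s / math.sqrt(k_ch), s / math.sqrt(ka), 0.25,
            s / math.sqrt(k_ch), s / math.sqrt(ka), 0.25,
        ]
    )
    return ToySystem(
        name="toy-ethanol",
        species=("C", "C", "O", "H", "H", "H"),
        template_coords=coords,
        bonds=(
            BondTerm(0, 1, k_cc, r_cc),
            BondTerm(1, 2, k_co, r_co),
            BondTerm(2, 3, k_oh, r_oh),
            BondTerm(0, 4, k_ch, r_ch),
            BondTerm(0, 5, k_ch, r_ch),
        ),
        angles=(
            AngleTerm(2, 1, 0, ka, th_cco),
            AngleTerm(3, 2, 1, ka, th_coh),
            AngleTerm(4, 0, 1, ka, th_cch),
            AngleTerm(5, 0, 1, ka, th_cch),
        ),
        torsions=(
            TorsionTerm(3, 2, 1, 0, series=((1, a1, 0.0), (3, a3, 0.0))),
            TorsionTerm(4, 0, 1, 2, series=((3, 0.6, 0.0),)),
        ),
        bond_corrections=(
            (BondCorrection(2, 1.5, 0.12),) if oh_bond_correction else ()
        ),
        torsion_corrections=(
            (TorsionCorrection(0, 1.2, 1, 0.3),) if torsion_correction else ()
        ),
        zmatrix=zmat,
        q_template=q,
        sample_scales=scales,
    )


def toy_hydroxyl_fragment(correction_amplitude: float = 1.5,
                          correction_width: float = 0.12) -> ToySystem:
    """3-atom C-O-H fragment spatially coincident with the hydroxyl group of
    ``toy_ethanol`` (same template positions, force constants, and O-H
    correction), for dataset-combination experiments where a small molecule
    supplies extra coverage of a coordinate it shares with a larger one."""
    eth = toy_ethanol(torsion_correction=False)
    return ToySystem(
        name="toy-hydroxyl-fragment",
        species=("C", "O", "H"),
        template_coords=eth.template_coords[[1, 2, 3]].copy(),
        bonds=(BondTerm(0, 1, 400.0, 1.43), BondTerm(1, 2, 600.0, 0.96)),
        angles=(AngleTerm(0, 1, 2, 70.0, math.radians(108.5)),),
        bond_corrections=(
            BondCorrection(1, correction_amplitude, correction_width),
        ),
        zmatrix=((), (0, 0), (1, 1, 0, 2)),
        q_template=np.array([1.43, 0.96, math.radians(108.5)]),
        sample_scales=np.array(
            [
                math.sqrt(SAMPLING_ENERGY_SCALE / 400.0),
                math.sqrt(SAMPLING_ENERGY_SCALE / 600.0),
                math.sqrt(SAMPLING_ENERGY_SCALE / 70.0),
            ]
        ),
    )


def _ring_geometry(kind: str):
    """Planar ring geometries in the xy-plane.

    ``benzene``: regular C6H6 hexagon.  ``resorcinol``: C6 ring with O at
    two meta positions, ring H on the other four carbons, and in-plane
    hydroxyl hydrogens whose two orientations (±) give four rotamer minima.
    """
    r_ring, r_ch, r_co, r_oh = 1.39, 1.09, 1.36, 0.96
    ring = [
        np.array([r_ring * math.cos(math.radians(60 * k)),
                  r_ring * math.sin(math.radians(60 * k)), 0.0])
        for k in range(6)
    ]
    if kind == "benzene":
        species = ["C"] * 6 + ["H"] * 6
        coords = ring + [p * ((r_ring + r_ch) / r_ring) for p in ring]
        return species, np.array(coords), None
    if kind != "resorcinol":
        raise ValueError(f"unknown ring kind {kind!r}")
    o_sites, h_sites = (0, 2), (1, 3, 4, 5)
    species = ["C"] * 6 + ["O", "O"] + ["H"] * 4 + ["H", "H"]
    coords = list(ring)
    for s in o_sites:
        coords.append(ring[s] * ((r_ring + r_co) / r_ring))
    for s in h_sites:
        coords.append(ring[s] * ((r_ring + r_ch) / r_ring))

    def hydroxyl(site_idx: int, orient: int) -> np.ndarray:
        # in-plane H on the O attached at ring angle 60*site_idx degrees;
        # orient = +1/-1 selects the two planar C-O-H rotamers
        theta_c = math.radians(60 * site_idx)
        opos = ring[site_idx] * ((r_ring + r_co) / r_ring)
        # H direction makes ~71 deg with the O->away-from-C radial direction
        ang = theta_c + orient * math.radians(71.0)
        return opos + r_oh * np.array([math.cos(ang), math.sin(ang), 0.0])

    coords.append(hydroxyl(0, +1))
    coords.append(hydroxyl(2, -1))
    return species, np.array(coords), hydroxyl


def toy_ring(kind: str = "resorcinol") -> ToySystem:
    species, coords, _ = _ring_geometry(kind)
    r_ring, r_ch, r_co, r_oh = 1.39, 1.09, 1.36, 0.96
    bonds = [BondTerm(i, (i + 1) % 6, 500.0, r_ring) for i in range(6)]
    angles = [AngleTerm((i - 1) % 6, i, (i + 1) % 6, 70.0, math.radians(120.0))
              for i in range(6)]
    torsions: list[TorsionTerm] = []
    if kind == "benzene":
        bonds += [BondTerm(i, i + 6, 380.0, r_ch) for i in range(6)]
        corrections = (BondCorrection(0, 1.5, 0.12),)
    else:
        bonds += [BondTerm(0, 6, 450.0, r_co), BondTerm(2, 7, 450.0, r_co)]
        bonds += [BondTerm(s, 8 + m, 380.0, r_ch)
                  for m, s in enumerate((1, 3, 4, 5))]
        bonds += [BondTerm(6, 12, 600.0, r_oh), BondTerm(7, 13, 600.0, r_oh)]
        angles += [AngleTerm(12, 6, 0, 55.0, math.radians(109.0)),
                   AngleTerm(13, 7, 2, 55.0, math.radians(109.0))]
        # hydroxyl torsions: two in-plane minima (phi = 0 and pi)
        torsions = [
            TorsionTerm(12, 6, 0, 1, series=((2, 1.5, 0.0),)),
            TorsionTerm(13, 7, 2, 1, series=((2, 1.5, 0.0),)),
        ]
        corrections = (BondCorrection(6, 1.5, 0.12), BondCorrection(7, 1.5, 0.12))
    return ToySystem(
        name=f"toy-ring-{kind}",
        species=tuple(species),
        template_coords=coords,
        bonds=tuple(bonds),
        angles=tuple(angles),
        torsions=tuple(torsions),
        bond_corrections=corrections,
        cartesian_jitter=0.03,
    )


def ring_rotamer_minima(kind: str = "resorcinol") -> list[Conformer]:
    """The four planar hydroxyl-rotamer minima of the resorcinol-like ring.

    The in-plane C2 operation of the ring framework maps the (+,+) and
    (−,−) rotamers onto each other and fixes the two mixed ones, so the
    orbit of the four minima under the order-4 planar group contains
    exactly these four geometries.
    """
    species, coords, hydroxyl = _ring_geometry(kind)
    if hydroxyl is None:
        raise ValueError("rotamer minima exist only for the resorcinol-like ring")
    out = []
    for s1, s2 in ((+1, -1), (-1, +1), (+1, +1), (-1, -1)):
        c = coords.copy()
        c[12] = hydroxyl(0, s1)
        c[13] = hydroxyl(2, s2)
        out.append(
            Conformer.from_species(species, c, label=f"rotamer{s1:+d}{s2:+d}")
        )
    return out


# ---------------------------------------------------------------------------
# dataset assembly


def make_dataset(
    system: ToySystem,
    n: int,
    gridspec: GridSpec | None = None,
    basis: FourierBasisSpec | None = None,
    density_mode: str = "bonded",
    gamma: float = 0.6,
    spread: float = 1.0,
    seed: int = 0,
    conformers=None,
) -> MolecularDataset:
    """Sample an ensemble and assemble the complete training records:
    potential descriptor, projected density coefficients, and both energy
    labels re-referenced to the lowest low-level energy in the set."""
    if gridspec is None:
        gridspec = system.default_gridspec()
    if basis is None:
        basis = FourierBasisSpec(per_dim=7, box_length=gridspec.box_length)
    if conformers is None:
        conformers = system.sample_conformers(n, spread=spread, seed=seed)
    descriptors, coeffs = [], []
    for c in conformers:
        descriptors.append(gaussian_potential(c, gridspec, gamma).values)
        dens = system.density(c, gridspec, mode=density_mode)
        coeffs.append(project_density(dens, gridspec, basis).u)
    X = np.array([c.coords for c in conformers])
    e_low = np.asarray(system.low_energy(X), float)
    e_high = np.asarray(system.high_energy(X), float)
    shift = float(e_low.min())
    e_low, e_high = e_low - shift, e_high - shift
    for c, lo, hi in zip(conformers, e_low, e_high):
        c.energy = EnergyRecord(float(lo), float(hi), reference_shift=shift)
    return MolecularDataset(
        conformers,
        np.array(descriptors),
        np.array(coeffs),
        e_low,
        e_high,
        basis,
        gridspec,
        gamma,
        shift,
        np.array([system.name] * len(conformers)),
    )
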