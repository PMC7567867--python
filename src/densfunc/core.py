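"""Core domain types: conformers, grids, and energy records.

A :class:`Conformer` is a labelled set of nuclei (element symbols, nuclear
charges, Cartesian coordinates in Å).  Charges default to *valence* electron
counts (H=1, C=4, N=5, O=6), matching a frozen-core convention in which core
electrons are folded into the effective nuclear charge; full atomic numbers
are available via ``charge_mode="full"``.

A :class:`GridSpec` describes the uniform cubic grid on which potentials and
densities are sampled: points sit at ``origin + i * spacing`` for
``i = 0 .. n-1`` along each axis (periodic-box convention, no point at the
far edge), which makes uniform Riemann quadrature exact for band-limited
integrands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valence electron counts under the frozen-core convention.
VALENCE_CHARGES = {"H": 1.0, "C": 4.0, "N": 5.0, "O": 6.0, "F": 7.0, "S": 6.0}

#: Full nuclear charges (atomic numbers).
FULL_CHARGES = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "F": 9.0, "S": 16.0}

#: Standard atomic weights in amu.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "S": 32.06,
}


@dataclass
class EnergyRecord:
    """Energy labels for one conformer, in kcal·mol⁻¹.

    ``e_low`` is the cheap level of theory (e.g. a semilocal DFT functional),
    ``e_high`` the expensive one (e.g. coupled cluster); ``reference_shift``
    is the energy of the lowest conformer in the training set, subtracted
    from both labels before learning and retained for round-trips.
    """

    e_low: float
    e_high: float | None = None
    reference_shift: float = 0.0

    @property
    def delta(self) -> float:
        """High-minus-low correction; requires both labels."""
        if self.e_high is None:
            raise ValueError("delta requires both energy labels")
        d = self.e_high - self.e_low
        if not np.isfinite(d):
            raise ValueError("non-finite energy delta")
        return d


@dataclass
class Conformer:
    """A molecular geometry: element symbols, nuclear charges, coordinates (Å)."""

    species: tuple[str, ...]
    charges: np.ndarray
    coords: np.ndarray
    label: str = ""
    energy: EnergyRecord | None = None

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.charges = np.asarray(self.charges, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.species)
        if self.charges.shape != (n,):
            raise ValueError(
                f"species/charges length mismatch: {n} vs {self.charges.shape}"
            )
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords must be ({n}, 3), got {self.coords.shape}"
            )
        if not np.all(self.charges > 0):
            raise ValueError("all nuclear charges must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_species(
        cls,
        species,
        coords,
        label: str = "",
        charge_mode: str = "valence",
        energy: EnergyRecord | None = None,
    ) -> "Conformer":
        """Build a conformer with charges looked up from the element table."""
        table = VALENCE_CHARGES if charge_mode == "valence" else FULL_CHARGES
        try:
            charges = np.array([table[s] for s in species], dtype=float)
        except KeyError as exc:
            raise KeyError(f"no charge tabulated for element {exc}") from exc
        return cls(tuple(species), charges, np.asarray(coords, float), label, energy)

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted nuclear centroid."""
        return self.coords.mean(axis=0)

    def centered(self) -> "Conformer":
        """Copy translated so the nuclear centroid sits at the origin."""
        return self.with_coords(self.coords - self.centroid)

    def with_coords(self, coords: np.ndarray) -> "Conformer":
        return Conformer(self.species, self.charges.copy(), np.asarray(coords, float),
                         self.label, self.energy)

    def masses(self) -> np.ndarray:
        """Standard atomic weights per atom, amu."""
        return np.array([ATOMIC_MASSES[s] for s in self.species])

    @property
    def n_valence_electrons(self) -> float:
        return float(self.charges.sum())


@dataclass(frozen=True)
class GridSpec:
    """Uniform cubic grid: ``points_per_dim`` samples per axis over a box of
    edge ``box_length`` Å starting at ``origin``."""

    box_length: float
    points_per_dim: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.box_length <= 0 or self.points_per_dim <= 0:
            raise ValueError("box_length and points_per_dim must be positive")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))

    @classmethod
    def centered(cls, box_length: float, points_per_dim: int) -> "GridSpec":
        """Grid whose box is centered on the coordinate origin."""
        h = -0.5 * box_length
        return cls(box_length, points_per_dim, (h, h, h))

    @classmethod
    def symmetric(cls, box_length: float, points_per_dim: int) -> "GridSpec":
        """Centered grid with cell-centered sampling, so the sample-point set
        maps onto itself under axis sign flips and 90° axis rotations —
        lattice-compatible symmetry operations permute field values
        exactly."""
        o = -0.5 * box_length + 0.5 * box_length / points_per_dim
        return cls(box_length, points_per_dim, (o, o, o))

    @property
    def spacing(self) -> float:
        return self.box_length / self.points_per_dim

    @property
    def n_points(self) -> int:
        return self.points_per_dim**3

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D sample coordinates along x, y, z (absolute, Å)."""
        base = np.arange(self.points_per_dim) * self.spacing
        o = np.asarray(self.origin)
        return base + o[0], base + o[1], base + o[2]

    def points(self) -> np.ndarray:
        """All grid points as an (n³, 3) array, z fastest (C order)."""
        ax, ay, az = self.axis_coords()
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def contains(self, coords: np.ndarray, margin: float = 0.0) -> bool:
        """True when every coordinate lies inside the box shrunk by ``margin``."""
        lo = np.asarray(self.origin) + margin
        hi = np.asarray(self.origin) + self.box_length - margin
        c = np.atleast_2d(coords)
        return bool(np.all(c >= lo) and np.all(c <= hi))
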