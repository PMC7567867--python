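"""Readers and writers for the text formats the pipeline touches.

Multi-frame XYZ carries conformer ensembles; energy labels ride along in the
comment line as ``key=value`` pairs (``E_low=… E_high=… shift=…``,
kcal·mol⁻¹).  Grid fields (densities, potentials) are exchanged as Gaussian
cube files; cube headers are in bohr per the format convention, converted at
this boundary only.
"""

from __future__ import annotations

import re

import numpy as np

from .core import Conformer, EnergyRecord, GridSpec, FULL_CHARGES
from .units import BOHR_TO_ANGSTROM


class XYZParseError(ValueError):
    """Malformed XYZ content; message names the offending line."""


def _parse_comment_energies(comment: str) -> EnergyRecord | None:
    pairs = dict(re.findall(r"(\w+)=([-+0-9.eE]+)", comment))
    if "E_low" not in pairs:
        return None
    return EnergyRecord(
        e_low=float(pairs["E_low"]),
        e_high=float(pairs["E_high"]) if "E_high" in pairs else None,
        reference_shift=float(pairs.get("shift", 0.0)),
    )


def read_xyz(path, charge_mode: str = "valence") -> list[Conformer]:
    """Read a (multi-frame) XYZ file into a list of conformers.

    Comment lines are scanned for ``E_low=… E_high=… shift=…`` energy labels,
    attached to each conformer's ``energy`` field when present.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    conformers: list[Conformer] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        species, coords = [], []
        for j in range(natoms):
            k = i + 2 + j
            if k >= len(lines) or not lines[k].strip():
                raise XYZParseError(
                    f"line {k + 1}: frame declares {natoms} atoms but file ends early"
                )
            parts = lines[k].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {k + 1}: expected 'symbol x y z'")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(f"line {k + 1}: non-numeric coordinate")
            species.append(parts[0])
            coords.append(xyz)
        conformers.append(
            Conformer.from_species(
                species,
                np.array(coords),
                label=comment.strip(),
                charge_mode=charge_mode,
                energy=_parse_comment_energies(comment),
            )
        )
        i += 2 + natoms
    return conformers


def write_xyz(conformers, path) -> None:
    """Write conformers as multi-frame XYZ; energies serialize into comments."""
    conformers = list(conformers)
    if not conformers:
        raise ValueError("cannot write an empty conformer sequence")
    with open(path, "w") as fh:
        for c in conformers:
            parts = []
            if c.energy is not None:
                parts.append(f"E_low={c.energy.e_low:.10g}")
                if c.energy.e_high is not None:
                    parts.append(f"E_high={c.energy.e_high:.10g}")
                if c.energy.reference_shift:
                    parts.append(f"shift={c.energy.reference_shift:.10g}")
            if c.label and c.energy is None:
                parts.append(c.label)
            fh.write(f"{c.n_atoms}\n{' '.join(parts)}\n")
            for s, (x, y, z) in zip(c.species, c.coords):
                fh.write(f"{s} {x:.8f} {y:.8f} {z:.8f}\n")


def write_cube(field_values, gridspec: GridSpec, conformer: Conformer, path) -> None:
    """Write a scalar grid field as a Gaussian cube file (header in bohr)."""
    values = np.asarray(field_values, dtype=float).ravel()
    n = gridspec.points_per_dim
    if values.size != gridspec.n_points:
        raise ValueError(
            f"field has {values.size} values, grid expects {gridspec.n_points}"
        )
    sp_bohr = gridspec.spacing / BOHR_TO_ANGSTROM
    origin_bohr = np.asarray(gridspec.origin) / BOHR_TO_ANGSTROM
    with open(path, "w") as fh:
        fh.write("densfunc grid field\n")
        fh.write("generated cube; values in C order, z fastest\n")
        fh.write(
            f"{conformer.n_atoms:5d} {origin_bohr[0]:12.6f} "
            f"{origin_bohr[1]:12.6f} {origin_bohr[2]:12.6f}\n"
        )
        for d in range(3):
            vec = [0.0, 0.0, 0.0]
            vec[d] = sp_bohr
            fh.write(f"{n:5d} {vec[0]:12.6f} {vec[1]:12.6f} {vec[2]:12.6f}\n")
        for s, q, (x, y, z) in zip(conformer.species, conformer.charges, conformer.coords):
            zint = int(FULL_CHARGES.get(s, q))
            xb, yb, zb = np.array([x, y, z]) / BOHR_TO_ANGSTROM
            fh.write(f"{zint:5d} {q:12.6f} {xb:12.6f} {yb:12.6f} {zb:12.6f}\n")
        grid = values.reshape(n, n, n)
        for ix in range(n):
            for iy in range(n):
                row = grid[ix, iy]
                for start in range(0, n, 6):
                    fh.write(
                        " ".join(f"{v: .6e}" for v in row[start : start + 6]) + "\n"
                    )


def read_cube(path):
    """Read a Gaussian cube file; returns ``(values, gridspec, conformer)``.

    Only axis-aligned cubic grids (the only kind this package writes) are
    supported.
    """
    with open(path) as fh:
        fh.readline()
        fh.readline()
        natoms_line = fh.readline().split()
        natoms = int(natoms_line[0])
        origin = np.array([float(x) for x in natoms_line[1:4]]) * BOHR_TO_ANGSTROM
        ns, spacings = [], []
        for d in range(3):
            parts = fh.readline().split()
            ns.append(int(parts[0]))
            spacings.append(float(parts[1 + d]) * BOHR_TO_ANGSTROM)
        if len(set(ns)) != 1 or abs(spacings[0] - spacings[1]) > 1e-9 or abs(
            spacings[0] - spacings[2]
        ) > 1e-9:
            raise ValueError("only cubic grids are supported")
        n = ns[0]
        species, charges, coords = [], [], []
        inv_full = {int(v): k for k, v in FULL_CHARGES.items()}
        for _ in range(natoms):
            parts = fh.readline().split()
            species.append(inv_full.get(int(parts[0]), "X"))
            charges.append(float(parts[1]))
            coords.append([float(x) * BOHR_TO_ANGSTROM for x in parts[2:5]])
        values = np.fromstring(fh.read(), sep=" ")
    if values.size != n**3:
        raise ValueError(f"expected {n ** 3} voxel values, found {values.size}")
    gridspec = GridSpec(box_length=spacings[0] * n, points_per_dim=n, origin=tuple(origin))
    conformer = Conformer(tuple(species), np.array(charges), np.array(coords))
    return values, gridspec, conformer
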