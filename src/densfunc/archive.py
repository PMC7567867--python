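"""HDF5 archives for datasets and fitted maps.

One archive layout covers the three persistent objects: a
:class:`~densfunc.maps.MolecularDataset`, an :class:`~densfunc.maps.HKMap`,
and an :class:`~densfunc.maps.EnergyMap`.  Hyperparameters travel as HDF5
attributes so a loaded model carries its full provenance.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .basis import FourierBasisSpec
from .core import Conformer, EnergyRecord, GridSpec
from .krr import KernelSpec, KRRModel
from .maps import EnergyMap, HKMap, MolecularDataset


def _write_basis(grp, basis: FourierBasisSpec) -> None:
    grp.attrs["basis"] = json.dumps(
        {
            "per_dim": basis.per_dim,
            "box_length": basis.box_length,
            "mode": basis.mode,
            "max_total_freq": basis.max_total_freq,
        }
    )


def _read_basis(grp) -> FourierBasisSpec:
    d = json.loads(grp.attrs["basis"])
    return FourierBasisSpec(**d)


def _write_gridspec(grp, gridspec: GridSpec) -> None:
    grp.attrs["gridspec"] = json.dumps(
        {
            "box_length": gridspec.box_length,
            "points_per_dim": gridspec.points_per_dim,
            "origin": list(gridspec.origin),
        }
    )


def _read_gridspec(grp) -> GridSpec:
    d = json.loads(grp.attrs["gridspec"])
    return GridSpec(d["box_length"], d["points_per_dim"], tuple(d["origin"]))


def save_dataset(dataset: MolecularDataset, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("dataset")
        _write_basis(g, dataset.basis)
        _write_gridspec(g, dataset.gridspec)
        g.attrs["gamma"] = dataset.gamma
        g.attrs["reference_shift"] = dataset.reference_shift
        g.create_dataset("descriptors", data=dataset.descriptors)
        g.create_dataset("coefficients", data=dataset.coefficients)
        g.create_dataset("e_low", data=dataset.e_low)
        if dataset.e_high is not None:
            g.create_dataset("e_high", data=dataset.e_high)
        g.create_dataset(
            "provenance", data=np.array(dataset.provenance, dtype="S64")
        )
        g.create_dataset(
            "species",
            data=np.array(
                ["|".join(c.species) for c in dataset.conformers], dtype="S256"
            ),
        )
        g.create_dataset(
            "coords", data=np.array([c.coords for c in dataset.conformers])
        )
        g.create_dataset(
            "charges", data=np.array([c.charges for c in dataset.conformers])
        )


def load_dataset(path) -> MolecularDataset:
    with h5py.File(path, "r") as f:
        g = f["dataset"]
        basis = _read_basis(g)
        gridspec = _read_gridspec(g)
        species = [s.decode().split("|") for s in g["species"][()]]
        coords = g["coords"][()]
        charges = g["charges"][()]
        e_low = g["e_low"][()]
        e_high = g["e_high"][()] if "e_high" in g else None
        shift = float(g.attrs["reference_shift"])
        conformers = []
        for i in range(len(species)):
            rec = EnergyRecord(
                float(e_low[i]),
                None if e_high is None else float(e_high[i]),
                reference_shift=shift,
            )
            conformers.append(
                Conformer(tuple(species[i]), charges[i], coords[i], energy=rec)
            )
        return MolecularDataset(
            conformers,
            g["descriptors"][()],
            g["coefficients"][()],
            e_low,
            e_high,
            basis,
            gridspec,
            float(g.attrs["gamma"]),
            shift,
            np.array([p.decode() for p in g["provenance"][()]]),
        )


def save_hk_map(hkmap: HKMap, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("hk_map")
        _write_basis(g, hkmap.basis)
        _write_gridspec(g, hkmap.gridspec)
        g.attrs["gamma"] = hkmap.gamma
        g.attrs["sigma"] = hkmap.kernel.sigma
        g.attrs["regularization"] = hkmap.regularization
        g.create_dataset("train_descriptors", data=hkmap.train_descriptors)
        g.create_dataset("beta", data=hkmap.beta)
        g.create_dataset("priors", data=hkmap.priors)


def load_hk_map(path) -> HKMap:
    with h5py.File(path, "r") as f:
        g = f["hk_map"]
        return HKMap(
            g["train_descriptors"][()],
            g["beta"][()],
            KernelSpec(sigma=float(g.attrs["sigma"])),
            float(g.attrs["regularization"]),
            g["priors"][()],
            _read_basis(g),
            _read_gridspec(g),
            float(g.attrs["gamma"]),
        )


def save_energy_map(energy_map: EnergyMap, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("energy_map")
        g.attrs["label_kind"] = energy_map.label_kind
        g.attrs["training_reference"] = energy_map.training_reference
        g.attrs["sigma"] = energy_map.model.kernel.sigma
        g.attrs["regularization"] = energy_map.model.regularization
        g.attrs["prior_mean"] = energy_map.model.prior_mean
        if energy_map.basis is not None:
            _write_basis(g, energy_map.basis)
        g.create_dataset("train_inputs", data=energy_map.model.train_inputs)
        g.create_dataset("dual_coefficients", data=energy_map.model.dual_coefficients)


def load_energy_map(path) -> EnergyMap:
    with h5py.File(path, "r") as f:
        g = f["energy_map"]
        model = KRRModel(
            KernelSpec(sigma=float(g.attrs["sigma"])),
            g["train_inputs"][()],
            g["dual_coefficients"][()],
            float(g.attrs["regularization"]),
            float(g.attrs["prior_mean"]),
        )
        basis = _read_basis(g) if "basis" in g.attrs else None
        return EnergyMap(
            model,
            str(g.attrs["label_kind"]),
            float(g.attrs["training_reference"]),
            basis,
        )
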