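"""The learned functionals: potential→density and density→energy maps.

Three maps make up the pipeline:

* the Hohenberg-Kohn (HK) map — one kernel ridge regression per density
  basis coefficient, all sharing a single Gram matrix over Gaussian
  nuclear-potential descriptors, predicting u[v] from a conformer;
* direct energy maps E_ML[u] at either level of theory — KRR over
  coefficient vectors with a training-mean prior;
* the Δ-correction map — KRR on E_high − E_low with a *zero* prior, so that
  the corrected total energy E_low + ΔE_ML(u) falls back on the low-level
  result far from the training set.

Datasets from different molecules sharing one box/basis/descriptor
configuration can be concatenated (with per-record provenance preserved) to
train combined maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import DensityCoefficients, FourierBasisSpec
from .core import Conformer, GridSpec
from .krr import (
    KernelSpec,
    KRRModel,
    default_regularization,
    fit_krr,
    kernel_matrix,
    predict_krr,
)
from .potential import gaussian_potential
from scipy.linalg import cho_factor, cho_solve


@dataclass
class MolecularDataset:
    """Archive-ready training records for one (or several) molecules.

    Rows are conformers; ``descriptors`` holds flattened potential fields,
    ``coefficients`` the projected density coefficient vectors, and the
    energies are stored relative to ``reference_shift`` (the lowest low-level
    energy in the set).  ``provenance`` tags each record with its source
    molecule so per-molecule test errors stay computable after combination.
    """

    conformers: list[Conformer]
    descriptors: np.ndarray
    coefficients: np.ndarray
    e_low: np.ndarray
    e_high: np.ndarray | None
    basis: FourierBasisSpec
    gridspec: GridSpec
    gamma: float
    reference_shift: float = 0.0
    provenance: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.conformers)
        self.descriptors = np.atleast_2d(np.asarray(self.descriptors, float))
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, float))
        self.e_low = np.asarray(self.e_low, float).ravel()
        if self.e_high is not None:
            self.e_high = np.asarray(self.e_high, float).ravel()
        if self.provenance is None:
            self.provenance = np.array(["" for _ in range(n)])
        else:
            self.provenance = np.asarray(self.provenance)
        sizes = {self.descriptors.shape[0], self.coefficients.shape[0],
                 self.e_low.size, n, self.provenance.size}
        if self.e_high is not None:
            sizes.add(self.e_high.size)
        if len(sizes) != 1:
            raise ValueError("inconsistent record counts across dataset fields")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def delta(self) -> np.ndarray:
        if self.e_high is None:
            raise ValueError("dataset has no high-level labels")
        return self.e_high - self.e_low

    def subset(self, indices) -> "MolecularDataset":
        idx = np.asarray(indices, int)
        return MolecularDataset(
            [self.conformers[i] for i in idx],
            self.descriptors[idx],
            self.coefficients[idx],
            self.e_low[idx],
            None if self.e_high is None else self.e_high[idx],
            self.basis,
            self.gridspec,
            self.gamma,
            self.reference_shift,
            self.provenance[idx],
        )


def _config_matches(a: MolecularDataset, b: MolecularDataset) -> bool:
    return (
        a.basis == b.basis
        and a.gridspec == b.gridspec
        and abs(a.gamma - b.gamma) < 1e-12
    )


def combine_datasets(*datasets: MolecularDataset) -> MolecularDataset:
    """Concatenate datasets sharing one basis/grid/descriptor configuration.

    Energies are re-referenced to the lowest low-level energy of the combined
    set so labels from different molecules stay on one scale.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    first = datasets[0]
    for d in datasets[1:]:
        if not _config_matches(first, d):
            raise ValueError("datasets have mismatched basis/grid/gamma configs")
    has_high = all(d.e_high is not None for d in datasets)
    # restore absolute energies, then re-reference jointly
    abs_low = np.concatenate([d.e_low + d.reference_shift for d in datasets])
    shift = float(abs_low.min())
    e_high = None
    if has_high:
        e_high = np.concatenate(
            [d.e_high + d.reference_shift for d in datasets]) - shift
    return MolecularDataset(
        [c for d in datasets for c in d.conformers],
        np.vstack([d.descriptors for d in datasets]),
        np.vstack([d.coefficients for d in datasets]),
        abs_low - shift,
        e_high,
        first.basis,
        first.gridspec,
        first.gamma,
        shift,
        np.concatenate([d.provenance for d in datasets]),
    )


@dataclass
class HKMap:
    """Potential→density map: L per-coefficient KRR models sharing one Gram
    matrix over potential descriptors (dual coefficients stacked as the
    columns of ``beta``)."""

    train_descriptors: np.ndarray
    beta: np.ndarray
    kernel: KernelSpec
    regularization: float
    priors: np.ndarray
    basis: FourierBasisSpec
    gridspec: GridSpec
    gamma: float

    @property
    def n_coefficients(self) -> int:
        return self.beta.shape[1]


def fit_hk_map(
    descriptors,
    coefficient_matrix,
    kernel: KernelSpec,
    lam: float | None = None,
    basis: FourierBasisSpec | None = None,
    gridspec: GridSpec | None = None,
    gamma: float | None = None,
    prior_mean_mode: str = "train_mean",
) -> HKMap:
    """Fit all per-coefficient density regressions against one factorization.

    (K + λI) is factorized once and solved for every coefficient column —
    the per-coefficient models are independent but share kernel and inputs.
    """
    X = np.atleast_2d(np.asarray(descriptors, float))
    U = np.atleast_2d(np.asarray(coefficient_matrix, float))
    if X.shape[0] != U.shape[0]:
        raise ValueError("one coefficient row per descriptor row is required")
    K = kernel_matrix(X, X, kernel.sigma)
    if lam is None:
        lam = default_regularization(K)
    if prior_mean_mode == "train_mean":
        priors = U.mean(axis=0)
    elif prior_mean_mode == "zero":
        priors = np.zeros(U.shape[1])
    else:
        raise ValueError(f"unknown prior_mean_mode {prior_mean_mode!r}")
    A = K + lam * np.eye(K.shape[0])
    beta = cho_solve(cho_factor(A), U - priors)
    return HKMap(X, beta, kernel, float(lam), priors, basis, gridspec, gamma)


def fit_hk_map_from_dataset(
    dataset: MolecularDataset, kernel: KernelSpec, lam: float | None = None
) -> HKMap:
    return fit_hk_map(
        dataset.descriptors,
        dataset.coefficients,
        kernel,
        lam=lam,
        basis=dataset.basis,
        gridspec=dataset.gridspec,
        gamma=dataset.gamma,
    )


def predict_density(hkmap: HKMap, conformer: Conformer) -> DensityCoefficients:
    """Predict the density coefficients of a conformer through the HK map."""
    if hkmap.gridspec is None or hkmap.gamma is None:
        raise ValueError("HK map lacks descriptor configuration")
    field = gaussian_potential(conformer, hkmap.gridspec, hkmap.gamma)
    u = predict_density_from_descriptor(hkmap, field.values)
    return DensityCoefficients(u, hkmap.basis)


def predict_density_from_descriptor(hkmap: HKMap, descriptor) -> np.ndarray:
    v = np.asarray(descriptor, float).ravel()
    if v.size != hkmap.train_descriptors.shape[1]:
        raise ValueError("descriptor length does not match the HK map grid")
    k = kernel_matrix(v[None, :], hkmap.train_descriptors, hkmap.kernel.sigma)
    return (k @ hkmap.beta).ravel() + hkmap.priors


@dataclass
class EnergyMap:
    """Density-coefficient → energy KRR model at one label kind
    ("low", "high", or "delta"; "delta" models carry a zero prior)."""

    model: KRRModel
    label_kind: str
    training_reference: float = 0.0
    basis: FourierBasisSpec | None = None


def fit_energy_map(
    coefficient_vectors,
    energies,
    label_kind: str,
    kernel: KernelSpec,
    lam: float | None = None,
    basis: FourierBasisSpec | None = None,
    training_reference: float = 0.0,
) -> EnergyMap:
    """KRR over density coefficient vectors.

    Correction ("delta") maps use a zero prior mean so predictions decay to
    no correction away from the data; direct maps revert to the training
    mean instead.
    """
    if label_kind not in ("low", "high", "delta"):
        raise ValueError(f"unknown label_kind {label_kind!r}")
    prior_mode = "zero" if label_kind == "delta" else "train_mean"
    model = fit_krr(coefficient_vectors, energies, kernel, lam=lam,
                    prior_mean_mode=prior_mode)
    return EnergyMap(model, label_kind, training_reference, basis)


def _coeff_vector(energy_map: EnergyMap, coefficients) -> np.ndarray:
    if isinstance(coefficients, DensityCoefficients):
        if energy_map.basis is not None and coefficients.basis != energy_map.basis:
            raise ValueError("coefficient basis does not match the energy map")
        return coefficients.u
    return np.asarray(coefficients, float).ravel()


def predict_energy(energy_map: EnergyMap, coefficients) -> float:
    """E(u) = Σ_i α_i k(u, u_i) + prior, in kcal·mol⁻¹."""
    return float(predict_krr(energy_map.model, _coeff_vector(energy_map, coefficients)))


def delta_dft_total_energy(
    e_low: float, delta_map: EnergyMap, coefficients
) -> float:
    """Corrected total energy: the low-level energy plus the learned
    high−low correction evaluated on the density coefficients."""
    if delta_map.label_kind != "delta":
        raise ValueError("delta_dft_total_energy requires a delta-kind map")
    return float(e_low) + predict_energy(delta_map, coefficients)
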