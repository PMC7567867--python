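"""Gaussian approximation to the external nuclear potential.

The descriptor for the potential-to-density (Hohenberg-Kohn) map is the
nuclear potential smeared with Gaussians of width γ and sampled on a cubic
grid:

    v(r) = Σ_α Z_α exp(−‖r − R_α‖² / (2γ²))

Each atomic term is an isotropic Gaussian, so the field factorizes along the
grid axes and is accumulated as an outer product of three 1D profiles per
atom — exact, and far cheaper than evaluating every voxel-atom pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Conformer, GridSpec

logger = logging.getLogger(__name__)


@dataclass
class GaussianPotentialField:
    """Flattened grid samples of the Gaussian nuclear potential (C order,
    z fastest), with the width γ (Å) and grid that produced them."""

    values: np.ndarray
    gamma: float
    gridspec: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.gridspec.n_points:
            raise ValueError("field size does not match grid")


def gaussian_potential(
    conformer: Conformer, gridspec: GridSpec, gamma: float
) -> GaussianPotentialField:
    """Evaluate the Z-weighted Gaussian potential of a conformer on a grid."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not gridspec.contains(conformer.coords, margin=3.0 * gamma):
        logger.warning(
            "conformer %s closer than 3*gamma to the box boundary; "
            "descriptor tails will be clipped",
            conformer.label or "<unnamed>",
        )
        if not gridspec.contains(conformer.coords):
            logger.warning("atoms lie outside the descriptor grid box")
    ax, ay, az = gridspec.axis_coords()
    n = gridspec.points_per_dim
    field = np.zeros((n, n, n))
    inv = 1.0 / (2.0 * gamma * gamma)
    for Z, (Rx, Ry, Rz) in zip(conformer.charges, conformer.coords):
        gx = np.exp(-((ax - Rx) ** 2) * inv)
        gy = np.exp(-((ay - Ry) ** 2) * inv)
        gz = np.exp(-((az - Rz) ** 2) * inv)
        field += Z * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return GaussianPotentialField(field.ravel(), gamma, gridspec)


def descriptor_distance(
    field_a: GaussianPotentialField, field_b: GaussianPotentialField
) -> float:
    """Euclidean distance between two potential fields on the same grid."""
    if field_a.gridspec != field_b.gridspec:
        raise ValueError("descriptor grids differ")
    if abs(field_a.gamma - field_b.gamma) > 1e-12:
        raise ValueError("descriptor widths differ")
    return float(np.linalg.norm(field_a.values - field_b.values))
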