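"""Orthonormal real Fourier basis for electron densities.

Densities are represented by coefficient vectors u in an orthonormal
trigonometric basis on the cubic box [0, L)³:

    n(r) = Σ_l u_l φ_l(r),     φ_l(r) = f_{j1}(x) f_{j2}(y) f_{j3}(z)

with 1D factors f_0 = 1/√L, f_{2k-1} = √(2/L)·cos(2πk x/L),
f_{2k} = √(2/L)·sin(2πk x/L).  A real (rather than complex-exponential)
basis spans the same band-limited space while keeping coefficients — and the
per-coefficient kernel regressions built on them — purely real.

Two index sets are supported: ``"tensor"`` keeps the full per_dim³ product;
``"ball"`` keeps tensor functions whose 1D frequencies sum to at most
``max_total_freq``, for trimming the coefficient budget.  Basis functions are
ordered by total frequency, then lexicographically by 1D index, so u_0 always
multiplies the constant function and carries the electron-count integral.

Projection from grid samples uses the plain voxel Riemann sum, which on a
uniform periodic-box grid is exact (to rounding) for integrands below the
Nyquist frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GridSpec


def _index_triples(per_dim: int, mode: str, max_total_freq: int | None):
    freqs_1d = [(j + 1) // 2 for j in range(per_dim)]
    triples = []
    for j1 in range(per_dim):
        for j2 in range(per_dim):
            for j3 in range(per_dim):
                ftot = freqs_1d[j1] + freqs_1d[j2] + freqs_1d[j3]
                if mode == "ball" and ftot > max_total_freq:
                    continue
                triples.append((ftot, j1, j2, j3))
    triples.sort()
    arr = np.array([(j1, j2, j3) for _, j1, j2, j3 in triples], dtype=int)
    return arr


@dataclass(frozen=True)
class FourierBasisSpec:
    """Real trigonometric basis on [0, box_length)³.

    ``per_dim`` 1D functions per axis (an odd count pairs every cosine with
    its sine); ``mode`` selects the full tensor product or a total-frequency
    ball with cutoff ``max_total_freq`` (default (per_dim−1)//2).
    """

    per_dim: int
    box_length: float
    mode: str = "tensor"
    max_total_freq: int | None = None

    def __post_init__(self) -> None:
        if self.per_dim < 1 or self.box_length <= 0:
            raise ValueError("per_dim and box_length must be positive")
        if self.mode not in ("tensor", "ball"):
            raise ValueError(f"unknown basis mode {self.mode!r}")
        if self.mode == "ball" and self.max_total_freq is None:
            object.__setattr__(self, "max_total_freq", (self.per_dim - 1) // 2)

    @property
    def max_freq_1d(self) -> int:
        return self.per_dim // 2

    def indices(self) -> np.ndarray:
        """(L, 3) array of 1D function indices per 3D basis function."""
        return _index_triples(self.per_dim, self.mode, self.max_total_freq)

    @property
    def size(self) -> int:
        if self.mode == "tensor":
            return self.per_dim**3
        return len(self.indices())

    def eval_1d(self, x: np.ndarray) -> np.ndarray:
        """All 1D factors at box coordinates x: shape (len(x), per_dim)."""
        L = self.box_length
        x = np.asarray(x, dtype=float)
        out = np.empty((x.size, self.per_dim))
        out[:, 0] = 1.0 / np.sqrt(L)
        amp = np.sqrt(2.0 / L)
        for j in range(1, self.per_dim):
            k = (j + 1) // 2
            phase = 2.0 * np.pi * k * x / L
            out[:, j] = amp * (np.cos(phase) if j % 2 == 1 else np.sin(phase))
        return out


@dataclass
class DensityCoefficients:
    """Coefficient vector u of a density in a :class:`FourierBasisSpec`."""

    u: np.ndarray
    basis: FourierBasisSpec

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).ravel()
        if self.u.size != self.basis.size:
            raise ValueError(
                f"coefficient vector length {self.u.size} does not match "
                f"basis size {self.basis.size}"
            )
        if not np.all(np.isfinite(self.u)):
            raise ValueError("coefficients must be finite")


def _to_box_coords(points, basis: FourierBasisSpec, origin) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if origin is not None:
        pts = pts - np.asarray(origin, dtype=float)
    L = basis.box_length
    if np.any(pts < -1e-9) or np.any(pts > L + 1e-9):
        raise ValueError("points outside the basis box")
    return pts


def evaluate_basis(basis: FourierBasisSpec, points, origin=None) -> np.ndarray:
    """Matrix of φ_l at given points: one row per point, one column per
    basis function.  ``origin`` maps absolute coordinates into the box."""
    pts = _to_box_coords(points, basis, origin)
    bx = basis.eval_1d(pts[:, 0])
    by = basis.eval_1d(pts[:, 1])
    bz = basis.eval_1d(pts[:, 2])
    idx = basis.indices()
    return bx[:, idx[:, 0]] * by[:, idx[:, 1]] * bz[:, idx[:, 2]]


def _check_nyquist(basis: FourierBasisSpec, gridspec: GridSpec) -> None:
    if abs(basis.box_length - gridspec.box_length) > 1e-9:
        raise ValueError("basis box and grid box differ")
    fmax = basis.max_freq_1d
    if 2 * fmax >= gridspec.points_per_dim:
        raise ValueError(
            f"Nyquist violation: 1D frequency {fmax} needs more than "
            f"{gridspec.points_per_dim} grid points per dimension"
        )


def _grid_factors(basis: FourierBasisSpec, gridspec: GridSpec):
    origin = np.asarray(gridspec.origin)
    ax, ay, az = gridspec.axis_coords()
    return (
        basis.eval_1d(ax - origin[0]),
        basis.eval_1d(ay - origin[1]),
        basis.eval_1d(az - origin[2]),
    )


def project_density(
    grid_values, gridspec: GridSpec, basis: FourierBasisSpec
) -> DensityCoefficients:
    """Project grid samples of a density onto the basis by voxel-weighted
    quadrature: u_l = Δv Σ_r n(r) φ_l(r)."""
    _check_nyquist(basis, gridspec)
    n = gridspec.points_per_dim
    vals = np.asarray(grid_values, dtype=float).reshape(n, n, n)
    bx, by, bz = _grid_factors(basis, gridspec)
    # separable contraction of the full tensor-product table
    t = np.einsum("xyz,xa->ayz", vals, bx)
    t = np.einsum("ayz,yb->abz", t, by)
    t = np.einsum("abz,zc->abc", t, bz)
    idx = basis.indices()
    u = gridspec.voxel_volume * t[idx[:, 0], idx[:, 1], idx[:, 2]]
    return DensityCoefficients(u, basis)


def reconstruct_density(
    coefficients: DensityCoefficients, points, origin=None
) -> np.ndarray:
    """Continuous density n(r) = Σ_l u_l φ_l(r) at arbitrary points."""
    B = evaluate_basis(coefficients.basis, points, origin=origin)
    return B @ coefficients.u


def reconstruct_on_grid(
    coefficients: DensityCoefficients, gridspec: GridSpec
) -> np.ndarray:
    """Density reconstructed on every grid point (flattened, C order)."""
    basis = coefficients.basis
    if abs(basis.box_length - gridspec.box_length) > 1e-9:
        raise ValueError("basis box and grid box differ")
    idx = basis.indices()
    per = basis.per_dim
    C = np.zeros((per, per, per))
    C[idx[:, 0], idx[:, 1], idx[:, 2]] = coefficients.u
    bx, by, bz = _grid_factors(basis, gridspec)
    t = np.einsum("abc,xa->xbc", C, bx)
    t = np.einsum("xbc,yb->xyc", t, by)
    t = np.einsum("xyc,zc->xyz", t, bz)
    return t.ravel()


def integrate_density(coefficients: DensityCoefficients) -> float:
    """Box integral of the density — the electron count.

    Only the constant basis function integrates to a nonzero value, so the
    integral is u_0 · L^{3/2}.
    """
    L = coefficients.basis.box_length
    return float(coefficients.u[0] * L**1.5)
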