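"""Forces and molecular dynamics on learned energy surfaces.

An energy surface is any callable mapping positions (N, 3) in Å to an energy
in kcal·mol⁻¹; a callable that additionally accepts a batch (B, N, 3) and
returns (B,) speeds up the finite-difference force stencils, but is not
required.  Forces default to central finite differences with ε = 0.001 Å —
model-agnostic, exact for quadratics, and second-order accurate otherwise.

Integrators: velocity Verlet (NVE), BAOAB-splitting Langevin at a target
temperature, and an impulse (r-RESPA) multiple-time-step scheme that
propagates on a cheap reference surface while applying the force difference
to a more accurate surface as symmetric half-kicks every ``n_inner`` steps —
time-reversible by construction, and collapsing to plain NVE on the accurate
surface when ``n_inner`` is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import Conformer
from .units import FORCE_TO_ACCEL, KB_KCAL_MOL_K, KINETIC_TO_KCAL

#: Abort threshold for a diverging trajectory, kcal·mol⁻¹.
ENERGY_DIVERGENCE_BOUND = 1e8


@dataclass
class MDState:
    """Instantaneous phase-space point: positions (Å), velocities (Å·fs⁻¹),
    masses (amu), time (fs)."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        self.masses = np.asarray(self.masses, float).ravel()
        if self.positions.shape != self.velocities.shape or \
                self.positions.shape[0] != self.masses.size:
            raise ValueError("inconsistent state shapes")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    def copy(self) -> "MDState":
        return MDState(self.positions.copy(), self.velocities.copy(),
                       self.masses.copy(), self.time)


@dataclass
class IntegratorParams:
    """MD settings: 0.5 fs timestep, 350 K Langevin target with friction
    0.413 fs⁻¹ (= 0.01 atomic units), finite-difference ε = 0.001 Å, and
    RESPA correction every 3 inner steps."""

    dt: float = 0.5
    temperature: float = 350.0
    friction: float = 0.413
    fd_epsilon: float = 0.001
    n_inner: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.fd_epsilon <= 0 or self.n_inner < 1:
            raise ValueError("dt, fd_epsilon must be positive and n_inner >= 1")
        if self.friction < 0:
            raise ValueError("friction must be nonnegative")


@dataclass
class Trajectory:
    """Recorded frames of an MD run (positions/velocities per frame, fs
    timestamps, potential/kinetic/total energies in kcal·mol⁻¹)."""

    positions: np.ndarray
    velocities: np.ndarray
    times: np.ndarray
    e_pot: np.ndarray
    e_kin: np.ndarray

    @property
    def e_tot(self) -> np.ndarray:
        return self.e_pot + self.e_kin

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def _as_positions(conformer_or_positions) -> np.ndarray:
    if isinstance(conformer_or_positions, Conformer):
        return conformer_or_positions.coords
    return np.asarray(conformer_or_positions, float)


def _energy_batch(energy_fn, stack: np.ndarray) -> np.ndarray:
    """Evaluate a (B, N, 3) stack, using the callable's batch path if it has
    one and falling back to a loop otherwise."""
    try:
        out = np.asarray(energy_fn(stack), float)
        if out.shape == (stack.shape[0],):
            return out
    except Exception:
        pass
    return np.array([float(energy_fn(x)) for x in stack])


def finite_difference_forces(
    energy_fn, conformer_or_positions, fd_epsilon: float = 0.001
) -> np.ndarray:
    """Central-difference forces F = −∂E/∂x, kcal·mol⁻¹·Å⁻¹ (6N energy
    evaluations)."""
    x = _as_positions(conformer_or_positions)
    n = x.shape[0]
    eps = float(fd_epsilon)
    if eps <= 0:
        raise ValueError("fd_epsilon must be positive")
    stack = np.repeat(x[None, :, :], 6 * n, axis=0)
    m = 0
    for i in range(n):
        for d in range(3):
            stack[m, i, d] += eps
            stack[m + 1, i, d] -= eps
            m += 2
    energies = _energy_batch(energy_fn, stack)
    if not np.all(np.isfinite(energies)):
        raise ValueError("non-finite energy in finite-difference stencil")
    diffs = energies[0::2] - energies[1::2]
    return -(diffs / (2.0 * eps)).reshape(n, 3)


def kinetic_energy(state: MDState) -> float:
    """½ Σ m v², converted to kcal·mol⁻¹."""
    ke = 0.5 * np.sum(state.masses[:, None] * state.velocities**2)
    return float(ke * KINETIC_TO_KCAL)


def instantaneous_temperature(state: MDState) -> float:
    """Kinetic temperature from equipartition over 3N degrees of freedom."""
    dof = 3 * state.masses.size
    return 2.0 * kinetic_energy(state) / (dof * KB_KCAL_MOL_K)


class _Recorder:
    def __init__(self):
        self.pos, self.vel, self.t, self.ep, self.ek = [], [], [], [], []

    def add(self, state: MDState, e_pot: float) -> None:
        if not np.isfinite(e_pot) or abs(e_pot) > ENERGY_DIVERGENCE_BOUND:
            raise RuntimeError(
                f"trajectory diverged: potential energy {e_pot} at t={state.time} fs"
            )
        self.pos.append(state.positions.copy())
        self.vel.append(state.velocities.copy())
        self.t.append(state.time)
        self.ep.append(e_pot)
        self.ek.append(kinetic_energy(state))

    def trajectory(self) -> Trajectory:
        return Trajectory(
            np.array(self.pos), np.array(self.vel), np.array(self.t),
            np.array(self.ep), np.array(self.ek),
        )


def _make_force_fn(energy_fn, params: IntegratorParams, force_fn=None):
    if force_fn is not None:
        return force_fn
    return lambda x: finite_difference_forces(energy_fn, x, params.fd_epsilon)


def nve_trajectory(
    energy_fn, state: MDState, params: IntegratorParams, n_steps: int,
    force_fn=None,
) -> Trajectory:
    """Velocity-Verlet microcanonical propagation."""
    forces = _make_force_fn(energy_fn, params, force_fn)
    s = state.copy()
    rec = _Recorder()
    rec.add(s, float(energy_fn(s.positions)))
    f = forces(s.positions)
    inv_m = FORCE_TO_ACCEL / s.masses[:, None]
    dt = params.dt
    for _ in range(n_steps):
        s.velocities = s.velocities + 0.5 * dt * f * inv_m
        s.positions = s.positions + dt * s.velocities
        f = forces(s.positions)
        s.velocities = s.velocities + 0.5 * dt * f * inv_m
        s.time += dt
        rec.add(s, float(energy_fn(s.positions)))
    return rec.trajectory()


def langevin_trajectory(
    energy_fn, state: MDState, params: IntegratorParams, n_steps: int,
    force_fn=None,
) -> Trajectory:
    """BAOAB-splitting Langevin thermostat; bitwise-reproducible under a
    fixed seed, and identical to velocity Verlet at zero friction."""
    forces = _make_force_fn(energy_fn, params, force_fn)
    rng = np.random.default_rng(params.seed)
    s = state.copy()
    rec = _Recorder()
    rec.add(s, float(energy_fn(s.positions)))
    f = forces(s.positions)
    inv_m = FORCE_TO_ACCEL / s.masses[:, None]
    dt = params.dt
    gamma = params.friction
    c1 = np.exp(-gamma * dt)
    # thermal velocity scale per atom, Å·fs⁻¹
    sigma_v = np.sqrt(
        KB_KCAL_MOL_K * params.temperature * FORCE_TO_ACCEL / s.masses
    )[:, None]
    c2 = np.sqrt(1.0 - c1 * c1)
    for _ in range(n_steps):
        s.velocities = s.velocities + 0.5 * dt * f * inv_m          # B
        s.positions = s.positions + 0.5 * dt * s.velocities         # A
        if gamma > 0:                                               # O
            noise = rng.standard_normal(s.velocities.shape)
            s.velocities = c1 * s.velocities + c2 * sigma_v * noise
        s.positions = s.positions + 0.5 * dt * s.velocities         # A
        f = forces(s.positions)
        s.velocities = s.velocities + 0.5 * dt * f * inv_m          # B
        s.time += dt
        rec.add(s, float(energy_fn(s.positions)))
    return rec.trajectory()


def respa_trajectory(
    reference_energy_fn,
    accurate_energy_fn,
    state: MDState,
    params: IntegratorParams,
    n_steps: int,
    reference_force_fn=None,
    accurate_force_fn=None,
) -> Trajectory:
    """Impulse (r-RESPA) multiple-time-step NVE propagation.

    Inner velocity-Verlet steps use cheap reference forces; every
    ``params.n_inner`` steps the force difference (accurate − reference) is
    applied as symmetric half-kicks scaled to the outer timestep.  Recorded
    potential energies are the accurate surface's.
    """
    ref_forces = _make_force_fn(reference_energy_fn, params, reference_force_fn)
    acc_forces = _make_force_fn(accurate_energy_fn, params, accurate_force_fn)
    n_inner = params.n_inner
    if n_steps % n_inner != 0:
        raise ValueError("n_steps must be a multiple of n_inner")
    s = state.copy()
    rec = _Recorder()
    rec.add(s, float(accurate_energy_fn(s.positions)))
    inv_m = FORCE_TO_ACCEL / s.masses[:, None]
    dt = params.dt
    outer_dt = n_inner * dt
    f_ref = ref_forces(s.positions)
    for _ in range(n_steps // n_inner):
        df = acc_forces(s.positions) - ref_forces(s.positions)
        s.velocities = s.velocities + 0.5 * outer_dt * df * inv_m
        inner_frames = []
        for _ in range(n_inner):
            s.velocities = s.velocities + 0.5 * dt * f_ref * inv_m
            s.positions = s.positions + dt * s.velocities
            f_ref = ref_forces(s.positions)
            s.velocities = s.velocities + 0.5 * dt * f_ref * inv_m
            s.time += dt
            inner_frames.append(s.copy())
        df = acc_forces(s.positions) - ref_forces(s.positions)
        s.velocities = s.velocities + 0.5 * outer_dt * df * inv_m
        # record after the closing half-kick so frame velocities are the
        # propagated ones at outer boundaries
        for frame in inner_frames[:-1]:
            rec.add(frame, float(accurate_energy_fn(frame.positions)))
        rec.add(s, float(accurate_energy_fn(s.positions)))
    return rec.trajectory()


@dataclass
class OptimizationResult:
    conformer: Conformer
    energy: float
    converged: bool
    n_iterations: int
    max_force: float


def optimize_geometry(
    energy_fn,
    start: Conformer,
    force_tol: float = 1e-3,
    max_iter: int = 500,
    fd_epsilon: float = 0.001,
) -> OptimizationResult:
    """Quasi-Newton (L-BFGS) descent on finite-difference gradients until the
    largest force component drops below ``force_tol`` kcal·mol⁻¹·Å⁻¹.

    Returns the best geometry found, flagged non-converged when the
    iteration cap is hit first.
    """
    n = start.n_atoms

    def fun(flat):
        return float(energy_fn(flat.reshape(n, 3)))

    def jac(flat):
        f = finite_difference_forces(energy_fn, flat.reshape(n, 3), fd_epsilon)
        return -f.ravel()

    res = minimize(
        fun,
        start.coords.ravel(),
        jac=jac,
        method="L-BFGS-B",
        options={"gtol": force_tol, "maxiter": max_iter, "ftol": 0.0},
    )
    coords = res.x.reshape(n, 3)
    max_force = float(np.max(np.abs(jac(res.x))))
    return OptimizationResult(
        conformer=start.with_coords(coords),
        energy=float(res.fun),
        converged=max_force < force_tol,
        n_iterations=int(res.nit),
        max_force=max_force,
    )
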