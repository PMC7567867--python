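"""Finite-difference forces, integrators, and geometry optimization."""

import numpy as np
import pytest

import densfunc as df
from densfunc.core import Conformer
from densfunc.dynamics import (
    IntegratorParams,
    MDState,
    finite_difference_forces,
    instantaneous_temperature,
    langevin_trajectory,
    nve_trajectory,
    optimize_geometry,
    respa_trajectory,
)
from densfunc.krr import KernelSpec, fit_krr, predict_krr
from densfunc.units import FORCE_TO_ACCEL, KB_KCAL_MOL_K


def harmonic(k=1.0, x0=None):
    def e(X):
        X = np.asarray(X, float)
        ref = 0.0 if x0 is None else x0
        if X.ndim == 2:
            return 0.5 * k * float(np.sum((X - ref) ** 2))
        return 0.5 * k * np.sum((X - ref) ** 2, axis=(-2, -1))

    return e


class TestFiniteDifferenceForces:
    def test_exact_for_quadratic(self, rng):
        """Central differences are exact for harmonic energies: at x0+d the
        force is exactly -k d."""
        x0 = rng.standard_normal((4, 3))
        d = rng.standard_normal((4, 3)) * 0.3
        f = finite_difference_forces(harmonic(1.0, x0), x0 + d, 1e-3)
        assert np.allclose(f, -d, atol=1e-10)

    def test_constant_energy_zero_forces(self):
        f = finite_difference_forces(lambda X: 5.0, np.zeros((3, 3)), 1e-3)
        assert np.allclose(f, 0.0)

    def test_matches_analytic_kernel_gradient(self, rng):
        """FD forces on a KRR energy model agree with the hand-derived
        analytic kernel gradient to better than 1e-5 at eps = 1e-3 A."""
        Xtr = rng.standard_normal((8, 6))  # 2 atoms, flattened
        ytr = rng.standard_normal(8)
        sigma = 1.2
        model = fit_krr(Xtr, ytr, KernelSpec(sigma), lam=1e-8)

        def energy(X):
            X = np.asarray(X, float)
            if X.ndim == 2:
                return predict_krr(model, X.ravel())
            return np.asarray(predict_krr(model, X.reshape(X.shape[0], -1)))

        def analytic_forces(x_flat):
            diff = x_flat[None, :] - model.train_inputs
            k = np.exp(-np.sum(diff**2, axis=1) / (2 * sigma**2))
            grad = (model.dual_coefficients * k) @ (-diff / sigma**2)
            return -grad

        x = rng.standard_normal((2, 3)) * 0.5
        f_fd = finite_difference_forces(energy, x, 1e-3)
        f_an = analytic_forces(x.ravel()).reshape(2, 3)
        assert np.max(np.abs(f_fd - f_an)) < 1e-5

    def test_second_order_convergence(self, water):
        """Halving eps cuts the FD error about fourfold."""
        x = water.template.coords + 0.03
        f_ref = finite_difference_forces(water.low_energy_fn(), x, 1e-6)
        e1 = np.max(np.abs(
            finite_difference_forces(water.low_energy_fn(), x, 4e-3) - f_ref))
        e2 = np.max(np.abs(
            finite_difference_forces(water.low_energy_fn(), x, 2e-3) - f_ref))
        assert e1 / e2 == pytest.approx(4.0, rel=0.15)

    def test_non_finite_energy_raises(self):
        with pytest.raises(ValueError):
            finite_difference_forces(lambda X: np.nan, np.zeros((1, 3)), 1e-3)


class TestNVE:
    def test_harmonic_oscillator_period(self):
        """1D harmonic oscillator: recovered period matches 2 pi sqrt(m/k)
        to 0.1%."""
        k, m = 100.0, 12.0
        period = 2 * np.pi * np.sqrt(m / (k * FORCE_TO_ACCEL))
        state = MDState(np.array([[0.3, 0.0, 0.0]]), np.zeros((1, 3)),
                        np.array([m]))
        params = IntegratorParams(dt=period / 2000)
        traj = nve_trajectory(harmonic(k), state, params, 4000)
        x = traj.positions[:, 0, 0]
        # zero crossings of x give half-periods
        crossings = np.where(np.diff(np.sign(x)) != 0)[0]
        t_cross = traj.times[crossings]
        measured = 2 * np.mean(np.diff(t_cross))
        assert measured == pytest.approx(period, rel=1e-3)

    def test_stationary_point_stays_put(self, water):
        # finite-difference forces at the minimum carry O(eps^2) truncation
        # noise, so "unchanged" means to that noise floor
        state = MDState(water.template.coords.copy(), np.zeros((3, 3)),
                        water.template.masses())
        traj = nve_trajectory(water.low_energy_fn(), state,
                              IntegratorParams(dt=0.5), 20)
        assert np.max(np.abs(traj.positions - traj.positions[0])) < 1e-5

    def test_momentum_conserved_on_translation_invariant_surface(self, rng):
        """For pair-distance energies the central-difference forces on the
        two ends cancel exactly, so FD-driven NVE conserves momentum to
        rounding."""
        from densfunc.synthetic import BondTerm, ToySystem

        diatomic = ToySystem(
            name="pair", species=("O", "O"),
            template_coords=np.array([[0.0, 0, 0], [1.2, 0, 0]]),
            bonds=(BondTerm(0, 1, 400.0, 1.2),),
        )
        masses = diatomic.template.masses()
        state = MDState(
            diatomic.template_coords + 0.05 * rng.standard_normal((2, 3)),
            0.01 * rng.standard_normal((2, 3)),
            masses,
        )
        traj = nve_trajectory(diatomic.low_energy_fn(), state,
                              IntegratorParams(dt=0.5), 500)
        p = np.einsum("tnd,n->td", traj.velocities, masses)
        assert np.max(np.abs(p - p[0])) < 1e-10

    def test_time_reversibility(self, water, rng):
        x0 = water.template.coords + 0.05 * rng.standard_normal((3, 3))
        state = MDState(x0.copy(), np.zeros((3, 3)), water.template.masses())
        params = IntegratorParams(dt=0.5)
        fwd = nve_trajectory(water.low_energy_fn(), state, params, 200)
        back_state = MDState(fwd.positions[-1].copy(), -fwd.velocities[-1],
                             water.template.masses())
        back = nve_trajectory(water.low_energy_fn(), back_state, params, 200)
        assert np.max(np.abs(back.positions[-1] - x0)) < 1e-6

    def test_divergence_aborts_with_diagnostic(self):
        state = MDState(np.array([[1.0, 0, 0]]), np.zeros((1, 3)), np.array([1.0]))
        blowup = lambda X: float(1e12 * np.sum(np.asarray(X) ** 2))
        with pytest.raises(RuntimeError, match="diverged"):
            nve_trajectory(blowup, state, IntegratorParams(dt=0.5), 10)


class TestLangevin:
    def test_zero_friction_reduces_to_velocity_verlet(self, water, rng):
        x0 = water.template.coords + 0.05 * rng.standard_normal((3, 3))
        masses = water.template.masses()
        params = IntegratorParams(dt=0.5, friction=0.0, seed=11)
        lt = langevin_trajectory(water.low_energy_fn(),
                                 MDState(x0.copy(), np.zeros((3, 3)), masses),
                                 params, 100)
        nt = nve_trajectory(water.low_energy_fn(),
                            MDState(x0.copy(), np.zeros((3, 3)), masses),
                            params, 100)
        assert np.max(np.abs(lt.positions - nt.positions)) < 1e-12

    def test_same_seed_bitwise_identical(self, water):
        masses = water.template.masses()
        params = IntegratorParams(dt=0.5, temperature=350.0, seed=4)
        runs = [
            langevin_trajectory(
                water.low_energy_fn(),
                MDState(water.template.coords.copy(), np.zeros((3, 3)), masses),
                params, 50,
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].positions, runs[1].positions)
        assert np.array_equal(runs[0].velocities, runs[1].velocities)

    def test_equipartition_in_harmonic_well(self):
        """Long thermostatted run equilibrates to the target temperature
        within a few percent (3N harmonic modes)."""
        k = 200.0
        masses = np.array([12.0, 12.0])
        state = MDState(np.zeros((2, 3)), np.zeros((2, 3)), masses)
        params = IntegratorParams(dt=0.5, temperature=350.0, friction=0.413,
                                  seed=2)
        force_fn = lambda X: -k * X
        traj = langevin_trajectory(harmonic(k), state, params, 30_000,
                                   force_fn=force_fn)
        temps = 2 * traj.e_kin[2000:] / (6 * KB_KCAL_MOL_K)
        assert np.mean(temps) == pytest.approx(350.0, rel=0.05)

    def test_negative_friction_rejected(self):
        with pytest.raises(ValueError):
            IntegratorParams(friction=-0.1)


class TestRESPA:
    def test_identical_surfaces_match_plain_nve(self, water, rng):
        x0 = water.template.coords + 0.05 * rng.standard_normal((3, 3))
        masses = water.template.masses()
        params = IntegratorParams(dt=0.5, n_inner=3)
        rt = respa_trajectory(water.low_energy_fn(), water.low_energy_fn(),
                              MDState(x0.copy(), np.zeros((3, 3)), masses),
                              params, 60)
        nt = nve_trajectory(water.low_energy_fn(),
                            MDState(x0.copy(), np.zeros((3, 3)), masses),
                            params, 60)
        assert np.max(np.abs(rt.positions - nt.positions)) < 1e-10

    def test_single_inner_step_equals_accurate_nve(self, water, rng):
        x0 = water.template.coords + 0.05 * rng.standard_normal((3, 3))
        masses = water.template.masses()
        params = IntegratorParams(dt=0.5, n_inner=1)
        rt = respa_trajectory(water.low_energy_fn(), water.high_energy_fn(),
                              MDState(x0.copy(), np.zeros((3, 3)), masses),
                              params, 50)
        nt = nve_trajectory(water.high_energy_fn(),
                            MDState(x0.copy(), np.zeros((3, 3)), masses),
                            params, 50)
        assert np.max(np.abs(rt.positions - nt.positions)) < 1e-10

    def test_time_reversibility(self, water, rng):
        x0 = water.template.coords + 0.05 * rng.standard_normal((3, 3))
        masses = water.template.masses()
        params = IntegratorParams(dt=0.5, n_inner=3)
        fwd = respa_trajectory(water.low_energy_fn(), water.high_energy_fn(),
                               MDState(x0.copy(), np.zeros((3, 3)), masses),
                               params, 99)
        back = respa_trajectory(
            water.low_energy_fn(), water.high_energy_fn(),
            MDState(fwd.positions[-1].copy(), -fwd.velocities[-1], masses),
            params, 99,
        )
        assert np.max(np.abs(back.positions[-1] - x0)) < 1e-6

    def test_non_multiple_step_count_rejected(self, water):
        state = MDState(water.template.coords.copy(), np.zeros((3, 3)),
                        water.template.masses())
        with pytest.raises(ValueError):
            respa_trajectory(water.low_energy_fn(), water.high_energy_fn(),
                             state, IntegratorParams(n_inner=3), 50)


class TestOptimization:
    def test_quadratic_bowl_converges_to_minimum(self, rng):
        x0 = rng.standard_normal((3, 3))
        target = rng.standard_normal((3, 3))
        start = Conformer.from_species(["O", "H", "H"], x0)
        result = optimize_geometry(harmonic(5.0, target), start,
                                   force_tol=1e-8)
        assert result.converged
        assert np.max(np.abs(result.conformer.coords - target)) < 1e-6

    def test_start_at_minimum_converges_immediately(self, water):
        result = optimize_geometry(water.low_energy_fn(), water.template,
                                   force_tol=1e-3)
        assert result.converged
        assert result.n_iterations <= 1
        assert np.max(np.abs(result.conformer.coords
                             - water.template.coords)) < 1e-8

    def test_iteration_cap_flags_non_converged(self, water, rng):
        start = water.template.with_coords(
            water.template.coords + 0.3 * rng.standard_normal((3, 3)))
        result = optimize_geometry(water.low_energy_fn(), start,
                                   force_tol=1e-10, max_iter=1)
        assert not result.converged


class TestDeltaCorrectedDoubleWell:
    """A 1D double-well pair where the levels of theory disagree: the
    low-level global minimum sits in one well, the high-level in the other.
    Optimizing on low + (KRR-learned correction) must find the high-level
    minimum locations, not the low-level ones."""

    A, B, K = 4.0, 0.3, 50.0

    @classmethod
    def e_low(cls, X):
        X = np.asarray(X, float)
        single = X.ndim == 2
        Xb = X[None] if single else X
        x, y, z = Xb[..., 0, 0], Xb[..., 0, 1], Xb[..., 0, 2]
        e = cls.A * (x**2 - 1) ** 2 + cls.B * x + 0.5 * cls.K * (y**2 + z**2)
        return float(e[0]) if single else e

    @classmethod
    def e_high(cls, X):
        X = np.asarray(X, float)
        single = X.ndim == 2
        Xb = X[None] if single else X
        e = np.asarray(cls.e_low(Xb)) - 2 * cls.B * Xb[..., 0, 0]
        return float(e[0]) if single else e

    def test_corrected_surface_recovers_high_level_minima(self, rng):
        start_p = Conformer.from_species(["H"], [[1.0, 0, 0]])
        start_m = Conformer.from_species(["H"], [[-1.0, 0, 0]])
        opt = lambda fn, s: optimize_geometry(fn, s, force_tol=1e-8)
        high_p, high_m = opt(self.e_high, start_p), opt(self.e_high, start_m)
        low_p, low_m = opt(self.e_low, start_p), opt(self.e_low, start_m)
        # the two levels disagree about the global minimum
        assert high_p.energy < high_m.energy
        assert low_m.energy < low_p.energy

        xs = np.concatenate([np.linspace(-1.6, 1.6, 30),
                             rng.uniform(-1.5, 1.5, 10)])
        inputs = np.zeros((40, 3))
        inputs[:, 0] = xs
        labels = -2 * self.B * xs  # the exact high-low difference
        model = fit_krr(inputs, labels, KernelSpec(0.7), lam=1e-10)
        corrected = lambda X: self.e_low(X) + float(
            predict_krr(model, np.asarray(X, float).ravel()))

        corr_p = optimize_geometry(corrected, low_p.conformer, force_tol=1e-6)
        corr_m = optimize_geometry(corrected, low_m.conformer, force_tol=1e-6)
        # locations match the high-level minima to 1e-3 in the driving
        # coordinate, and are distinct from the low-level ones
        assert abs(corr_p.conformer.coords[0, 0]
                   - high_p.conformer.coords[0, 0]) < 1e-3
        assert abs(corr_m.conformer.coords[0, 0]
                   - high_m.conformer.coords[0, 0]) < 1e-3
        assert abs(corr_p.conformer.coords[0, 0]
                   - low_p.conformer.coords[0, 0]) > 5e-3
        # and the corrected surface ranks the wells like the high level
        assert corr_p.energy < corr_m.energy
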