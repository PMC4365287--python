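"""Mean-field solvers: logistic mass, persistence classification, the birth
operator P and the normalized/full evolution equations."""

import math

import numpy as np
import pytest

import hermesim as hs
from hermesim.macroscopic import (MacroParams, apply_P, attractor_rescale,
                                  carrying_capacity, classify_persistence,
                                  mass_solution, solve_density,
                                  solve_normalized)


def normal_grid(mean=0.0, var=1.0, lo=-8.0, hi=8.0, n=512, mass=1.0):
    g = hs.GridDensity.from_function(
        lambda z: np.exp(-(z - mean) ** 2 / (2 * var)) / math.sqrt(2 * math.pi * var),
        lo, hi, n, normalize=True)
    return hs.rescale_to_mass(g, mass)


class TestMassSolution:
    def params(self, p=2.0, D=1.0, I=1.0, U=1.0):
        return MacroParams(p=p, D=D, I=I, U=U, mating=hs.MatingModel(p=p))

    def test_stationary_at_carrying_capacity(self):
        pa = self.params()
        mbar = carrying_capacity(pa)
        assert mbar == 1.0
        ts = np.linspace(0, 20, 7)
        assert np.allclose(mass_solution(mbar, pa, ts), mbar)

    def test_logistic_convergence(self):
        pa = self.params()
        assert float(mass_solution(0.1, pa, 50.0)) == pytest.approx(1.0, abs=1e-6)

    def test_extinction_when_death_dominates(self):
        pa = self.params(p=1.0, D=2.0)
        assert float(mass_solution(0.7, pa, 80.0)) < 1e-10

    def test_no_competition_reduces_to_exponential(self):
        pa = self.params(p=2.0, D=1.0, I=0.0, U=0.0)
        assert float(mass_solution(0.5, pa, 3.0)) \
            == pytest.approx(0.5 * math.exp(3.0))

    def test_matches_numerical_ode(self):
        from scipy.integrate import solve_ivp
        pa = self.params(p=1.7, D=0.4, I=0.8, U=1.3)
        sol = solve_ivp(lambda t, m: pa.p * m - (pa.D + pa.I * pa.U * m) * m,
                        (0, 6), [0.25], rtol=1e-10, atol=1e-12)
        assert float(mass_solution(0.25, pa, 6.0)) \
            == pytest.approx(sol.y[0, -1], rel=1e-7)


class TestPersistence:
    def test_extinct_branch(self):
        assert classify_persistence((0.5, 1.0), (1.5, 2.0)) == "extinct"

    def test_persistent_branch(self):
        assert classify_persistence((1.0, 1.2), (0.2, 0.5)) == "persistent"

    def test_undetermined(self):
        assert classify_persistence((1.0, 1.0), (0.8, 1.2)) == "undetermined"

    def test_assortative_uses_unit_rate(self):
        assert classify_persistence((5.0, 9.0), (1.0, 2.0),
                                    "assortative_symmetric") == "extinct"
        assert classify_persistence((0.1, 0.2), (0.3, 0.9),
                                    "assortative_symmetric") == "persistent"


class TestApplyP:
    def test_single_atom_pushes_through_kernel(self, midpoint_kernel):
        mu = hs.AtomicMeasure([0.8], [1.0])
        out = apply_P(mu, midpoint_kernel)
        assert out.locations.tolist() == [0.8]
        assert out.weights.tolist() == [1.0]

    def test_single_atom_additive_is_noise_law(self, additive_kernel):
        # P delta_q = K(q, q, .) = law of q + Z
        q = 1.5
        mu = hs.AtomicMeasure([q], [1.0])
        out = apply_P(mu, additive_kernel, order=24)
        assert hs.moment(out, 1) == pytest.approx(q, abs=1e-10)
        assert hs.variance(out) == pytest.approx(1.0, abs=1e-10)

    def test_mean_preserved_random_atomic(self, midpoint_kernel,
                                          interpolation_kernel):
        rng = np.random.default_rng(0)
        locs = rng.uniform(0, 2, 10)
        w = rng.uniform(0.1, 1, 10)
        mu = hs.AtomicMeasure(locs, w / w.sum())
        for kern in (midpoint_kernel, interpolation_kernel):
            out = apply_P(mu, kern)
            assert hs.moment(out, 1) == pytest.approx(mu.mean, abs=1e-8)

    def test_mean_preserved_grid_routes(self, additive_kernel, tjonwu_kernel):
        g = normal_grid(mean=0.7, lo=-10, hi=12, n=1024)
        out = apply_P(g, additive_kernel)
        assert hs.moment(out, 1) == pytest.approx(0.7, abs=1e-6)
        e = hs.tjon_wu_equilibrium(1.0, 0.0, 25.0, 1024)
        out2 = apply_P(e, tjonwu_kernel)
        assert hs.moment(out2, 1) == pytest.approx(1.0, abs=1e-3)

    def test_exponential_is_tjonwu_fixed_point(self, tjonwu_kernel):
        # if S ~ Gamma(2,1) and V ~ U(0,1) then S V ~ Exp(1)
        eq = hs.tjon_wu_equilibrium(1.0, 0.0, 30.0, 4096)
        out = apply_P(eq, tjonwu_kernel)
        assert hs.wasserstein(out, eq) < 5e-3

    def test_empirical_contraction_additive(self, additive_kernel):
        # d(P mu, P nu) < d(mu, nu) on random equal-mean pairs
        rng = np.random.default_rng(42)
        grid = hs.GridDensity(-9.0, 9.0, np.full(1024, 1 / 18))
        for _ in range(20):
            from conftest import random_atomic_probability
            mu = random_atomic_probability(rng, n=6, mean=0.0)
            nu = random_atomic_probability(rng, n=6, mean=0.0)
            d0 = hs.wasserstein(mu, nu)
            pmu = apply_P(mu, additive_kernel, out_grid=grid)
            pnu = apply_P(nu, additive_kernel, out_grid=grid)
            d1 = hs.wasserstein(pmu, pnu)
            assert d1 < d0

    def test_rejects_non_probability(self, midpoint_kernel):
        with pytest.raises(ValueError, match="probability"):
            apply_P(hs.AtomicMeasure([0.0], [2.0]), midpoint_kernel)

    def test_assortative_weights_keep_probability_and_mean(self,
                                                           interpolation_kernel):
        mating = hs.MatingModel(variant="assortative_symmetric",
                                a=hs.gaussian_pref(1.0))
        rng = np.random.default_rng(1)
        mu = hs.AtomicMeasure(rng.uniform(0, 1, 8), np.full(8, 1 / 8))
        out = apply_P(mu, interpolation_kernel, mating=mating)
        assert hs.moment(out, 0) == pytest.approx(1.0, abs=1e-12)


class TestSolveNormalized:
    def test_mass_exactly_one(self, midpoint_kernel):
        mu0 = hs.AtomicMeasure(np.linspace(0, 1, 32), np.full(32, 1 / 32))
        traj = solve_normalized(mu0, midpoint_kernel, T=1.0, dt=0.05)
        assert np.max(np.abs(traj.mass - 1.0)) < 1e-12

    def test_mean_conserved(self, midpoint_kernel):
        mu0 = hs.AtomicMeasure(np.linspace(0, 1, 32), np.full(32, 1 / 32))
        traj = solve_normalized(mu0, midpoint_kernel, T=2.0, dt=0.02)
        assert abs(traj.mean[-1] - traj.mean[0]) < 1e-6

    def test_fixed_point_is_stationary(self, tjonwu_kernel):
        eq = hs.tjon_wu_equilibrium(1.0, 0.0, 25.0, 1024)
        traj = solve_normalized(eq, tjonwu_kernel, T=1.0, dt=0.1)
        assert hs.wasserstein(traj.measures[-1], eq) < 1e-3

    def test_variance_decay_interpolation(self, interpolation_kernel):
        # Var(Z) = 1/3 for Z ~ U(-1,1): variance decays at (1 - 1/3)/2 = 1/3
        mu0 = hs.AtomicMeasure(np.linspace(0, 1, 64), np.full(64, 1 / 64))
        traj = solve_normalized(mu0, interpolation_kernel, T=3.0, dt=0.01,
                                compress_cells=256, order=8)
        rate = hs.variance_decay_fit(traj)
        assert rate == pytest.approx(1.0 / 3.0, rel=0.02)

    def test_rejects_big_dt(self, midpoint_kernel):
        mu0 = hs.AtomicMeasure([0.0, 1.0], [0.5, 0.5])
        with pytest.raises(ValueError, match="dt"):
            solve_normalized(mu0, midpoint_kernel, T=3.0, dt=1.5)

    def test_duhamel_weights_agree_with_euler_at_small_dt(self, midpoint_kernel):
        mu0 = hs.AtomicMeasure(np.linspace(0, 1, 16), np.full(16, 1 / 16))
        te = solve_normalized(mu0, midpoint_kernel, T=1.0, dt=0.01)
        td = solve_normalized(mu0, midpoint_kernel, T=1.0, dt=0.01, duhamel=True)
        assert hs.wasserstein(te.measures[-1], td.measures[-1]) < 1e-3


class TestSolveDensity:
    def logistic_setup(self, ncells=512, sigma=0.5):
        u0 = normal_grid(mass=0.1, n=ncells)
        kernel = hs.make_additive(hs.normal_noise(sigma))
        params = MacroParams(p=2.0, D=1.0, I=1.0, U=1.0,
                             mating=hs.MatingModel(p=2.0), kernel=kernel)
        return u0, params

    def test_mass_matches_logistic_closed_form(self):
        u0, params = self.logistic_setup()
        traj = solve_density(u0, params, T=10.0, dt=0.001)
        closed = float(mass_solution(0.1, params, 10.0))
        assert abs(traj.mass[-1] - closed) < 1e-3

    def test_positivity(self):
        u0, params = self.logistic_setup(ncells=256)
        traj = solve_density(u0, params, T=2.0, dt=0.002)
        for g in traj.measures:
            assert np.all(g.values >= 0)

    def test_extinction_regime(self):
        u0 = normal_grid(mass=1.0, n=256)
        kernel = hs.make_additive(hs.normal_noise(0.5))
        params = MacroParams(p=0.5, D=2.0, I=1.0, U=1.0,
                             mating=hs.MatingModel(p=0.5), kernel=kernel)
        traj = solve_density(u0, params, T=20.0, dt=0.002)
        assert traj.mass[-1] < traj.mass[0] / 10

    def test_first_order_convergence_in_dt(self):
        u0, params = self.logistic_setup(ncells=256)
        errs = []
        for dt in (0.008, 0.004):
            traj = solve_density(u0, params, T=2.0, dt=dt)
            closed = float(mass_solution(0.1, params, 2.0))
            errs.append(abs(traj.mass[-1] - closed))
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 3.0

    def test_cfl_guard(self):
        u0, params = self.logistic_setup(ncells=128)
        params = MacroParams(p=2.0, D=600.0, I=1.0, U=1.0,
                             mating=params.mating, kernel=params.kernel)
        with pytest.raises(ValueError, match="dt"):
            solve_density(u0, params, T=1.0, dt=0.001)

    def test_trait_dependent_death_shifts_profile(self):
        # killing the right half shifts the mean left: a sanity check of the
        # trait-resolved death term
        u0 = normal_grid(mass=1.0, n=256)
        kernel = hs.make_additive(hs.normal_noise(0.5))
        params = MacroParams(p=1.0, D=lambda x: np.where(x > 0, 2.0, 0.1),
                             I=0.1, U=0.1, mating=hs.MatingModel(p=1.0),
                             kernel=kernel)
        traj = solve_density(u0, params, T=2.0, dt=0.002)
        assert traj.mean[-1] < traj.mean[0] - 0.1


class TestAttractorRescale:
    def test_snapshots_become_probabilities(self):
        u0 = normal_grid(mass=0.5, n=256)
        kernel = hs.make_additive(hs.normal_noise(0.5))
        params = MacroParams(p=2.0, D=1.0, I=1.0, U=1.0,
                             mating=hs.MatingModel(p=2.0), kernel=kernel)
        traj = solve_density(u0, params, T=1.0, dt=0.002)
        res = attractor_rescale(traj, params)
        assert np.allclose(res.mass, 1.0)
        assert np.allclose(res.times, 2.0 * traj.times)

    def test_matches_normalized_flow(self):
        # a constant-rate full run, normalized and time-rescaled, follows the
        # normalized equation started from the same profile
        u0 = normal_grid(mass=1.0, lo=-10, hi=10, n=1024)  # mass Mbar = 1
        kernel = hs.make_additive(hs.normal_noise(1.0))
        params = MacroParams(p=2.0, D=1.0, I=1.0, U=1.0,
                             mating=hs.MatingModel(p=2.0), kernel=kernel)
        full = solve_density(u0, params, T=1.5, dt=0.001)
        rescaled = attractor_rescale(full, params)
        norm = solve_normalized(hs.rescale_to_mass(u0, 1.0), kernel,
                                T=3.0, dt=0.002)
        gap = hs.wasserstein(rescaled.measures[-1], norm.measures[-1])
        assert gap < 0.02

    def test_extinct_trajectory_rejected(self):
        g = hs.GridDensity(-1.0, 1.0, np.zeros(8))
        traj = hs.MacroTrajectory(np.array([0.0]), [g])
        params = MacroParams(p=2.0, D=1.0, I=1.0, U=1.0,
                             mating=hs.MatingModel(p=2.0))
        with pytest.raises(ValueError, match="extinct"):
            attractor_rescale(traj, params)
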