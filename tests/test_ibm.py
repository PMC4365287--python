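"""The stochastic individual-based model: event rates, SSA steps, trajectories
and the mean-field probe."""

import math

import numpy as np
import pytest
from scipy import stats

import hermesim as hs
from hermesim.ibm import (DemographyParams, PopulationState, event_rates,
                          meanfield_gap, sample_from_measure, simulate, step)


@pytest.fixture
def semi_random():
    return hs.MatingModel(variant="semi_random", p=1.0, selfing=True)


class TestEventRates:
    def test_birth_total_two_individuals(self, semi_random, midpoint_kernel):
        state = PopulationState([0.0, 1.0])
        b, d = event_rates(state, semi_random, midpoint_kernel,
                           DemographyParams(), 1)
        assert b == pytest.approx(2.0)   # sum over ordered pairs = sum p = n
        assert np.all(d == 0.0)

    def test_constant_natural_death(self, semi_random, midpoint_kernel):
        state = PopulationState([0.0, 0.5, 1.0])
        _, d = event_rates(state, semi_random, midpoint_kernel,
                           DemographyParams(D=1.0), 1)
        assert np.allclose(d, 1.0)

    def test_competition_includes_self(self, semi_random, midpoint_kernel):
        # death_i = D + (I/N) * U * n with the self term included
        n, iota, u = 5, 0.7, 0.3
        state = PopulationState(np.linspace(0, 1, n))
        _, d = event_rates(state, semi_random, midpoint_kernel,
                           DemographyParams(D=0.1, I=iota, U=u), 1)
        assert np.allclose(d, 0.1 + iota * u * n)

    def test_self_competition_can_be_excluded(self, semi_random, midpoint_kernel):
        n = 5
        state = PopulationState(np.linspace(0, 1, n))
        _, d = event_rates(state, semi_random, midpoint_kernel,
                           DemographyParams(I=1.0, U=1.0,
                                            exclude_self_competition=True), 1)
        assert np.allclose(d, n - 1)

    def test_interaction_scaling(self, semi_random, midpoint_kernel):
        state = PopulationState(np.zeros(10))
        _, d200 = event_rates(state, semi_random, midpoint_kernel,
                              DemographyParams(I=1.0, U=1.0), 200)
        assert np.allclose(d200, 10 / 200)

    def test_empty_state(self, semi_random, midpoint_kernel):
        b, d = event_rates(PopulationState([]), semi_random, midpoint_kernel,
                           DemographyParams(), 1)
        assert b == 0.0 and d.size == 0

    def test_birth_total_matches_rate_matrix(self, midpoint_kernel):
        rng = np.random.default_rng(0)
        traits = rng.uniform(0, 2, 9)
        for variant, selfing in [("semi_random", True), ("semi_random", False),
                                 ("assortative_symmetric", True),
                                 ("assortative_symmetric", False),
                                 ("assortative_female", True),
                                 ("assortative_normalized", True)]:
            m = hs.MatingModel(variant=variant, p=lambda x: 1 + x,
                               a=hs.gaussian_pref(1.0), selfing=selfing)
            b, _ = event_rates(PopulationState(traits), m, midpoint_kernel,
                               DemographyParams(), 1)
            assert b == pytest.approx(hs.rate_matrix(traits, m).sum(), rel=1e-10)


class TestStep:
    def test_birth_grows_by_one(self, semi_random, midpoint_kernel):
        state = PopulationState([0.0, 1.0])
        new, rec = step(state, semi_random, midpoint_kernel,
                        DemographyParams(), 1, np.random.default_rng(0))
        assert rec.type == "birth"
        assert new.size == 3
        i, j = rec.actors
        assert rec.offspring == (state.traits[i] + state.traits[j]) / 2

    def test_death_shrinks_by_one(self, semi_random, midpoint_kernel):
        # death-only dynamics: make births impossible via D >> p and check a
        # chosen death event
        state = PopulationState([0.0, 1.0, 2.0])
        demo = DemographyParams(D=1e9)
        new, rec = step(state, semi_random, midpoint_kernel, demo, 1,
                        np.random.default_rng(1))
        assert rec.type == "death_natural"
        assert new.size == 2

    def test_zero_rate_state_freezes(self, midpoint_kernel):
        m = hs.MatingModel(variant="semi_random", p=1.0, selfing=False)
        state = PopulationState([0.4])  # single non-selfing individual
        new, rec = step(state, m, midpoint_kernel, DemographyParams(), 1,
                        np.random.default_rng(2))
        assert rec.type == "frozen"
        assert new.size == 1

    def test_waiting_times_are_exponential(self, semi_random, midpoint_kernel):
        # frozen rates: sample the first waiting time from a fixed state;
        # total rate = births (n) + deaths (n D)
        state = PopulationState([0.0, 1.0, 2.0])
        demo = DemographyParams(D=0.5)
        total = 3.0 + 3 * 0.5
        rng = np.random.default_rng(3)
        gaps = [step(state, semi_random, midpoint_kernel, demo, 1, rng)[1].time
                for _ in range(10_000)]
        _, pval = stats.kstest(gaps, "expon", args=(0, 1 / total))
        assert pval > 0.01


class TestSimulate:
    def test_horizon_zero_returns_initial(self, semi_random, midpoint_kernel):
        traj = simulate(PopulationState([1.0, 2.0]), 0.0, semi_random,
                        midpoint_kernel, DemographyParams(), seed=0)
        assert len(traj.snapshots) >= 1
        assert traj.snapshots[-1][1].size == 2

    def test_seed_determinism(self, semi_random, midpoint_kernel):
        demo = DemographyParams(D=0.5, I=0.1, U=0.2)
        t1 = simulate(PopulationState(np.linspace(0, 1, 10)), 2.0, semi_random,
                      midpoint_kernel, demo, seed=7, record_events=True)
        t2 = simulate(PopulationState(np.linspace(0, 1, 10)), 2.0, semi_random,
                      midpoint_kernel, demo, seed=7, record_events=True)
        assert len(t1.events) == len(t2.events)
        for a, b in zip(t1.events, t2.events):
            assert a.time == b.time and a.type == b.type and a.actors == b.actors

    def test_event_counts_reconcile_with_final_size(self, semi_random,
                                                    midpoint_kernel):
        demo = DemographyParams(D=0.8, I=0.05, U=1.0)
        traj = simulate(PopulationState(np.linspace(0, 1, 15)), 3.0,
                        semi_random, midpoint_kernel, demo, seed=11,
                        record_events=True)
        births = sum(1 for e in traj.events if e.type == "birth")
        deaths = len(traj.events) - births
        assert traj.meta["final_size"] == 15 + births - deaths

    def test_extinction_is_absorbing(self, semi_random, midpoint_kernel):
        # sure extinction: D >= p
        demo = DemographyParams(D=5.0)
        sizes = []
        for s in range(50):
            traj = simulate(PopulationState(np.zeros(5)), 10.0, semi_random,
                            midpoint_kernel, demo, seed=s,
                            snapshot_times=[10.0])
            sizes.append(traj.snapshots[-1][1].size)
        assert np.mean(sizes) < 0.2

    def test_linear_birth_death_mean_growth(self, semi_random, midpoint_kernel):
        # with I = 0 the size is a linear birth-death chain with rates
        # (p, D) per head: E n_t = n0 exp((p - D) t)
        demo = DemographyParams(D=0.5)
        n0, T, reps = 20, 1.0, 200
        sizes = [simulate(PopulationState(np.zeros(n0)), T, semi_random,
                          midpoint_kernel, demo, seed=s,
                          snapshot_times=[T]).snapshots[-1][1].size
                 for s in range(reps)]
        target = n0 * math.exp(0.5 * T)
        se = np.std(sizes) / math.sqrt(reps)
        assert abs(np.mean(sizes) - target) < 5 * se

    def test_scaled_mass_stabilizes_at_carrying_capacity(self, midpoint_kernel):
        # p=2, D=1, I=U=1 -> Mbar = 1; scaled process at N=200 from mass 0.1
        mating = hs.MatingModel(p=2.0)
        demo = DemographyParams(D=1.0, I=1.0, U=1.0)
        masses = []
        for s in range(12):
            rng = np.random.default_rng(100 + s)
            traj = simulate(PopulationState(rng.normal(0, 1, 20)), 15.0,
                            mating, midpoint_kernel, demo, scale_N=200,
                            seed=s, snapshot_times=[15.0])
            masses.append(traj.snapshots[-1][1].size / 200)
        se = np.std(masses) / math.sqrt(len(masses))
        assert abs(np.mean(masses) - 1.0) < 3 * se + 0.02

    def test_hard_cap_aborts(self, semi_random, midpoint_kernel):
        with pytest.raises(RuntimeError, match="hard cap"):
            simulate(PopulationState(np.zeros(50)), 50.0, semi_random,
                     midpoint_kernel, DemographyParams(), seed=0, hard_cap=100)


class TestSampling:
    def test_sample_from_grid_matches_cdf(self):
        g = hs.GridDensity.from_function(
            lambda z: np.exp(-z ** 2 / 2) / math.sqrt(2 * math.pi),
            -6, 6, 256, normalize=True)
        rng = np.random.default_rng(5)
        draws = sample_from_measure(g, 40_000, rng)
        _, pval = stats.kstest(draws, "norm")
        assert pval > 0.01

    def test_sample_from_atoms(self):
        mu = hs.AtomicMeasure([0.0, 1.0], [0.25, 0.75])
        rng = np.random.default_rng(6)
        draws = sample_from_measure(mu, 20_000, rng)
        assert set(np.unique(draws)) <= {0.0, 1.0}
        assert abs((draws == 1.0).mean() - 0.75) < 0.02


class TestMeanField:
    def test_gap_decreases_along_N_ladder(self, additive_kernel):
        u0 = hs.GridDensity.from_function(
            lambda z: np.exp(-z ** 2 / 2) / math.sqrt(2 * math.pi),
            -8, 8, 512, normalize=True)
        kernel = hs.make_additive(hs.normal_noise(0.5))
        params = hs.MacroParams(p=1.0, D=0.5, I=1.0, U=1.0,
                                mating=hs.MatingModel(p=1.0), kernel=kernel)
        demo = DemographyParams(D=0.5, I=1.0, U=1.0)
        rows = meanfield_gap(u0, params, demo, Ns=[50, 200, 800], T=3.0,
                             replicates=6, seed=7)
        gaps = [r["mean_gap"] for r in rows]
        assert all(np.isfinite(gaps))
        # monotone decrease, allowing at most one inversion
        inversions = sum(1 for a, b in zip(gaps, gaps[1:]) if b >= a)
        assert inversions <= 1
        assert gaps[-1] < gaps[0]
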