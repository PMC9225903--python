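"""Constrained binary PSO: transfer functions, repair, swarm dynamics."""

import itertools
import math

import numpy as np
import pytest

from snptag.bpso import (
    InfeasibleConfigError,
    Particle,
    SwarmConfig,
    fitness,
    init_swarm,
    map_probability,
    optimize,
    position_update,
    repair,
    step,
    velocity_update,
)

from conftest import make_clustering


def make_particle(position, velocity=None, pbest=None):
    position = np.asarray(position, dtype=np.uint8)
    if velocity is None:
        velocity = np.zeros(position.shape[0])
    if pbest is None:
        pbest = position.copy()
    return Particle(position, np.asarray(velocity, float), pbest, 0.0)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"S": 0},
            {"S": 2, "switch_fraction": 0.0},
            {"S": 2, "v_min": 4.0, "v_max": 4.0},
            {"S": 2, "c1": 0.0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SwarmConfig(**kwargs)

    def test_phase_boundary(self):
        cfg = SwarmConfig(S=2, max_iter=100, switch_fraction=0.5)
        assert cfg.phase_at(0) == "early"
        assert cfg.phase_at(49) == "early"
        assert cfg.phase_at(50) == "late"


class TestFitness:
    def test_examples(self):
        clus = make_clustering([4, 3, 2, 1])
        m = 10
        assert fitness(np.zeros(4), clus, m) == 0.0
        assert fitness(np.array([1, 1, 0, 0]), clus, m) == pytest.approx(0.7)
        one_class = make_clustering([10])
        assert fitness(np.array([1]), one_class, 10) == 1.0


class TestMapProbability:
    def test_anchor_values(self):
        assert map_probability(0.0, "early") == 0.5
        assert map_probability(0.0, "late") == 0.0
        assert map_probability(math.log(3), "late") == pytest.approx(0.5)

    def test_late_symmetric_and_saturating(self):
        v = np.linspace(0.1, 10, 50)
        pos = np.asarray(map_probability(v, "late"))
        neg = np.asarray(map_probability(-v, "late"))
        np.testing.assert_allclose(pos, neg, atol=1e-12)
        assert np.all(np.diff(pos) > 0)  # increasing in |v|
        assert map_probability(50.0, "late") == pytest.approx(1.0)
        assert map_probability(-50.0, "late") == pytest.approx(1.0)

    def test_early_monotone(self):
        v = np.linspace(-5, 5, 21)
        s = np.asarray(map_probability(v, "early"))
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s <= 1))


class TestVelocityUpdate:
    def test_converged_particle_has_zero_late_velocity(self):
        cfg = SwarmConfig(S=1)
        x = np.array([1, 0, 1], dtype=np.uint8)
        p = make_particle(x, velocity=[2.0, -1.0, 0.5])
        rng = np.random.default_rng(0)
        v = velocity_update(p, x.astype(float), cfg, "late", rng)
        np.testing.assert_array_equal(v, 0.0)

    def test_pull_toward_one(self):
        cfg = SwarmConfig(S=1)
        p = make_particle([0, 0], velocity=[0.0, 0.0],
                          pbest=np.array([1, 1], np.uint8))
        rng = np.random.default_rng(1)
        v = velocity_update(p, np.array([1.0, 1.0]), cfg, "late", rng)
        assert np.all(v >= 0)

    def test_inertia_and_clamp(self):
        cfg = SwarmConfig(S=1, w=1.0, v_max=4.0, v_min=-4.0)
        x = np.array([1], dtype=np.uint8)
        p = make_particle(x, velocity=[100.0])
        rng = np.random.default_rng(2)
        # pbest = gbest = x: only the inertia term survives, then clamps
        v = velocity_update(p, x.astype(float), cfg, "early", rng)
        assert v[0] == 4.0


class TestPositionUpdate:
    def test_late_rules(self):
        rng = np.random.default_rng(0)
        p = make_particle([0, 1, 1, 0], velocity=[50.0, -50.0, 0.0, 0.0])
        new = position_update(p, "late", rng)
        assert new[0] == 1  # strong positive velocity flips on
        assert new[1] == 0  # strong negative velocity flips off
        assert new[2] == 1 and new[3] == 0  # v = 0 leaves bits unchanged

    def test_early_resamples_from_sigmoid(self):
        rng = np.random.default_rng(0)
        p = make_particle([0, 1], velocity=[50.0, -50.0])
        new = position_update(p, "early", rng)
        np.testing.assert_array_equal(new, [1, 0])


class TestRepair:
    def test_worked_particle(self):
        """The 15-bit particle with 8 selected loci is cut back to S=6,
        dropping the selected candidates with the smallest cluster sizes."""
        bits = np.array([int(c) for c in "010100110010111"], dtype=np.uint8)
        assert bits.sum() == 8
        rng = np.random.default_rng(42)
        sizes = rng.integers(1, 30, size=15)
        clus = make_clustering(list(sizes))  # 15 classes, sizes injected
        out = repair(bits, 6, clus)
        assert out.sum() == 6
        selected_before = np.flatnonzero(bits)
        kept = np.flatnonzero(out)
        assert set(kept) <= set(selected_before)
        # sort oracle: the kept 6 are the largest-size selected candidates
        oracle = sorted(selected_before, key=lambda j: (-sizes[j], j))[:6]
        assert sorted(kept) == sorted(oracle)

    def test_identity_when_already_S(self):
        clus = make_clustering([2, 2, 2])
        pos = np.array([1, 0, 1], dtype=np.uint8)
        np.testing.assert_array_equal(repair(pos, 2, clus), pos)

    def test_deficit_fills_largest_classes(self):
        clus = make_clustering([5, 3, 3, 1])
        out = repair(np.zeros(4, dtype=np.uint8), 2, clus)
        np.testing.assert_array_equal(out, [1, 1, 0, 0])

    def test_tiebreak_lower_index(self):
        clus = make_clustering([3, 3, 3, 3])
        out = repair(np.zeros(4, dtype=np.uint8), 2, clus)
        np.testing.assert_array_equal(out, [1, 1, 0, 0])

    def test_infeasible(self):
        clus = make_clustering([2, 2])
        with pytest.raises(InfeasibleConfigError):
            repair(np.array([1, 0], dtype=np.uint8), 3, clus)


class TestSwarm:
    def test_init_contract(self):
        clus = make_clustering([3, 2, 2, 1, 1, 1])
        cfg = SwarmConfig(S=3, population_size=10, seed=5)
        rng = np.random.default_rng(cfg.seed)
        state = init_swarm(cfg, clus, rng)
        for p in state.particles:
            assert p.position.sum() == 3
            assert np.all((p.velocity >= cfg.v_min)
                          & (p.velocity <= cfg.v_max))
            np.testing.assert_array_equal(p.position, p.pbest_position)
        assert state.gbest_fitness == max(p.pbest_fitness
                                          for p in state.particles)

    def test_init_infeasible_mentions_lambda(self):
        clus = make_clustering([2, 2])
        with pytest.raises(InfeasibleConfigError, match="lambda"):
            init_swarm(SwarmConfig(S=5), clus, np.random.default_rng(0))

    def test_gbest_monotone_and_budget_respected(self):
        clus = make_clustering([6, 4, 3, 3, 2, 1, 1])
        cfg = SwarmConfig(S=3, population_size=12, max_iter=40, seed=9)
        tags, state = optimize(clus, cfg)
        assert len(tags) == 3
        hist = state.fitness_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))
        for p in state.particles:
            assert p.position.sum() == 3

    def test_deterministic_given_seed(self):
        clus = make_clustering([4, 4, 3, 2, 2, 1])
        cfg = SwarmConfig(S=2, population_size=8, max_iter=30, seed=123)
        t1, s1 = optimize(clus, cfg)
        t2, s2 = optimize(clus, cfg)
        assert t1 == t2
        assert s1.fitness_history == s2.fitness_history

    def test_late_fixpoint(self):
        """All particles at gbest with zero velocities stay put in the
        late phase (only iteration advances)."""
        clus = make_clustering([3, 2, 1, 1])
        cfg = SwarmConfig(S=2, population_size=4, max_iter=10,
                          switch_fraction=0.1, seed=0)
        rng = np.random.default_rng(0)
        state = init_swarm(cfg, clus, rng)
        best = state.gbest_position.copy()
        for p in state.particles:
            p.position = best.copy()
            p.pbest_position = best.copy()
            p.velocity[:] = 0.0
            p.pbest_fitness = state.gbest_fitness
        state.iteration = 5  # late phase
        step(state, cfg, clus, rng)
        for p in state.particles:
            np.testing.assert_array_equal(p.position, best)

    def test_unique_feasible_solution(self):
        clus = make_clustering([5, 3, 2])
        cfg = SwarmConfig(S=3, population_size=5, max_iter=5, seed=1)
        tags, state = optimize(clus, cfg)
        assert sorted(tags) == sorted(clus.centers)
        assert state.gbest_fitness == pytest.approx(1.0)

    def test_matches_exhaustive_optimum_small_instance(self):
        rng = np.random.default_rng(2024)
        sizes = list(rng.integers(1, 20, size=10))
        clus = make_clustering(sizes)
        m = sum(sizes)
        best = max(
            sum(sizes[k] for k in combo) / m
            for combo in itertools.combinations(range(10), 3)
        )
        cfg = SwarmConfig(S=3, population_size=20, max_iter=80, seed=7)
        _, state = optimize(clus, cfg)
        assert state.gbest_fitness == pytest.approx(best)
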