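"""Emotional particle swarm: emotion dynamics, perception, per-state updates,
and the optimizer loop."""

import numpy as np
import pytest
from scipy import stats

import fermsense as fs
from fermsense.exceptions import ValidationError
from fermsense.ipso import (
    HAPPY,
    NORMAL,
    SAD,
    Particle,
    SwarmState,
    init_swarm,
    partition_emotions,
    perception,
    step_happy,
    step_normal,
    step_sad,
    update_emotion,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def make_particle(**kw):
    defaults = dict(
        position=np.array([0.0]),
        velocity=np.array([0.0]),
        fitness=1.0,
        pbest=np.array([0.0]),
        pbest_fitness=1.0,
        emotion=0.0,
    )
    defaults.update(kw)
    return Particle(**defaults)


def make_state(particles, gbest_fitness, gworst_fitness, gbest=None):
    return SwarmState(
        particles=particles,
        gbest=gbest if gbest is not None else np.array([0.0]),
        gbest_fitness=gbest_fitness,
        gworst_fitness=gworst_fitness,
    )


class StubRng:
    """Deterministic stand-in consuming the same call pattern as a Generator."""

    def __init__(self, random_value=0.5, uniform_value=0.5):
        self.random_value = random_value
        self.uniform_value = uniform_value

    def random(self, n=None):
        return self.random_value if n is None else np.full(n, self.random_value)

    def uniform(self, lo, hi, n=None):
        mid = lo + (hi - lo) * self.uniform_value
        return mid if n is None else np.full(n, mid)


class TestInit:
    CFG = fs.SwarmConfig(size=12, dims=3, lower=(-1, -1, -1), upper=(2, 2, 2),
                         max_iter=5, seed=7)

    def test_seeded_reproducibility(self):
        a = init_swarm(self.CFG, sphere)
        b = init_swarm(self.CFG, sphere)
        for p, q in zip(a.particles, b.particles):
            np.testing.assert_array_equal(p.position, q.position)
            assert p.emotion == q.emotion

    def test_initial_emotions_in_band(self):
        state = init_swarm(self.CFG, sphere)
        for p in state.particles:
            assert -0.1 <= p.emotion <= 0.1

    def test_degenerate_box(self):
        eps = 1e-9
        cfg = fs.SwarmConfig(size=5, dims=2, lower=(1.0, 1.0),
                             upper=(1.0 + eps, 1.0 + eps), max_iter=1, seed=0)
        state = init_swarm(cfg, sphere)
        for p in state.particles:
            assert np.all(np.abs(p.position - 1.0) <= eps)

    def test_nonfinite_objective_names_point(self):
        with pytest.raises(ValidationError, match="initial point"):
            init_swarm(self.CFG, lambda x: float("nan"))


class TestEmotion:
    def test_improvement_at_global_best_is_neutral(self):
        p = make_particle(fitness=1.0)
        state = make_state([p], gbest_fitness=1.0, gworst_fitness=9.0)
        assert update_emotion(p, prev_fitness=5.0, state=state) == p.emotion

    def test_worsening_at_global_worst_is_neutral(self):
        p = make_particle(fitness=9.0)
        state = make_state([p], gbest_fitness=1.0, gworst_fitness=9.0)
        assert update_emotion(p, prev_fitness=5.0, state=state) == p.emotion

    def test_improvement_increment_value(self):
        # prev 5, now 3, gb 1, gw 9 -> (5-3)(3-1)/(9-1)^2 = 0.0625
        p = make_particle(fitness=3.0, emotion=0.1)
        state = make_state([p], gbest_fitness=1.0, gworst_fitness=9.0)
        assert update_emotion(p, 5.0, state) == pytest.approx(0.1 + 0.0625)

    def test_clamped_to_unit_band(self):
        p = make_particle(fitness=1.0, emotion=0.99)
        state = make_state([p], gbest_fitness=0.0, gworst_fitness=1.1)
        e = update_emotion(p, 1e9, state)
        assert e == 1.0

    def test_degenerate_spread_guarded(self):
        p = make_particle(fitness=1.0, emotion=0.3)
        state = make_state([p], gbest_fitness=1.0, gworst_fitness=1.0)
        assert update_emotion(p, 2.0, state) == 0.3


class TestPartition:
    @staticmethod
    def _labels(emotions, rule="mean-of-extremes"):
        particles = [make_particle(emotion=e) for e in emotions]
        state = make_state(particles, 0.0, 1.0)
        return partition_emotions(state, rule)

    def test_all_equal_is_all_normal(self):
        assert self._labels([0.4, 0.4, 0.4, 0.4]) == [NORMAL] * 4

    def test_three_point_spread(self):
        assert self._labels([-0.9, 0.0, 0.9]) == [SAD, NORMAL, HAPPY]

    def test_location_covariance(self):
        base = [-0.6, -0.2, 0.1, 0.5, 0.8]
        assert self._labels(base) == self._labels([e + 0.15 for e in base])

    def test_all_normal_forcing(self):
        assert self._labels([-0.9, 0.0, 0.9], rule="all-normal") == [NORMAL] * 3

    def test_tertiles(self):
        labels = self._labels([-0.9, -0.5, 0.0, 0.1, 0.5, 0.9], rule="tertiles")
        assert labels == [SAD, SAD, NORMAL, NORMAL, HAPPY, HAPPY]


class TestPerception:
    def test_unit_ratio_is_zero(self):
        assert perception(0.01, k=1.0, s0=0.01, bounds=None) == pytest.approx(0.0)

    def test_log_ratio_value(self):
        r = perception(0.1, k=1.0, s0=0.01, bounds=None)
        assert r == pytest.approx(-np.log(10.0), abs=1e-12)

    def test_zero_gap_saturates_at_upper_clamp(self):
        assert perception(0.0, k=1.0, s0=0.01) == 2.0

    def test_clamping(self):
        assert perception(1e9, k=1.0, s0=1.0) == 0.1
        assert perception(1e-9, k=1.0, s0=1.0) == 2.0


SCALAR_CFG = fs.SwarmConfig(size=3, dims=1, lower=(-100.0,), upper=(100.0,),
                            inertia=0.5, c1=1.0, c2=1.0, max_iter=1, seed=0)


class TestSteps:
    def test_normal_hand_computation(self):
        # V' = 0.5*1 + 1*0.5*(2-0) + 1*0.5*(4-0) = 3.5; x' = 3.5
        p = make_particle(position=np.array([0.0]), velocity=np.array([1.0]),
                          pbest=np.array([2.0]))
        state = make_state([p], 0.0, 1.0, gbest=np.array([4.0]))
        step_normal(p, state, SCALAR_CFG, StubRng())
        assert p.velocity[0] == pytest.approx(3.5)
        assert p.position[0] == pytest.approx(3.5)

    def test_pure_inertia_drift(self):
        cfg = fs.SwarmConfig(size=3, dims=1, lower=(-100.0,), upper=(100.0,),
                             inertia=1.0, c1=0.0, c2=0.0, max_iter=1, seed=0)
        p = make_particle(velocity=np.array([2.0]))
        state = make_state([p], 0.0, 1.0)
        step_normal(p, state, cfg, StubRng())
        assert p.velocity[0] == 2.0 and p.position[0] == 2.0

    def test_converged_particle_only_decays(self):
        p = make_particle(position=np.array([1.0]), velocity=np.array([0.8]),
                          pbest=np.array([1.0]))
        state = make_state([p], 0.0, 1.0, gbest=np.array([1.0]))
        step_normal(p, state, SCALAR_CFG, StubRng())
        assert p.velocity[0] == pytest.approx(0.4)

    def test_happy_hand_computation(self):
        # gaps chosen so rg = -ln(e^-2) = 2 and rh = -ln(e^-0.5) = 0.5 at s0 = 1
        f = 10.0
        p = make_particle(position=np.array([0.0]), velocity=np.array([1.0]),
                          pbest=np.array([2.0]), fitness=f,
                          pbest_fitness=f - np.exp(-0.5))
        state = make_state([p], gbest_fitness=f - np.exp(-2.0),
                           gworst_fitness=f + 1, gbest=np.array([4.0]))
        cfg = SCALAR_CFG
        step_happy(p, state, cfg, StubRng(), s0=1.0)
        # V' = 0.5*1 + 1*0.5*2*(2-0) + 1*0.5*0.5*(4-0) = 0.5 + 2 + 1 = 3.5
        assert p.velocity[0] == pytest.approx(3.5)
        assert p.position[0] == pytest.approx(3.5)

    def test_happy_with_unit_perception_matches_normal(self):
        s0 = np.exp(1.0)  # gap 1 -> r = -ln(1/e) = 1 for both terms
        f = 5.0
        mk = lambda: make_particle(position=np.array([0.3]),
                                   velocity=np.array([0.7]),
                                   pbest=np.array([1.0]), fitness=f,
                                   pbest_fitness=f - 1.0)
        p1, p2 = mk(), mk()
        state = make_state([p1], gbest_fitness=f - 1.0, gworst_fitness=f + 9,
                           gbest=np.array([2.0]))
        step_happy(p1, state, SCALAR_CFG, StubRng(), s0=s0)
        step_normal(p2, state, SCALAR_CFG, StubRng())
        assert p1.velocity[0] == pytest.approx(p2.velocity[0])

    def test_sad_jump_to_previous_best(self):
        p = make_particle()
        state = make_state([p], 0.0, 1.0, gbest=np.array([3.3]))
        step_sad(p, state, SCALAR_CFG, StubRng(random_value=0.3))
        assert p.position[0] == 3.3

    def test_sad_restart_distribution(self):
        cfg = fs.SwarmConfig(size=3, dims=1, lower=(0.0,), upper=(10.0,),
                             restart_c1=0.35, max_iter=1, seed=0)
        rng = np.random.default_rng(0)
        p = make_particle()
        state = make_state([p], 0.0, 1.0)
        vels = []
        for _ in range(10_000):
            step_sad(p, state, cfg, rng)
            vels.append(p.velocity[0])
        vels = np.array(vels)
        assert np.all(np.abs(vels) <= 3.5)
        ks = stats.kstest(vels, stats.uniform(loc=-3.5, scale=7.0).cdf)
        assert ks.pvalue > 0.01

    def test_sad_keeps_pbest_memory(self):
        p = make_particle(pbest=np.array([9.9]), pbest_fitness=-1.0)
        state = make_state([p], 0.0, 1.0)
        step_sad(p, state, SCALAR_CFG, StubRng(random_value=0.9))
        assert p.pbest[0] == 9.9 and p.pbest_fitness == -1.0


class TestOptimize:
    CFG = fs.SwarmConfig(size=20, dims=2, lower=(-5, -5), upper=(5, 5),
                         max_iter=60, seed=3)

    def test_sphere_convergence(self):
        best = [
            fs.ipso_optimize(
                sphere, fs.SwarmConfig(size=30, dims=2, lower=(-5, -5),
                                       upper=(5, 5), max_iter=100, seed=s)
            ).fun
            for s in range(3)
        ]
        assert np.median(best) < 1e-2

    def test_trace_non_increasing(self):
        for run in (fs.ipso_optimize, fs.pso_optimize):
            trace = run(sphere, self.CFG).trace
            assert np.all(np.diff(trace) <= 0)

    def test_disabled_threshold_runs_all_iterations(self):
        res = fs.ipso_optimize(sphere, self.CFG)
        assert res.n_iter == self.CFG.max_iter

    def test_threshold_stops_early(self):
        cfg = fs.SwarmConfig(size=20, dims=2, lower=(-5, -5), upper=(5, 5),
                             max_iter=500, fitness_threshold=1.0, seed=3)
        res = fs.ipso_optimize(sphere, cfg)
        assert res.n_iter < 500 and res.fun < 1.0

    def test_all_normal_reduction_matches_pso(self):
        from dataclasses import replace

        forced = replace(self.CFG, partition_rule="all-normal")
        a = fs.ipso_optimize(sphere, forced)
        b = fs.pso_optimize(sphere, self.CFG)
        np.testing.assert_array_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.x, b.x)

    def test_positions_stay_in_box(self):
        seen = []

        def recording(x):
            seen.append(np.array(x))
            return sphere(x)

        fs.ipso_optimize(recording, self.CFG)
        arr = np.array(seen)
        assert arr.min() >= -5.0 and arr.max() <= 5.0

    def test_seeded_determinism(self):
        a = fs.ipso_optimize(sphere, self.CFG)
        b = fs.ipso_optimize(sphere, self.CFG)
        np.testing.assert_array_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.x, b.x)

    def test_nonfinite_mid_run_recovers(self):
        calls = [0]

        def flaky(x):
            calls[0] += 1
            if 100 <= calls[0] < 110:  # burst of failures well after init
                return float("nan")
            return sphere(x)

        res = fs.ipso_optimize(flaky, self.CFG)
        assert np.isfinite(res.fun)

    def test_init_position_override(self):
        from dataclasses import replace

        cfg = replace(self.CFG, init_positions=((1.25, -2.5),), max_iter=1)
        seen = []

        def recording(x):
            seen.append(np.array(x))
            return sphere(x)

        init_swarm(cfg, recording)
        np.testing.assert_array_equal(seen[0], [1.25, -2.5])

    def test_trace_export(self, tmp_path):
        import pandas as pd

        res = fs.ipso_optimize(sphere, self.CFG)
        path = tmp_path / "trace.csv"
        res.trace_to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["iteration", "best_fitness"]
        assert len(df) == res.n_iter
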