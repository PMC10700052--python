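import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import effsel as es
from effsel.wfsim import selection_probability


class TestWfStep:
    def test_absorbing_boundaries(self, rng):
        assert es.wf_step(0.0, 1.5, 100, rng) == (0.0, 0.0, 0.0)
        assert es.wf_step(1.0, 0.5, 100, rng) == (1.0, 0.0, 0.0)

    def test_selection_component_formula(self, rng):
        # Δs = q(1-q)(f-1)/(1+q(f-1)); at q=0.5, f=6/5 this is 0.05/1.1
        _, ds, _ = es.wf_step(0.5, 6 / 5, 1000, rng)
        assert ds == pytest.approx(0.5 * 0.5 * 0.2 / 1.1, rel=1e-12)
        assert ds == pytest.approx(0.045, abs=5e-4)

    def test_neutral_step_has_zero_selection(self, rng):
        q_next, ds, dd = es.wf_step(0.3, 1.0, 1000, rng)
        assert ds == 0.0
        assert q_next == pytest.approx(0.3 + dd)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            es.wf_step(-0.1, 1.0, 100, rng)
        with pytest.raises(ValueError):
            es.wf_step(1.1, 1.0, 100, rng)
        with pytest.raises(ValueError):
            es.wf_step(0.5, 0.0, 100, rng)
        with pytest.raises(ValueError):
            es.wf_step(0.5, -2.0, 100, rng)

    @given(copies=st.integers(1, 99), f=st.floats(0.05, 20.0),
           seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_additivity_exact_whenever_representable(self, copies, f, seed):
        # q_next == q + Δs + Δd bitwise whenever float64 admits such a split.
        # When the frequency collapses across binades (large |Δ| landing on a
        # much smaller q_next) the component lattice can be coarser than the
        # target's rounding window, making an exact split impossible; the
        # decomposition must then still reconstruct to within one ulp of the
        # largest component.  A brute-force ulp-neighborhood search certifies
        # impossibility rather than taking it on faith.
        q = copies / 100
        rng = np.random.default_rng(seed)
        q_next, ds, dd = es.wf_step(q, f, 100, rng)
        if q + ds + dd == q_next:
            return
        tol = np.spacing(max(abs(q), abs(ds), abs(dd)))
        assert abs((q + ds + dd) - q_next) <= tol

        def nudged(x, k):
            for _ in range(abs(k)):
                x = np.nextafter(x, np.inf if k > 0 else -np.inf)
            return x

        for i in range(-3, 4):
            ds_t = nudged(ds, i)
            base = q_next - (q + ds_t)
            for j in range(-3, 4):
                assert q + ds_t + nudged(base, j) != q_next

    def test_neutral_drift_variance_calibration(self):
        # one-generation Var(q') = q(1-q)/Ne under neutrality
        n, ne, q0 = 100_000, 100, 0.5
        rng = np.random.default_rng(42)
        q_next, ds, dd = es.wf_step_array(np.full(n, q0), 1.0, ne, rng)
        assert np.all(ds == 0.0)
        expected = q0 * (1 - q0) / ne
        # MC standard error of a variance estimate: var * sqrt(2/(n-1))
        mc_se = expected * np.sqrt(2 / (n - 1))
        assert abs(q_next.var(ddof=1) - expected) < 3 * mc_se
        assert q_next.mean() == pytest.approx(q0, abs=5 * np.sqrt(expected / n))


class TestFitnessForDelta:
    def test_zero_delta_is_neutral(self):
        assert es.fitness_for_delta(0.5, 0.0) == 1.0

    def test_balanced_schedule_fitness_value(self):
        # Δs = -0.045 at q = 0.5 needs f = 0.455/0.545 ≈ 5/6
        f = es.fitness_for_delta(0.5, -0.045)
        assert f == pytest.approx(0.455 / 0.545, rel=1e-12)
        assert f == pytest.approx(5 / 6, abs=2e-3)

    @given(q=st.floats(0.01, 0.99), delta=st.floats(-0.4, 0.4))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_round_trip_matches_selection_probability(self, q, delta):
        if not 0.001 < q + delta < 0.999:
            return
        f = es.fitness_for_delta(q, delta)
        assert selection_probability(q, f) - q == pytest.approx(delta, abs=1e-12)

    def test_unreachable_delta_rejected(self):
        with pytest.raises(ValueError):
            es.fitness_for_delta(0.5, 0.6)
        with pytest.raises(ValueError):
            es.fitness_for_delta(0.2, -0.2)
        with pytest.raises(ValueError):
            es.fitness_for_delta(0.0, 0.1)


class TestSimConfig:
    def test_frequency_to_copies_conversion(self):
        cfg = es.SimConfig(ne=1000, regime=es.ConstantFitness(1.0), init_freq=0.5)
        assert cfg.init_copies == 500

    def test_off_lattice_frequency_rejected(self):
        with pytest.raises(ValueError, match="multiple of 1/ne"):
            es.SimConfig(ne=1000, regime=es.ConstantFitness(1.0), init_freq=1 / 3)

    def test_both_or_neither_init_rejected(self):
        with pytest.raises(ValueError):
            es.SimConfig(ne=100, regime=es.ConstantFitness(1.0))
        with pytest.raises(ValueError):
            es.SimConfig(ne=100, regime=es.ConstantFitness(1.0),
                         init_freq=0.5, init_copies=50)

    def test_boundary_start_rejected(self):
        with pytest.raises(ValueError):
            es.SimConfig(ne=100, regime=es.ConstantFitness(1.0), init_copies=0)
        with pytest.raises(ValueError):
            es.SimConfig(ne=100, regime=es.ConstantFitness(1.0), init_copies=100)


class TestSimulate:
    def test_determinism(self):
        cfg = es.SimConfig(ne=200, regime=es.default_markov_regime(),
                           init_freq=0.5, max_generations=100, seed=99)
        a, b = es.simulate(cfg), es.simulate(cfg)
        for attr in ("q_before", "fitness", "delta_s", "delta_d", "q_after"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))
        assert a.outcome == b.outcome

    def test_neutral_run_telescopes_with_pure_drift(self):
        cfg = es.SimConfig(ne=1000, regime=es.ConstantFitness(1.0),
                           init_freq=0.5, max_generations=10, seed=5)
        traj = es.simulate(cfg)
        assert np.all(traj.delta_s == 0.0)
        assert traj.q_final == pytest.approx(0.5 + traj.delta_d.sum())

    def test_trajectory_invariants(self, markov_trajectory):
        t = markov_trajectory
        # exact per-generation additivity and lattice frequencies
        for i in range(t.n_generations):
            assert t.q_before[i] + t.delta_s[i] + t.delta_d[i] == t.q_after[i]
        copies = t.q_after * t.ne
        assert np.allclose(copies, np.round(copies), atol=1e-9)
        assert np.all((t.q_after >= 0) & (t.q_after <= 1))
        assert np.array_equal(t.q_after[:-1], t.q_before[1:])

    def test_block_regime_realized_fitness_sequence(self):
        n = 5
        cfg = es.SimConfig(
            ne=1000, regime=es.BlockFitness(5 / 6, 6 / 5, n_switch=n + 1),
            init_freq=0.5, max_generations=2 * n, seed=3)
        traj = es.simulate(cfg)
        assert np.array_equal(traj.fitness, [5 / 6] * n + [6 / 5] * n)

    def test_outcome_labels_match_final_frequency(self):
        reg = es.ConstantFitness(5.0)  # strong positive selection fixes fast
        cfg = es.SimConfig(ne=50, regime=reg, init_copies=25, seed=1)
        traj = es.simulate(cfg)
        assert traj.outcome == "fixed" and traj.q_final == 1.0
        reg = es.ConstantFitness(0.05)
        cfg = es.SimConfig(ne=50, regime=reg, init_copies=25, seed=1)
        traj = es.simulate(cfg)
        assert traj.outcome == "lost" and traj.q_final == 0.0

    def test_target_delta_error_carries_generation(self):
        # Δs = -0.3 per generation runs the frequency into the floor
        reg = es.TargetDeltaFitness([-0.3] * 10)
        cfg = es.SimConfig(ne=1000, regime=reg, init_freq=0.5,
                           max_generations=10, seed=0)
        with pytest.raises(ValueError, match="generation 2"):
            es.simulate(cfg)


class TestLinearRule:
    def test_delta_s_is_linear_in_q(self):
        cfg = es.SimConfig(ne=1000, regime=es.ConstantFitness(6 / 5),
                           init_freq=0.5, max_generations=1, seed=2)
        traj = es.simulate_linear_rule(cfg)
        assert traj.delta_s[0] == pytest.approx(0.1, abs=1e-15)  # (f-1)q

    def test_clamp_at_high_frequency(self):
        cfg = es.SimConfig(ne=1000, regime=es.ConstantFitness(6 / 5),
                           init_freq=0.9, max_generations=1, seed=2)
        traj = es.simulate_linear_rule(cfg)
        # p = min(0.9 * 1.2, 1) = 1 -> deterministic fixation
        assert traj.delta_s[0] == pytest.approx(0.1)
        assert traj.q_after[0] == 1.0

    def test_neutral_linear_rule_matches_wf(self):
        cfg = es.SimConfig(ne=500, regime=es.ConstantFitness(1.0),
                           init_freq=0.4, max_generations=20, seed=17)
        a = es.simulate(cfg)
        b = es.simulate_linear_rule(cfg)
        assert np.array_equal(a.q_after, b.q_after)


class TestSimulateBatch:
    def test_matches_scalar_distribution_and_is_deterministic(self):
        reg = es.default_markov_regime()
        a = es.simulate_batch(100, 50, reg, 1000, n_generations=30, rng=8)
        b = es.simulate_batch(100, 50, reg, 1000, n_generations=30, rng=8)
        assert np.array_equal(a.final_copies, b.final_copies)
        assert np.array_equal(a.sum_delta_s, b.sum_delta_s)

    def test_drift_sum_identity(self):
        res = es.simulate_batch(200, 100, es.default_markov_regime(), 500,
                                n_generations=50, rng=9)
        total = res.final_freq - res.q0
        assert np.allclose(res.sum_delta_s + res.sum_delta_d, total, atol=1e-15)

    def test_neutral_fixation_probability_is_initial_frequency(self):
        # classic result: a neutral single copy fixes with probability 1/Ne
        ne, n = 100, 100_000
        res = es.simulate_batch(ne, 1, es.ConstantFitness(1.0), n,
                                max_generations=100_000, rng=10)
        assert np.all(res.outcome != 2)
        k = int((res.outcome == 1).sum())
        from scipy.stats import binomtest
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
        assert ci.low <= 1 / ne <= ci.high

    def test_monte_carlo_q2_matches_exact_enumeration(self):
        # empirical two-generation mean vs the exact binomial expectation
        ne, reps = 50, 1_000_000
        f1, f2 = 1.1, 0.85
        reg = es.BlockFitness(f1, f2, n_switch=2)
        res = es.simulate_batch(ne, 25, reg, reps, n_generations=2, rng=4)
        exact = es.exact_expected_q2(es.TwoGenSpec(ne=ne, q0=0.5, f1=f1, f2=f2))
        emp = res.final_freq.mean()
        se = res.final_freq.std(ddof=1) / np.sqrt(reps)
        assert abs(emp - exact) < 3 * se

    def test_fixed_horizon_freezes_absorbed_runs(self):
        # strong selection at tiny Ne absorbs quickly; accumulators must stop
        res = es.simulate_batch(10, 5, es.ConstantFitness(3.0), 200,
                                n_generations=50, rng=6)
        absorbed = res.outcome != 2
        assert absorbed.any()
        assert np.all(res.n_generations[absorbed] <= 50)
        assert np.all(res.final_copies[res.outcome == 1] == 10)
        assert np.all(res.final_copies[res.outcome == 0] == 0)
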