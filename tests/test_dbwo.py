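from math import erf, pi, sqrt, tanh

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirselect import (BWOConfig, MCCVPlan, WhaleState, binarize, bwo_iterate,
                       dbwo_select, levy_step, transfer)
from nirselect.dbwo import levy_sigma


class TestTransferFunctions:
    def test_reference_values(self):
        assert transfer(0.0, "sigmoid") == 0.5
        assert transfer(0.0, "V1") == 0.0
        assert transfer(0.0, "V2") == 0.0
        np.testing.assert_allclose(transfer(1.0, "V2"), abs(tanh(1.0)))
        np.testing.assert_allclose(transfer(1.0, "V1"),
                                   abs(erf(sqrt(pi) / 2)))

    @given(st.floats(-50, 50), st.sampled_from(["sigmoid", "V1", "V2"]))
    @settings(max_examples=200, deadline=None)
    def test_range_and_v_shape_evenness(self, x, kind):
        v = transfer(x, kind)
        assert 0.0 <= v <= 1.0
        if kind != "sigmoid":
            np.testing.assert_allclose(transfer(-x, kind), v, atol=1e-15)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            transfer(np.nan, "V2")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            transfer(0.0, "W3")


class TestLevyFlight:
    def test_mantegna_sigma_closed_form(self):
        np.testing.assert_allclose(levy_sigma(1.5), 0.696575, atol=1e-5)

    def test_reproducible(self):
        a = levy_step(20, 1.5, 0.1, np.random.default_rng(5))
        b = levy_step(20, 1.5, 0.1, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_tail_heavier_than_gaussian(self):
        from scipy.stats import kurtosis
        draws = levy_step(100_000, 1.5, 1.0, np.random.default_rng(0))
        assert kurtosis(draws) > 10  # excess kurtosis, wide margin over 0

    def test_beta_out_of_range(self):
        with pytest.raises(ValueError):
            levy_step(5, 2.5, 1.0, np.random.default_rng(0))


class TestBinarize:
    def test_v_shape_zero_step_never_flips(self, rng):
        prev = rng.uniform(size=50) < 0.5
        pos = rng.uniform(-6, 6, size=50)
        # identical previous position => step 0 => flip probability 0
        out = binarize(pos, prev, "V2", 1, rng, previous_position=pos)
        np.testing.assert_array_equal(out, prev)

    def test_s_shape_saturates_to_all_ones(self, rng):
        out = binarize(np.full(30, 500.0), np.zeros(30, bool), "sigmoid", 1, rng)
        assert out.all()

    def test_minimum_selection_guard(self, rng):
        # S-shaped with hugely negative positions: every bit off, then the
        # guard must switch exactly n_lv random channels back on
        out = binarize(np.full(40, -500.0), np.zeros(40, bool), "sigmoid", 5, rng)
        assert out.sum() == 5

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            binarize(np.zeros(3), np.zeros(4, bool), "V2", 1, rng)


def _quadratic_fitness(target):
    """Fitness = hamming distance to a target mask (plus tiny constant)."""
    def f(bits):
        return float(np.sum(bits != target)) + 0.5
    return f


def _init_state(p, pop, n_lv, rng):
    positions = rng.uniform(-6, 6, size=(pop, p))
    bits = rng.uniform(size=(pop, p)) < 0.5
    bits[:, :n_lv] = True
    fit = np.full(pop, np.inf)
    state = WhaleState(positions=positions, bits=bits, fitness=fit,
                       best_bits=bits[0].copy(), best_fitness=np.inf,
                       n_lv=n_lv)
    state.best_position = positions[0].copy()
    return state


class TestIteration:
    def test_incumbent_never_worsens_and_bounds_hold(self, rng):
        cfg = BWOConfig(pop_size=8, max_iter=30, seed=0)
        target = rng.uniform(size=40) < 0.3
        f = _quadratic_fitness(target)
        state = _init_state(40, 8, 2, rng)
        state.fitness = np.array([f(b) for b in state.bits])
        i = int(np.argmin(state.fitness))
        state.best_fitness = state.fitness[i]
        state.best_bits = state.bits[i].copy()
        state.best_position = state.positions[i].copy()
        prev = state.best_fitness
        for _ in range(30):
            bwo_iterate(state, cfg, f, "V2", rng)
            assert state.best_fitness <= prev
            prev = state.best_fitness
            assert state.positions.min() >= cfg.lower
            assert state.positions.max() <= cfg.upper
            assert all(b.sum() >= state.n_lv for b in state.bits)

    def test_zero_whale_fall_schedule_never_triggers(self, rng):
        cfg = BWOConfig(pop_size=6, max_iter=20, wf_start=0.0, wf_end=0.0, seed=0)
        target = rng.uniform(size=20) < 0.5
        f = _quadratic_fitness(target)
        state = _init_state(20, 6, 1, rng)
        state.fitness = np.array([f(b) for b in state.bits])
        for _ in range(20):
            bwo_iterate(state, cfg, f, "sigmoid", rng)
        assert state.whale_falls == 0

    def test_identical_seeds_give_identical_trajectories(self, rng):
        target = np.zeros(25, bool)
        target[:8] = True
        f = _quadratic_fitness(target)
        cfg = BWOConfig(pop_size=5, max_iter=10, seed=3)
        outs = []
        for _ in range(2):
            g = np.random.default_rng(99)
            state = _init_state(25, 5, 2, g)
            state.fitness = np.array([f(b) for b in state.bits])
            for _ in range(10):
                bwo_iterate(state, cfg, f, "V1", g)
            outs.append((state.positions.copy(), state.bits.copy(),
                         state.fitness.copy(), state.best_fitness))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        np.testing.assert_array_equal(outs[0][1], outs[1][1])
        np.testing.assert_array_equal(outs[0][2], outs[1][2])
        assert outs[0][3] == outs[1][3]


class TestDBWOSelect:
    PLAN = MCCVPlan(n_repeats=5, calib_fraction=0.8, seed=1)

    def test_curve_monotone_and_reproducible(self, benchmark):
        ds, informative, cal = benchmark
        cfg = BWOConfig(pop_size=6, max_iter=12, seed=5)
        a = dbwo_select(ds, 4, cfg, tf="V2", plan=self.PLAN)
        b = dbwo_select(ds, 4, cfg, tf="V2", plan=self.PLAN)
        assert np.all(np.diff(a.fitness_curve) <= 1e-15)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_allclose(a.fitness_curve, b.fitness_curve)
        assert a.method == "DBWO" and a.n_selected >= 4

    def test_improves_on_full_spectrum_fitness(self, benchmark):
        ds, informative, cal = benchmark
        from nirselect import rmsecv
        cfg = BWOConfig(pop_size=10, max_iter=30, seed=2)
        res = dbwo_select(ds, 4, cfg, tf="V2", plan=self.PLAN)
        full = rmsecv(ds.X, ds.y, 4, self.PLAN)
        assert res.fitness_curve[-1] <= full

    def test_infeasible_n_lv_rejected(self, benchmark):
        ds, _, _ = benchmark
        with pytest.raises(ValueError):
            dbwo_select(ds, ds.n_samples + 1, BWOConfig(pop_size=4, max_iter=2))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BWOConfig(pop_size=1)
        with pytest.raises(ValueError):
            BWOConfig(levy_beta=2.5)
        with pytest.raises(ValueError):
            BWOConfig(lower=2.0, upper=-2.0)
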