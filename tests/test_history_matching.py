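"""Implausibility arithmetic, waves, diagnostics and region intersection."""

import numpy as np
import pytest

from cardiogsa.history_matching import (
    Target,
    _diagnostics,
    final_threshold_check,
    implausibility,
    intersect_regions,
    run_wave,
    wave_diagnostics,
)
from cardiogsa.parameter_space import (
    DesignMatrix,
    SimulationBatch,
    latin_hypercube,
    space_from_table,
)

from conftest import unit_space


class TestImplausibility:
    def test_zero_at_target(self):
        I = implausibility([[2.0]], [[0.5]], [Target("y", 2.0, 1.0)])
        assert I[0] == 0.0

    def test_hand_value(self):
        # (5 - 2) / sqrt(0 + 1) = 3
        I = implausibility([[5.0]], [[0.0]], [Target("y", 2.0, 1.0)])
        assert I[0] == pytest.approx(3.0)

    def test_max_rule(self):
        targets = [Target("a", 0.0, 1.0), Target("b", 0.0, 1.0)]
        I = implausibility([[1.0, 2.0]], [[0.0, 0.0]], targets)
        assert I[0] == pytest.approx(2.0)

    def test_target_mismatch_rejected(self):
        with pytest.raises(ValueError):
            implausibility([[1.0, 2.0]], [[0.1, 0.1]], [Target("y", 0.0, 1.0)])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            Target("y", 1.0, 0.0)


class TestThresholdSchedule:
    def test_valid_schedules(self):
        assert final_threshold_check([5.0, 4.0, 3.0]) == [5.0, 4.0, 3.0]
        assert final_threshold_check([3.0]) == [3.0]

    def test_increasing_rejected(self):
        with pytest.raises(ValueError):
            final_threshold_check([3.0, 4.0])

    def test_final_above_three_corrected(self):
        with pytest.warns(UserWarning):
            sched = final_threshold_check([5.0, 4.0])
        assert sched[-1] == 3.0


class TestIntersectRegions:
    def test_truncation_to_smallest(self):
        s1, s2 = unit_space(2), None
        s2 = space_from_table(
            [{"name": "z1", "role": "free", "bounds": [0, 1]}])
        c1 = DesignMatrix(np.random.default_rng(0).random((3, 2)), s1, "cloud")
        c2 = DesignMatrix(np.random.default_rng(1).random((5, 1)), s2, "cloud")
        joint = intersect_regions([c1, c2], seed=0)
        assert joint.values.shape == (3, 3)
        assert joint.space.names == ["x1", "x2", "z1"]

    def test_single_cloud_identity(self):
        space = unit_space(2)
        c = DesignMatrix(np.random.default_rng(2).random((4, 2)), space, "cloud")
        joint = intersect_regions([c], seed=1)
        assert {tuple(r) for r in joint.values} == {tuple(r) for r in c.values}

    def test_overlapping_blocks_rejected(self):
        space = unit_space(2)
        c = DesignMatrix(np.zeros((2, 2)), space, "cloud")
        with pytest.raises(ValueError, match="overlap"):
            intersect_regions([c, c], seed=0)

    def test_marginals_preserved_under_pairing(self):
        # equal cloud sizes: each block's marginal is exactly permuted
        sa = unit_space(1)
        sb = space_from_table(
            [{"name": "w", "role": "free", "bounds": [0, 1]}])
        a = DesignMatrix(np.random.default_rng(3).random((6, 1)), sa, "cloud")
        b = DesignMatrix(np.random.default_rng(4).random((6, 1)), sb, "cloud")
        joint = intersect_regions([a, b], seed=5)
        assert sorted(joint.values[:, 0]) == sorted(a.values[:, 0])
        assert sorted(joint.values[:, 1]) == sorted(b.values[:, 0])


def _toy_simulator(X):
    return (X[:, :1] ** 2), np.ones(len(X), bool)


def _toy_wave(seed, I_th=3.0, n_train=15, n_test=3000, waves=2, sigma=0.01):
    space = unit_space(1, lo=-1.0, hi=1.0)
    targets = [Target("y", 0.25, sigma)]
    design = latin_hypercube(space, n_train, seed)
    Y, ok = _toy_simulator(design.values)
    state = SimulationBatch(design, Y, ["y"], ok)
    fit_kw = dict(n_restarts=2)
    for w in range(waves):
        state = run_wave(state, _toy_simulator, targets, I_th=I_th,
                         n_test=n_test, n_simul=8, seed=seed + w,
                         fit_kwargs=fit_kw)
    return state


class TestWaves:
    def test_toy_target_recovery_brackets_roots(self):
        """f(x) = x^2 with target 0.25 +/- 0.01: the surviving cloud
        concentrates near the analytic pre-image x = +/-0.5."""
        state = _toy_wave(seed=10)
        assert state.plausible.any()
        x = state.test_cloud.values[state.plausible, 0]
        assert np.abs(np.abs(x) - 0.5).max() < 0.1
        # both roots are represented
        assert (x > 0).any() and (x < 0).any()

    def test_infinite_threshold_degenerates(self):
        state = _toy_wave(seed=3, I_th=np.inf, waves=1)
        assert state.plausible.all()

    def test_percent_plausible_non_increasing(self):
        """Across three waves the non-implausible share does not grow
        (statistically, five seeds)."""
        drops = []
        for seed in range(5):
            space = unit_space(1, lo=-1.0, hi=1.0)
            targets = [Target("y", 0.25, 0.02)]
            design = latin_hypercube(space, 12, seed)
            Y, ok = _toy_simulator(design.values)
            state = SimulationBatch(design, Y, ["y"], ok)
            percents = []
            for w in range(3):
                state = run_wave(state, _toy_simulator, targets, I_th=3.0,
                                 n_test=2000, n_simul=6, seed=100 + seed + w,
                                 fit_kwargs=dict(n_restarts=2))
                percents.append(state.diagnostics.percent_plausible)
            drops.append(percents[-1] - percents[0])
        assert np.mean(drops) <= 1.0  # small MC tolerance

    def test_sigma_limits(self):
        wide = _toy_wave(seed=6, waves=1, sigma=1e3)
        assert wide.plausible.all()
        hopeless_targets = [Target("y", 50.0, 1e-6)]
        space = unit_space(1, lo=-1.0, hi=1.0)
        design = latin_hypercube(space, 12, 0)
        Y, ok = _toy_simulator(design.values)
        with pytest.warns(UserWarning, match="no plausible"):
            state = run_wave(SimulationBatch(design, Y, ["y"], ok),
                             _toy_simulator, hopeless_targets, I_th=3.0,
                             n_test=500, seed=0,
                             fit_kwargs=dict(n_restarts=2))
        assert state.exhausted

    def test_training_set_grows_between_waves(self):
        s1 = _toy_wave(seed=8, waves=1)
        s2 = _toy_wave(seed=8, waves=2)
        assert len(s2.batch.design) > len(s1.batch.design)

    def test_diagnostics_summaries(self):
        state = _toy_wave(seed=9, waves=1)
        d = state.diagnostics
        assert 0.0 <= d.percent_plausible <= 100.0
        assert d.max_I >= d.mean_I
        assert d.max_vratio >= d.mean_vratio
        recomputed = wave_diagnostics(state, [Target("y", 0.25, 0.01)])
        assert recomputed.percent_plausible == pytest.approx(
            d.percent_plausible)

    def test_diagnostics_hand_cases(self):
        targets = [Target("y", 0.0, 2.0)]
        d = _diagnostics(np.zeros(10), np.full((10, 1), 2.0), targets, 3.0)
        assert d.percent_plausible == 100.0
        assert d.mean_I == 0.0
        assert d.mean_vratio == pytest.approx(1.0)  # GP sd equals sigma
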