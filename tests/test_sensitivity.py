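"""Sobol total effects, ranking/retention, signed effects and screening."""

import numpy as np
import pytest

from cardiogsa.emulator import fit_gpe
from cardiogsa.history_matching import Target
from cardiogsa.parameter_space import latin_hypercube
from cardiogsa.sensitivity import (
    ConstraintSet,
    SobolResult,
    generate_plausible_base,
    rank_and_retain,
    screen_samples,
    signed_effects,
    total_effects,
)

from conftest import unit_space


def ishigami(X, a=7.0, b=0.1):
    return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
            + b * X[:, 2] ** 4 * np.sin(X[:, 0]))


#: closed-form Ishigami total effects for a=7, b=0.1
ISHIGAMI_ST = np.array([0.5576, 0.4424, 0.2437])


class TestTotalEffects:
    def test_single_variable_function(self):
        space = unit_space(3)
        res = total_effects([lambda X: X[:, 0]], space, 4096, n_draws=1, seed=0)
        np.testing.assert_allclose(
            res.total_effects[:, 0], [1.0, 0.0, 0.0], atol=0.02)

    def test_ishigami_closed_form(self):
        space = unit_space(3, lo=-np.pi, hi=np.pi)
        res = total_effects([ishigami], space, 8192, n_draws=1, seed=0)
        np.testing.assert_allclose(res.total_effects[:, 0], ISHIGAMI_ST,
                                   atol=0.03)
        # interactions present: total effects sum above one
        assert res.total_effects[:, 0].sum() > 1.0

    def test_additive_function_first_order_equals_total(self):
        space = unit_space(3)
        res = total_effects(
            [lambda X: X[:, 0] + 2.0 * X[:, 1] - X[:, 2]],
            space, 4096, n_draws=1, seed=0,
        )
        assert res.first_order[:, 0].sum() == pytest.approx(
            res.total_effects[:, 0].sum(), abs=0.03)

    def test_constant_output_warns_and_zeros(self):
        space = unit_space(2)
        with pytest.warns(UserWarning, match="constant"):
            res = total_effects([lambda X: np.full(len(X), 5.0)], space,
                                512, n_draws=1, seed=0)
        assert (res.total_effects == 0).all()

    def test_jansen_matches_brute_force_double_loop(self):
        """Jansen estimator vs double-loop Monte-Carlo on a 3-D polynomial."""
        def poly(X):
            return X[:, 0] + 2.0 * X[:, 1] ** 2 + X[:, 0] * X[:, 2]

        space = unit_space(3)
        res = total_effects([poly], space, 8192, n_draws=1, seed=0)

        # brute force: S_Ti = E[Var(f | x_~i)] / Var(f), repeated to get a
        # standard error for the comparison
        rng = np.random.default_rng(42)
        reps = []
        for _ in range(10):
            n_outer, n_inner = 400, 200
            st = np.zeros(3)
            base = rng.random((n_outer, 3))
            for i in range(3):
                Xr = np.repeat(base[:, None, :], n_inner, axis=1)
                Xr[:, :, i] = rng.random((n_outer, n_inner))
                vals = poly(Xr.reshape(-1, 3)).reshape(n_outer, n_inner)
                st[i] = vals.var(axis=1, ddof=1).mean()
            allv = poly(rng.random((20000, 3)))
            reps.append(st / allv.var())
        reps = np.array(reps)
        mean_bf = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert (np.abs(res.total_effects[:, 0] - mean_bf) < 3 * se + 0.01).all()


class TestRanking:
    def _result(self, st_matrix):
        st_matrix = np.atleast_2d(np.asarray(st_matrix, float)).T
        D = st_matrix.shape[0]
        return SobolResult(
            st_matrix, np.zeros_like(st_matrix), np.zeros_like(st_matrix),
            [f"p{i}" for i in range(D)], ["y0"], 8, 1, 0,
        )

    def test_cumulative_retention(self):
        ranking = rank_and_retain(self._result([0.6, 0.3, 0.1]), 0.90)
        assert ranking.retained == ["p0", "p1"]
        assert ranking.normalized_max.sum() == pytest.approx(1.0, abs=1e-9)

    def test_equal_scores_retain_all(self):
        ranking = rank_and_retain(self._result([0.2] * 4), 0.90)
        assert len(ranking.retained) == 4

    def test_ties_broken_by_stable_order(self):
        ranking = rank_and_retain(self._result([0.3, 0.3, 0.4]), 0.90)
        assert ranking.order == ["p2", "p0", "p1"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rank_and_retain(self._result([0.0, 0.0]))


class TestSignedEffects:
    class _FakeModel:
        def __init__(self, beta):
            self.beta = np.asarray(beta, float)

    def test_sign_attachment(self):
        st = np.array([[0.4], [0.2]])
        res = SobolResult(st, st * 0, st * 0, ["a", "b"], ["y"], 8, 1, 0)
        signed = signed_effects(res, [self._FakeModel([0.0, -1.0, 0.0])])
        assert signed[0, 0] == pytest.approx(-0.4)
        assert signed[1, 0] == 0.0

    def test_signs_match_finite_difference_slopes(self):
        """Emulator beta signs agree with central-difference slopes of the
        generating function at the box centre for the dominant inputs."""
        def f(X):
            return 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.2 * np.sin(X[:, 2])

        space = unit_space(3)
        design = latin_hypercube(space, 60, seed=0)
        model = fit_gpe(design.values, f(design.values),
                        bounds=space.bounds, seed=0)
        centre = np.full((1, 3), 0.5)
        for i in range(2):
            e = np.zeros(3)
            e[i] = 0.05
            fd = f(centre + e) - f(centre - e)
            assert np.sign(model.beta[1 + i]) == np.sign(fd[0])


class TestScreening:
    def _constraint(self, space, target_value, sigma=0.1):
        design = latin_hypercube(space, 40, seed=0)
        y = design.values[:, 0]
        model = fit_gpe(design.values, y, bounds=space.bounds, seed=0)
        return ConstraintSet([model], [Target("y", target_value, sigma)], [0])

    def test_no_constraints_all_pass(self):
        design = latin_hypercube(unit_space(2), 50, seed=1)
        assert screen_samples(design, [], I_th=3.0).all()

    def test_unreachable_target_rejects_everything(self):
        space = unit_space(1)
        cset = self._constraint(space, target_value=50.0, sigma=0.01)
        design = latin_hypercube(space, 100, seed=2)
        assert not screen_samples(design, [cset], I_th=3.0).any()
        with pytest.raises(ValueError):
            generate_plausible_base(space, [cset], n_required=50, seed=0,
                                    max_iter=3)

    def test_screening_reproducible(self):
        space = unit_space(1)
        cset = self._constraint(space, target_value=0.5, sigma=0.05)
        a = generate_plausible_base(space, [cset], n_required=30, seed=5)
        b = generate_plausible_base(space, [cset], n_required=30, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        assert (np.abs(a.values[:, 0] - 0.5) < 0.25).all()

    def test_overlapping_blocks_rejected(self):
        space = unit_space(2)
        c1 = self._constraint(unit_space(1), 0.5)
        c2 = ConstraintSet(c1.models, c1.targets, [0])
        design = latin_hypercube(space, 10, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            screen_samples(design, [c2, c2], I_th=3.0)


def test_posterior_draw_sd_shrinks_with_training_size():
    """Across-draw spread of the total effects falls as the emulator is
    trained on more simulations."""
    space = unit_space(2)

    def f(X):
        return np.sin(3 * X[:, 0]) + X[:, 1]

    spreads = []
    for n in (15, 120):
        design = latin_hypercube(space, n, seed=3)
        model = fit_gpe(design.values, f(design.values),
                        bounds=space.bounds, seed=0)
        res = total_effects([model], space, 512, n_draws=40, seed=1)
        spreads.append(res.total_effects_sd[:, 0].mean())
    assert spreads[1] < spreads[0]
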