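"""Calcium/tension surrogates and passive Guccione mechanics."""

import numpy as np
import pytest

from cardiogsa import cell_and_passive as cp


class TestCalcium:
    def test_single_beat_peak_normalisation(self):
        params = cp.CalciumParams()
        ca = cp.simulate_calcium(params, bcl=4000.0, n_beats=1, dt=0.1)
        expected = params.Ca_dias + params.Ca_amp * params.amp_scale
        assert ca.value.max() == pytest.approx(expected, rel=1e-4)

    def test_amp_scale_linearity(self):
        p1 = cp.CalciumParams(amp_scale=1.0)
        p2 = cp.CalciumParams(amp_scale=2.0)
        c1 = cp.simulate_calcium(p1, 854.0, n_beats=4)
        c2 = cp.simulate_calcium(p2, 854.0, n_beats=4)
        a1 = c1.value.max() - p1.Ca_dias
        a2 = c2.value.max() - p2.Ca_dias
        assert a2 == pytest.approx(2.0 * a1, rel=1e-6)
        # time-to-peak unchanged
        assert c1.value.argmax() == c2.value.argmax()

    def test_pacing_grid_matches_bcl(self):
        ca = cp.simulate_calcium(cp.CalciumParams(), 854.0, n_beats=2, dt=1.0)
        assert ca.bcl == 854.0
        assert ca.t[-1] == pytest.approx(2 * 854.0, abs=1.0)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            cp.CalciumParams(tau_rise=200.0, tau_decay=100.0)

    def test_non_convergence_warns(self):
        slow = cp.CalciumParams(tau_decay=3000.0)
        with pytest.warns(UserWarning, match="not converged"):
            cp.simulate_calcium(slow, 500.0, n_beats=2)


class TestTension:
    def test_saturating_calcium_reaches_reference_tension(self):
        """Sustained saturating calcium drives the strong fraction to r_s
        and hence tension to T_ref, within 1%."""
        params = cp.LandParams()
        t = np.arange(0.0, 4000.0, 1.0)
        ca = cp.CalciumTransient(t, np.full_like(t, 50.0), bcl=4000.0)
        T = cp.simulate_tension(ca, params, dt=0.05)
        assert T.value[-1] == pytest.approx(params.T_ref, rel=0.01)

    def test_steady_state_pool_ratios(self):
        """The rate choices pin the P=1 fixed point at S = r_s, W/S = r_w."""
        params = cp.LandParams()
        k_uw, k_ws, k_wu, k_sw = cp._tension_rates(params)
        # linear steady state with P = 1:
        #   W' = k_uw (1 - W - S) - (k_wu + k_ws) W + k_sw S = 0
        #   S' = k_ws W - k_sw S = 0
        M = np.array([
            [k_uw + k_wu + k_ws, k_uw - k_sw],
            [-k_ws, k_sw],
        ])
        W, S = np.linalg.solve(M, np.array([k_uw, 0.0]))
        assert S == pytest.approx(params.r_s, rel=1e-9)
        assert W / S == pytest.approx(params.r_w, rel=1e-9)

    def test_diastolic_calcium_gives_negligible_tension(self):
        params = cp.LandParams()
        t = np.arange(0.0, 4000.0, 1.0)
        ca = cp.CalciumTransient(t, np.full_like(t, 0.1), bcl=4000.0)
        T = cp.simulate_tension(ca, params, dt=0.05)
        assert T.value.max() < 0.05 * params.T_ref

    def test_batched_integration_matches_single(self):
        params = cp.LandParams()
        ca1 = cp.simulate_calcium(cp.CalciumParams(), 854.0, n_beats=2)
        stacked = cp.CalciumTransient(
            ca1.t, np.vstack([ca1.value, ca1.value]), 854.0)
        single = cp.simulate_tension(ca1, params, dt=0.1)
        batch = cp.simulate_tension(stacked, [params, params], dt=0.1,
                                    buffer_scale=np.array([1.0, 1.0]))
        np.testing.assert_allclose(batch.value[0], single.value, rtol=1e-12)
        np.testing.assert_allclose(batch.value[1], single.value, rtol=1e-12)

    def test_velocity_factor_clamped(self):
        params = cp.LandParams()
        ca = cp.simulate_calcium(cp.CalciumParams(), 854.0, n_beats=2)
        v = np.full_like(ca.t, 1.0)  # strong shortening
        T = cp.simulate_tension(ca, params, velocity_series=v, dt=0.1)
        assert (T.value >= 0).all()
        assert T.value.max() == 0.0  # factor clamps to zero at this velocity


class TestTransientFeatures:
    def test_triangular_pulse(self):
        t = np.arange(0.0, 101.0, 1.0)
        v = np.where(t <= 50, t / 50.0, (100.0 - t) / 50.0)
        f = cp.transient_features(cp.CalciumTransient(t, v, bcl=100.0))
        assert f.time_to_peak == pytest.approx(50.0)
        assert f.peak == pytest.approx(1.0)
        # 90% recovery toward the zero baseline happens at v = 0.1
        assert f.duration90 == pytest.approx(95.0, abs=1.0)

    def test_constant_series(self):
        t = np.arange(0.0, 101.0, 1.0)
        f = cp.transient_features(cp.CalciumTransient(t, np.full_like(t, 2.0),
                                                      bcl=100.0))
        assert f.amplitude == 0.0 and f.duration90 == 0.0

    def test_grid_refinement_invariance(self):
        params = cp.LandParams()
        ca = cp.simulate_calcium(cp.CalciumParams(), 854.0, n_beats=3)
        f1 = cp.transient_features(cp.simulate_tension(ca, params, dt=0.05))
        f2 = cp.transient_features(cp.simulate_tension(ca, params, dt=0.025))
        for name in ("peak", "time_to_peak", "duration90"):
            assert getattr(f1, name) == pytest.approx(
                getattr(f2, name), rel=0.01)


class TestGuccione:
    params = cp.GuccioneParams(a=1.0, b_f=8.0, b_ft=4.0, b_t=3.0)

    def test_energy_hand_values(self):
        E = np.zeros((3, 3))
        E[0, 0] = 0.1
        assert cp.strain_energy(E, 1.0, self.params) == pytest.approx(
            0.5 * (np.exp(0.08) - 1.0))
        E2 = np.zeros((3, 3))
        E2[1, 1] = 0.1
        assert cp.strain_energy(E2, 1.0, self.params) == pytest.approx(
            0.5 * (np.exp(0.03) - 1.0))

    def test_zero_strain(self):
        assert cp.strain_energy(np.zeros((3, 3)), 1.0, self.params) == 0.0
        assert (cp.pk2_stress(np.zeros((3, 3)), self.params) == 0.0).all()

    def test_stress_hand_value(self):
        E = np.zeros((3, 3))
        E[0, 0] = 0.1
        S = cp.pk2_stress(E, self.params)
        assert S[0, 0] == pytest.approx(0.8 * np.exp(0.08))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cp.strain_energy(np.zeros((3, 3)), -1.0, self.params)
        E = np.zeros((3, 3))
        E[0, 1] = 0.1  # asymmetric
        with pytest.raises(ValueError):
            cp.strain_energy(E, 1.0, self.params)

    def test_stress_is_energy_gradient(self):
        """PK2 matches central finite differences of the energy over 100
        random small strains (symmetric perturbation of each component)."""
        rng = np.random.default_rng(7)
        eps = 1e-6
        for _ in range(100):
            E = rng.normal(0.0, 0.05, (3, 3))
            E = 0.5 * (E + E.T)
            S = cp.pk2_stress(E, self.params)
            for i in range(3):
                for j in range(i, 3):
                    Ep, Em = E.copy(), E.copy()
                    Ep[i, j] += eps
                    Ep[j, i] = Ep[i, j]
                    Em[i, j] -= eps
                    Em[j, i] = Em[i, j]
                    fd = (cp.strain_energy(Ep, 1.0, self.params)
                          - cp.strain_energy(Em, 1.0, self.params)) / (2 * eps)
                    assert fd == pytest.approx(S[i, j], rel=1e-4, abs=1e-8)

    def test_convex_along_fibre_stretch(self):
        e = np.linspace(0.0, 0.2, 41)
        psi = np.array([
            cp.strain_energy(np.diag([x, 0.0, 0.0]), 1.0, self.params)
            for x in e
        ])
        assert (np.diff(psi, 2) > -1e-12).all()


class TestChamberInflation:
    gv = cp.VENTRICULAR_GUCCIONE

    def test_zero_pressure_identity(self):
        v, e = cp.inflate_chamber(self.gv, 110.0, 60.0, 0.0)
        assert v == 60.0 and e == 0.0

    def test_volume_monotone_in_pressure(self):
        ps = np.linspace(0.0, 30.0, 16)
        vs = [cp.inflate_chamber(self.gv, 110.0, 60.0, p)[0] for p in ps]
        assert (np.diff(vs) > 0).all()

    def test_compliance_decreases(self):
        """dV/dp falls with pressure (strain stiffening)."""
        ps = np.linspace(1.0, 30.0, 30)
        vs = np.array([cp.inflate_chamber(self.gv, 110.0, 60.0, p)[0]
                       for p in ps])
        dvdp = np.gradient(vs, ps)
        assert dvdp[-1] < dvdp[0]
        assert (dvdp > 0).all()

    def test_stiffer_wall_inflates_less(self):
        soft = cp.inflate_chamber(cp.GuccioneParams(a=1.0), 110.0, 60.0, 8.0)
        stiff = cp.inflate_chamber(cp.GuccioneParams(a=2.0), 110.0, 60.0, 8.0)
        assert stiff[0] < soft[0]

    def test_unload_round_trip(self):
        v0 = cp.unload_chamber(self.gv, 110.0, 150.0, 8.8)
        v, _ = cp.inflate_chamber(self.gv, 110.0, v0, 8.8)
        assert v == pytest.approx(150.0, rel=1e-4)

    def test_higher_edp_smaller_unloaded_volume(self):
        v1 = cp.unload_chamber(self.gv, 110.0, 150.0, 4.0)
        v2 = cp.unload_chamber(self.gv, 110.0, 150.0, 9.0)
        assert v2 < v1

    def test_zero_edp_identity(self):
        assert cp.unload_chamber(self.gv, 110.0, 150.0, 0.0) == 150.0
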