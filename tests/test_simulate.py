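import math
from dataclasses import replace

import numpy as np
import pytest

from springboard import kinematics as kin
from springboard.errors import ValidationError
from springboard.simulate import SimConfig, render_recording, simulate, sweep


RIGID = SimConfig(k_p=math.inf, noise_sd=0.0)


class TestTakeoffLimits:
    @pytest.mark.parametrize("profile", ["leg_linkage", "linear_spring"])
    def test_rigid_substrate_closed_form_speed(self, profile):
        cfg = replace(RIGID, force_profile=profile)
        res = simulate(cfg)
        assert res.takeoff_speed == pytest.approx(cfg.rigid_takeoff_speed, rel=1e-6)

    def test_very_stiff_platform_approaches_rigid(self):
        cfg = SimConfig(k_p=3.42e6, m_p_eff=1e-3, platform_damping_ratio=0.0)
        res = simulate(cfg)
        assert res.takeoff_speed == pytest.approx(cfg.rigid_takeoff_speed, rel=1e-3)

    def test_immovable_platform_approaches_rigid(self):
        cfg = SimConfig(k_p=24.0, m_p_eff=10.0)  # ~10 kg tip mass
        res = simulate(cfg)
        assert res.takeoff_speed == pytest.approx(cfg.rigid_takeoff_speed, rel=1e-2)
        assert res.max_platform_displacement < 1e-4


class TestEnergyLedger:
    @pytest.mark.parametrize("profile", ["leg_linkage", "linear_spring"])
    def test_conservation_without_damping(self, profile):
        cfg = SimConfig(
            k_p=10.0, m_p_eff=5e-4, platform_damping_ratio=0.0, force_profile=profile
        )
        res = simulate(cfg)
        assert res.energy_drift <= 1e-3 * res.initial_energy

    def test_stored_energy_identity(self):
        res = simulate(SimConfig(k_p=24.0))
        assert res.ledger["leg_spring_pe"].iloc[0] == pytest.approx(
            0.5 * res.config.k_g_true * res.config.x_true**2
        )

    def test_damping_dissipates_monotonically(self):
        res = simulate(SimConfig(k_p=2.0, platform_damping_ratio=0.1))
        d = res.ledger["dissipated"].to_numpy()
        assert np.all(np.diff(d) >= -1e-15)
        assert d[-1] > 0

    def test_momentum_bookkeeping(self):
        res = simulate(SimConfig(k_p=10.0, m_p_eff=5e-4, platform_damping_ratio=0.0))
        p_scale = res.config.m_g * res.takeoff_speed
        assert res.momentum_residual <= 1e-6 * p_scale


class TestRecoilEvent:
    def test_fig7_like_configuration(self):
        # light stiff board: bottoms out, then recoils while still loaded
        res = simulate(SimConfig(k_p=24.0, m_p_eff=2.5e-4))
        assert res.recoil_before_takeoff
        assert res.t_max_platform_displacement < res.takeoff_time
        assert res.max_platform_displacement > 1e-3

    def test_no_recoil_on_very_compliant_board(self):
        res = simulate(SimConfig(k_p=1.0, m_p_eff=1.2e-3))
        assert not res.recoil_before_takeoff


class TestRenderRecording:
    def test_noise_free_positions_equal_truth(self):
        res = simulate(replace(RIGID, seed=5))
        rec, truth = render_recording(res, platform_id="control")
        i = rec.last_contact_frame
        t = (i - rec.first_movement_frame) / rec.frame_rate
        s_g = res.state_at(t)[0]
        u = math.sqrt(0.5)  # 45 deg thrust axis
        assert rec.body_series.at_frame(i)[0] == pytest.approx(s_g * u, abs=1e-12)
        assert truth["takeoff_speed"] == pytest.approx(res.takeoff_speed)

    def test_same_seed_is_deterministic(self):
        cfg = SimConfig(k_p=24.0, noise_sd=1e-4, seed=11)
        r1, _ = render_recording(simulate(cfg), platform_id="B", line_index=1)
        r2, _ = render_recording(simulate(cfg), platform_id="B", line_index=1)
        np.testing.assert_array_equal(r1.body_series.x, r2.body_series.x)
        np.testing.assert_array_equal(r1.tarsus_series.y, r2.tarsus_series.y)

    def test_chord_speed_close_to_true_speed(self):
        res = simulate(RIGID)
        rec, truth = render_recording(res, platform_id="control")
        v_chord = kin.take_off_velocity(rec)
        assert v_chord == pytest.approx(truth["takeoff_speed"], rel=0.015)

    def test_insufficient_duration_rejected(self):
        res = simulate(RIGID, post_takeoff_s=0.002)
        with pytest.raises(ValidationError, match="10 ms"):
            render_recording(res)


class TestSweep:
    @pytest.fixture(scope="class")
    @staticmethod
    def light_sweep():
        base = SimConfig()
        k = base.k_g_true * np.array([0.3, 0.5, 0.7, 0.9, 10.0, 50.0, 200.0])
        return base, sweep(base, k, [2.5e-4])

    def test_rel_ke_nondecreasing_below_k_g(self, light_sweep):
        base, tab = light_sweep
        sub = tab[tab.k_p < base.k_g_true].sort_values("k_p")
        assert np.all(np.diff(sub["rel_KE"]) >= 0)

    def test_stiff_platforms_preserve_speed(self, light_sweep):
        base, tab = light_sweep
        assert (tab.loc[tab.k_p >= 10 * base.k_g_true, "rel_speed"] >= 0.98).all()

    def test_compliant_platforms_reduce_speed(self, light_sweep):
        base, tab = light_sweep
        assert (tab.loc[tab.k_p < base.k_g_true, "rel_speed"] < 1.0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            sweep(SimConfig(), [], [1e-3])


class TestEndToEndRecovery:
    def test_k_g_recovery_noise_free(self, control_morph):
        x = kin.acceleration_distance(control_morph)
        cfg = replace(RIGID, x_true=x)
        res = simulate(cfg)
        rec, _ = render_recording(res, platform_id="control")
        v = kin.take_off_velocity(rec)
        k_est = control_morph.body_mass * v**2 / x**2
        assert k_est == pytest.approx(cfg.k_g_true, rel=0.02)

    def test_k_g_recovery_with_digitization_noise(self, control_morph):
        x = kin.acceleration_distance(control_morph)
        errs = []
        for seed in range(50):
            cfg = SimConfig(k_p=math.inf, x_true=x, noise_sd=1e-4, seed=seed)
            res = simulate(cfg)
            rec, _ = render_recording(res, platform_id="control")
            v = kin.take_off_velocity(rec)
            k_est = control_morph.body_mass * v**2 / x**2
            errs.append(abs(k_est - cfg.k_g_true) / cfg.k_g_true)
        assert np.mean(errs) < 0.05
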