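import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from springboard import kinematics as kin
from springboard.errors import DomainError, ValidationError
from springboard.tracking_io import Morphometrics

from conftest import make_recording


class TestTakeOffVelocity:
    def test_diagonal_chord(self):
        rec = make_recording((0.0, 0.0), (0.0102, 0.0102))
        assert kin.take_off_velocity(rec) == pytest.approx(1.4425, abs=2e-4)

    def test_stationary(self):
        rec = make_recording((0.0, 0.0), (0.0, 0.0))
        assert kin.take_off_velocity(rec) == 0.0

    def test_pure_vertical(self):
        rec = make_recording((0.0, 0.0), (0.0, 0.0144))
        assert kin.take_off_velocity(rec) == pytest.approx(1.44)

    def test_missing_window_frame_rejected(self):
        rec = make_recording()
        object.__setattr__(rec, "last_contact_frame", 27)  # frame 37 absent
        with pytest.raises(ValidationError, match="missing"):
            kin.take_off_velocity(rec)

    def test_non_integer_window_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            make_recording(frame_rate=1333.0)


class TestTimeToTakeoff:
    def test_28_frames_at_1000fps(self):
        rec = make_recording(first_movement=0, last_contact=28)
        assert kin.time_to_takeoff(rec) == pytest.approx(0.028)

    def test_shift_invariance(self):
        rec = make_recording(first_movement=12, last_contact=40)
        assert kin.time_to_takeoff(rec) == pytest.approx(0.028)

    def test_degenerate_zero_interval_warns(self):
        rec = make_recording(first_movement=28, last_contact=28)
        with pytest.warns(UserWarning, match="zero-frame"):
            assert kin.time_to_takeoff(rec) == 0.0


class TestPlatformDisplacement:
    def test_sagging_board(self):
        rec = make_recording(
            tarsus=((0.30, 0.0), (0.30, -0.020)),
            fixed_end=(0.0, 0.0),
            platform_id="A",
            line_index=6,
        )
        disp, angle = kin.platform_displacement(rec)
        assert disp == pytest.approx(0.020)
        assert angle == pytest.approx(-3.81, abs=0.01)

    def test_rigid_control_no_motion(self):
        rec = make_recording()  # no tarsus series
        assert kin.platform_displacement(rec) == (0.0, 0.0)

    def test_plane_angle_atan2(self):
        rec = make_recording(
            tarsus=((0.124, 0.0), (0.124, -0.0124)),
            fixed_end=(0.0, 0.0),
            platform_id="B",
            line_index=2,
        )
        _, angle = kin.platform_displacement(rec)
        assert angle == pytest.approx(-5.71, abs=0.01)


class TestElevation:
    def test_symmetric_diagonal_flat_plane(self):
        rec = make_recording((0.0, 0.0), (0.0102, 0.0102))
        assert kin.elevation(rec, 0.0) == pytest.approx(45.0)

    def test_sagging_plane_adds_angle(self):
        rec = make_recording((0.0, 0.0), (0.0102, 0.0102))
        assert kin.elevation(rec, -5.0) == pytest.approx(50.0)

    def test_vertical_takeoff(self):
        rec = make_recording((0.0, 0.0), (0.0, 0.005))
        assert kin.elevation(rec, 0.0) == pytest.approx(90.0)

    def test_zero_displacement_undefined(self):
        rec = make_recording((0.0, 0.0), (0.0, 0.0))
        with pytest.raises(DomainError):
            kin.elevation(rec, 0.0)


class TestAccelerationDistance:
    def test_law_of_cosines_at_control_means(self, control_morph):
        assert kin.acceleration_distance(control_morph) == pytest.approx(
            26.02e-3, abs=0.01e-3
        )

    def test_collinear_limit(self):
        m = Morphometrics("a", 1e-3, 0.0156, takeoff_angle_deg=179.9999)
        assert kin.acceleration_distance(m) == pytest.approx(2 * 0.0156, rel=1e-6)

    def test_folded_limit(self):
        m = Morphometrics("a", 1e-3, 0.0156, takeoff_angle_deg=1e-6)
        assert kin.acceleration_distance(m) == pytest.approx(0.0, abs=1e-9)

    @given(alphas=st.lists(st.floats(1.0, 179.0), min_size=2, max_size=6, unique=True))
    def test_monotone_in_takeoff_angle(self, alphas):
        alphas = sorted(alphas)
        xs = [
            kin.acceleration_distance(Morphometrics("a", 1e-3, 0.0156, a))
            for a in alphas
        ]
        assert all(a < b for a, b in zip(xs, xs[1:]))


class TestAcceleration:
    def test_mean_acceleration_of_control_jump(self):
        assert kin.acceleration(1.44, 0.028) == pytest.approx(51.43, abs=0.01)

    def test_null_jump(self):
        assert kin.acceleration(0.0, 0.028) == 0.0

    def test_time_scaling(self):
        assert kin.acceleration(1.44, 0.056) == pytest.approx(kin.acceleration(1.44, 0.028) / 2)

    def test_zero_time_rejected(self):
        with pytest.raises(DomainError):
            kin.acceleration(1.44, 0.0)


@given(phi=st.floats(-math.pi, math.pi))
def test_rotation_invariance(phi):
    """Rotating the scene and the plane angle together leaves speed,
    relative elevation and displacement magnitudes unchanged."""
    c, s = math.cos(phi), math.sin(phi)

    def rot(p):
        return (c * p[0] - s * p[1], s * p[0] + c * p[1])

    p0, p1 = (0.001, 0.002), (0.0102, 0.0155)
    t0, t1 = (0.30, 0.0), (0.299, -0.020)
    base = make_recording(p0, p1, tarsus=(t0, t1), platform_id="A", line_index=5)
    rotated = make_recording(
        rot(p0), rot(p1), tarsus=(rot(t0), rot(t1)),
        fixed_end=rot((0.0, 0.0)), platform_id="A", line_index=5,
    )
    assert kin.take_off_velocity(rotated) == pytest.approx(
        kin.take_off_velocity(base), rel=1e-9
    )
    d0, a0 = kin.platform_displacement(base)
    d1, a1 = kin.platform_displacement(rotated)
    assert d1 == pytest.approx(d0, rel=1e-9)
    e0 = kin.elevation(base, a0)
    e1 = kin.elevation(rotated, a1)
    assert (e1 - e0 + 180) % 360 - 180 == pytest.approx(0.0, abs=1e-6)


def test_extract_jump_variables_consistency(control_morph):
    rec = make_recording(
        (0.0, 0.0), (0.0102, 0.0102),
        tarsus=((0.30, 0.0), (0.30, -0.010)),
        platform_id="A", line_index=4,
    )
    jv = kin.extract_jump_variables(rec, control_morph, k_p=15.6, platform_mass=6.34e-3)
    assert jv.kinetic_energy == pytest.approx(
        0.5 * control_morph.body_mass * jv.velocity**2
    )
    assert jv.power == pytest.approx(jv.kinetic_energy / jv.time_to_takeoff)
    assert jv.stiffness_ratio == pytest.approx(jv.k_g / 15.6)
    assert jv.mass_ratio == pytest.approx(1.13 / 6.34, rel=1e-3)
    assert 0 < jv.acceleration_distance <= control_morph.femur_length + control_morph.tibia_length
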