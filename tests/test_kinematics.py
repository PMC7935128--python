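"""Law-of-cosines angles, cycle normalization, ensemble statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mousegait.errors import GeometryError, SegmentationError
from mousegait.events import GaitCycle
from mousegait.kinematics import (
    GRID,
    JOINTS,
    JointAngleSeries,
    NormalizedCurve,
    compute_angle_series,
    joint_angle,
    mean_sd_curve,
    normalize_cycle,
    smooth_series,
)


def _vector_angle_oracle(p, v, d):
    """Independent dot-product / atan2 route."""
    u, w = np.asarray(p) - v, np.asarray(d) - v
    return np.degrees(np.arctan2(abs(u[0] * w[1] - u[1] * w[0]), u @ w))


@pytest.mark.parametrize(
    "p,v,d,expected",
    [
        ((0, 0), (1, 0), (2, 0), 180.0),  # collinear
        ((0, 4), (0, 0), (3, 0), 90.0),  # 3-4-5 right angle
        ((1, 0), (0, 0), (0.5, 0.8660254037844386), 60.0),  # equilateral
        ((2, 0), (0, 0), (5, 0), 0.0),  # folded back on itself
    ],
)
def test_joint_angle_exact_constructions(p, v, d, expected):
    assert joint_angle(p, v, d) == pytest.approx(expected, abs=1e-9)


def test_joint_angle_matches_vector_oracle_on_random_triangles():
    rng = np.random.default_rng(42)
    pts = rng.uniform(-100, 100, size=(1000, 3, 2))
    worst = max(
        abs(joint_angle(p, v, d) - _vector_angle_oracle(p, v, d))
        for p, v, d in pts
    )
    assert worst < 1e-9


def test_joint_angle_rigid_motion_invariance_and_symmetry():
    rng = np.random.default_rng(7)
    for _ in range(200):
        p, v, d = rng.uniform(-50, 50, size=(3, 2))
        base = joint_angle(p, v, d)
        assert joint_angle(d, v, p) == pytest.approx(base, abs=1e-9)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = rng.uniform(-1000, 1000, size=2)
        moved = [rot @ q + shift for q in (p, v, d)]
        assert joint_angle(*moved) == pytest.approx(base, abs=1e-9)


def test_joint_angle_degenerate_segment_names_frame():
    with pytest.raises(GeometryError, match="frame 0"):
        joint_angle((0.0, 0.0), (0.0, 0.0), (1.0, 0.0))


def test_angle_series_matches_generator_truth(control_trial_truth):
    trial, truth = control_trial_truth
    series = compute_angle_series(trial)
    for joint in JOINTS:
        err = np.max(np.abs(series[joint].angle - truth.angles[joint]))
        assert err < 1e-6, joint


def test_missing_marker_propagates_to_its_joints_only(coarse_trial_truth):
    trial, _ = coarse_trial_truth
    trial = trial.copy()
    # knee marker feeds all three triplets; iliac crest only the hip's
    trial.sagittal_markers["knee"][10] = np.nan
    trial.sagittal_markers["iliac_crest"][20] = np.nan
    series = compute_angle_series(trial)
    for joint in JOINTS:  # knee is a marker of every triplet
        assert np.isnan(series[joint].angle[10])
    assert np.isnan(series["hip"].angle[20])
    assert np.isfinite(series["knee"].angle[20])
    assert np.isfinite(series["ankle"].angle[20])
    assert np.isfinite(series["hip"].angle[9])


def test_one_frame_trial_gives_one_sample_series(coarse_trial_truth):
    trial, _ = coarse_trial_truth
    trial = trial.copy()
    for group in ("sagittal_markers", "transverse_paws"):
        d = getattr(trial, group)
        for k in d:
            d[k] = d[k][:1]
    series = compute_angle_series(trial)
    assert all(len(series[j]) == 1 for j in JOINTS)


def _series(values, fr=100.0):
    return JointAngleSeries(joint="ankle", angle=np.asarray(values, float),
                            frame_rate=fr)


def _cycle(start, toe, end):
    return GaitCycle(start_frame=start, toe_off_frame=toe, end_frame=end)


def test_normalize_constant_trace():
    curve = normalize_cycle(_series(np.full(30, 90.0)), _cycle(0, 15, 29))
    assert np.allclose(curve.angle, 90.0)


def test_normalize_linear_ramp_midpoint():
    curve = normalize_cycle(_series(np.linspace(10, 20, 21)), _cycle(0, 10, 20))
    assert curve.angle[50] == pytest.approx(15.0, abs=1e-12)
    assert curve.angle[0] == pytest.approx(10.0)
    assert curve.angle[100] == pytest.approx(20.0)


def test_normalize_sampled_sinusoid_close_to_analytic():
    frames = np.arange(26)
    values = 100 + 15 * np.sin(2 * np.pi * frames / 25)
    curve = normalize_cycle(_series(values), _cycle(0, 15, 25))
    analytic = 100 + 15 * np.sin(2 * np.pi * GRID / 100)
    assert np.max(np.abs(curve.angle - analytic)) < 0.5


def test_normalization_idempotent_on_grid_curve():
    rng = np.random.default_rng(3)
    values = rng.uniform(0, 180, 101)
    once = normalize_cycle(_series(values), _cycle(0, 50, 100))
    again = normalize_cycle(
        _series(once.angle), _cycle(0, 50, 100)
    )
    assert np.max(np.abs(again.angle - once.angle)) < 1e-9


def test_normalize_rejects_single_frame_cycle():
    with pytest.raises(SegmentationError):
        normalize_cycle(_series(np.zeros(10)), _cycle(3, 4, 3 + 0))


def _curve(values):
    return NormalizedCurve(joint="hip", percent=GRID.copy(),
                           angle=np.asarray(values, float))


def test_mean_sd_of_identical_curves_is_zero_sd():
    c = _curve(np.linspace(40, 80, 101))
    stats = mean_sd_curve([c, c])
    assert np.allclose(stats.mean, c.angle)
    assert np.allclose(stats.sd, 0.0)
    assert not stats.single_curve


def test_mean_sd_two_constant_curves():
    stats = mean_sd_curve([_curve(np.full(101, 10.0)), _curve(np.full(101, 20.0))])
    assert np.allclose(stats.mean, 15.0)
    assert np.allclose(stats.sd, 7.0710678, atol=1e-6)
    assert np.allclose(stats.sem, 5.0, atol=1e-6)


def test_single_curve_flagged_zero_sd():
    stats = mean_sd_curve([_curve(np.full(101, 42.0))])
    assert stats.single_curve
    assert np.allclose(stats.sd, 0.0)


def test_mixed_joints_rejected():
    a = _curve(np.full(101, 10.0))
    b = NormalizedCurve(joint="knee", percent=GRID.copy(), angle=np.full(101, 10.0))
    with pytest.raises(ValueError, match="joint"):
        mean_sd_curve([a, b])


def test_pointwise_sd_recovers_noise_scale(rng):
    truth = 100 + 20 * np.sin(2 * np.pi * GRID / 100)
    curves = [_curve(truth + rng.normal(0, 2.0, 101)) for _ in range(200)]
    stats = mean_sd_curve(curves)
    assert stats.sd.min() > 1.6
    assert stats.sd.max() < 2.4


def test_smoothing_preserves_constant_and_reduces_noise(rng):
    const = smooth_series(_series(np.full(50, 77.0)), 5)
    assert np.allclose(const.angle, 77.0)
    noisy = _series(90 + rng.normal(0, 2.0, 2000))
    smoothed = smooth_series(noisy, 5)
    assert np.std(smoothed.angle) < 0.6 * np.std(noisy.angle)
    with pytest.raises(ValueError, match="odd"):
        smooth_series(noisy, 4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    scale=st.floats(5, 175),
    theta=st.floats(0, 2 * np.pi),
    dx=st.floats(-500, 500),
)
def test_angle_scale_invariance_property(scale, theta, dx):
    """The interior angle depends only on shape, not size or pose."""
    p = np.array([np.cos(theta), np.sin(theta)])
    d = np.array([1.0, 0.0])
    v = np.zeros(2)
    base = joint_angle(p, v, d)
    scaled = joint_angle(p * scale + dx, v * scale + dx, d * scale + dx)
    assert scaled == pytest.approx(base, abs=1e-7)
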