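"""Unit and property tests for per-track migration metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perihalo.tracks import (
    CellTrack,
    GradientFrame,
    angle_histogram,
    filter_by_displacement,
    group_compare,
    track_metrics,
)


def make_track(points, track_id="t", dt=1.0):
    points = np.asarray(points, dtype=float)
    return CellTrack(track_id=track_id, times=np.arange(len(points)) * dt, positions=points)


# ---------------------------------------------------------------------------
# independent oracle, written directly from the formula text


def oracle_metrics(times, points, gdir):
    """Brute-force recomputation of every metric with plain Python."""
    n = len(points)
    track_length = sum(
        math.dist(points[i], points[i + 1]) for i in range(n - 1)
    )
    end = (points[-1][0] - points[0][0], points[-1][1] - points[0][1])
    displacement = math.hypot(*end)
    upgradient = end[0] * gdir[0] + end[1] * gdir[1]
    chemotactic_displacement = upgradient / track_length if track_length > 0 else math.nan
    speed = track_length / (times[-1] - times[0])
    if displacement > 0:
        big_theta = math.atan2(end[1], end[0]) - math.atan2(gdir[1], gdir[0])
        chemotactic_index = math.cos(big_theta)
    else:
        chemotactic_index = math.nan
    headings = []
    for i in range(n - 1):
        dx = points[i + 1][0] - points[i][0]
        dy = points[i + 1][1] - points[i][1]
        if dx != 0 or dy != 0:
            headings.append(math.degrees(math.atan2(dy, dx)))
    deltas = []
    for a, b in zip(headings, headings[1:]):
        d = abs(b - a) % 360.0
        deltas.append(360.0 - d if d > 180.0 else d)
    mean_angle_change = sum(deltas) / len(deltas) if deltas else math.nan
    return dict(
        track_length=track_length,
        displacement=displacement,
        upgradient_displacement=upgradient,
        chemotactic_displacement=chemotactic_displacement,
        speed=speed,
        chemotactic_index=chemotactic_index,
        mean_angle_change=mean_angle_change,
    )


# ---------------------------------------------------------------------------
# worked examples


def test_straight_upgradient(gradient_x):
    m = track_metrics(make_track([(0, 0), (10, 0), (20, 0)]), gradient_x)
    assert m.track_length == pytest.approx(20.0)
    assert m.displacement == pytest.approx(20.0)
    assert m.chemotactic_displacement == pytest.approx(1.0)
    assert m.chemotactic_index == pytest.approx(1.0)
    assert m.speed == pytest.approx(10.0)
    assert m.mean_angle_change == pytest.approx(0.0)


def test_orthogonal_track(gradient_x):
    m = track_metrics(make_track([(0, 0), (0, 10), (0, 20)]), gradient_x)
    assert m.chemotactic_displacement == pytest.approx(0.0)
    assert m.chemotactic_index == pytest.approx(0.0, abs=1e-12)


def test_l_shaped_track(gradient_x):
    m = track_metrics(make_track([(0, 0), (10, 0), (10, 10)]), gradient_x)
    assert m.track_length == pytest.approx(20.0)
    assert m.displacement == pytest.approx(14.1421, abs=1e-4)
    assert m.upgradient_displacement == pytest.approx(10.0)
    assert m.chemotactic_displacement == pytest.approx(0.5)
    assert m.chemotactic_index == pytest.approx(math.cos(math.radians(45)), abs=1e-5)
    assert m.mean_angle_change == pytest.approx(90.0)


def test_zero_length_track_reports_missing(gradient_x):
    m = track_metrics(make_track([(5, 5), (5, 5), (5, 5)]), gradient_x)
    assert math.isnan(m.chemotactic_displacement)
    assert math.isnan(m.chemotactic_index)
    assert m.track_length == 0.0


def test_single_step_angle_change_missing(gradient_x):
    m = track_metrics(make_track([(0, 0), (3, 4)]), gradient_x)
    assert math.isnan(m.mean_angle_change)
    assert m.displacement == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# validation


def test_track_requires_two_samples():
    with pytest.raises(ValueError, match="at least 2"):
        CellTrack("x", [0.0], [[0.0, 0.0]])


def test_track_rejects_non_increasing_times():
    with pytest.raises(ValueError, match="strictly increasing"):
        CellTrack("x", [0.0, 1.0, 1.0], [[0, 0], [1, 0], [2, 0]])


def test_gradient_must_be_unit():
    with pytest.raises(ValueError, match="unit vector"):
        GradientFrame(direction=np.array([1.0, 1.0]))


# ---------------------------------------------------------------------------
# displacement filter


def test_filter_boundary_inclusive(gradient_x):
    at = make_track([(0, 0), (24.1, 0)], "at")
    below = make_track([(0, 0), (24.0999, 0)], "below")
    kept = filter_by_displacement([at, below], 24.1)
    assert [t.track_id for t in kept] == ["at"]


def test_filter_empty_input():
    assert filter_by_displacement([], 24.1) == []


# ---------------------------------------------------------------------------
# angle histogram


def test_angle_histogram_all_upgradient(gradient_x):
    tracks = [make_track([(0, 0), (10, 0)], f"t{i}") for i in range(5)]
    centers, fractions = angle_histogram(tracks, gradient_x, 8)
    assert fractions[np.argmin(np.abs(centers))] == pytest.approx(1.0)


def test_angle_histogram_sums_to_one(gradient_x, rng):
    tracks = [
        make_track([(0, 0), tuple(rng.normal(size=2))], f"t{i}") for i in range(100)
    ]
    _, fractions = angle_histogram(tracks, gradient_x, 12)
    assert fractions.sum() == pytest.approx(1.0, abs=1e-12)


def test_angle_histogram_isotropic(gradient_x, rng):
    angles = rng.uniform(-math.pi, math.pi, 4000)
    tracks = [
        make_track([(0, 0), (math.cos(a), math.sin(a))], f"t{i}")
        for i, a in enumerate(angles)
    ]
    _, fractions = angle_histogram(tracks, gradient_x, 8)
    assert np.all(np.abs(fractions - 0.125) < 0.02)


def test_angle_histogram_empty_errors(gradient_x):
    with pytest.raises(ValueError):
        angle_histogram([], gradient_x, 8)


# ---------------------------------------------------------------------------
# group comparison


def _rows(values, metric="speed"):
    return [{metric: v} for v in values]


def test_group_compare_identical_groups():
    data = {"a": _rows([1.0, 2.0, 3.0]), "b": _rows([1.0, 2.0, 3.0])}
    (res,) = group_compare(data, reference="a", metrics=["speed"])
    assert res.fold_change == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_group_compare_shifted_groups(rng):
    a = rng.normal(0.0, 1.0, 100)
    b = rng.normal(1.0, 1.0, 100)  # 1 SD shift
    (res,) = group_compare(
        {"ref": _rows(a), "shift": _rows(b)}, reference="ref", metrics=["speed"]
    )
    assert res.p_value < 1e-3


def test_group_compare_small_group_errors():
    with pytest.raises(ValueError, match="tiny"):
        group_compare(
            {"ok": _rows([1.0, 2.0, 3.0]), "tiny": _rows([1.0])},
            reference="ok",
            metrics=["speed"],
        )


# ---------------------------------------------------------------------------
# properties


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None)
def test_cd_equals_ci_times_displacement_over_length(seed):
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(0, 5, (5, 2)), axis=0)
    gdir = rng.normal(size=2)
    gdir /= np.linalg.norm(gdir)
    m = track_metrics(make_track(pts), GradientFrame(direction=gdir))
    if m.track_length > 0 and m.displacement > 0:
        assert m.chemotactic_displacement == pytest.approx(
            m.chemotactic_index * m.displacement / m.track_length, abs=1e-12
        )


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None)
def test_rigid_motion_invariance(seed):
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(0, 5, (6, 2)), axis=0)
    gdir = rng.normal(size=2)
    gdir /= np.linalg.norm(gdir)
    theta = rng.uniform(0, 2 * math.pi)
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    shift = rng.normal(0, 100, 2)

    m0 = track_metrics(make_track(pts), GradientFrame(direction=gdir))
    m1 = track_metrics(
        make_track(pts @ rot.T + shift), GradientFrame(direction=rot @ gdir)
    )
    for attr in (
        "track_length",
        "displacement",
        "upgradient_displacement",
        "chemotactic_displacement",
        "speed",
        "chemotactic_index",
        "mean_angle_change",
    ):
        a, b = getattr(m0, attr), getattr(m1, attr)
        if math.isnan(a):
            assert math.isnan(b)
        else:
            assert a == pytest.approx(b, abs=1e-9)


@given(st.integers(0, 10_000))
@settings(max_examples=100, deadline=None)
def test_oracle_equivalence_random_tracks(seed):
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(0, 5, (5, 2)), axis=0)
    times = np.arange(5, dtype=float)
    gdir = rng.normal(size=2)
    gdir /= np.linalg.norm(gdir)
    m = track_metrics(
        CellTrack("o", times, pts), GradientFrame(direction=gdir)
    )
    expected = oracle_metrics(times, pts.tolist(), tuple(gdir))
    for key, value in expected.items():
        got = getattr(m, key)
        if math.isnan(value):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(value, abs=1e-9), key


def test_metric_invariants_hold(gradient_x, rng):
    for _ in range(50):
        pts = np.cumsum(rng.normal(0, 5, (8, 2)), axis=0)
        m = track_metrics(make_track(pts), gradient_x)
        assert m.track_length >= m.displacement >= abs(m.upgradient_displacement) - 1e-12
        assert -1.0 - 1e-12 <= m.chemotactic_displacement <= 1.0 + 1e-12
        assert -1.0 - 1e-12 <= m.chemotactic_index <= 1.0 + 1e-12
        assert m.speed >= 0
        assert 0.0 <= m.mean_angle_change <= 180.0
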