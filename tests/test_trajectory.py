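"""Tests for trajectory metrics: binning, exclusion, SNAC geometry."""

import numpy as np
import pytest
from shapely.geometry import box

from flyassay import (
    SnacSession,
    Trajectory,
    activity_index,
    distance_travelled,
    exclusion_filter,
    snac_metrics,
)
from flyassay.errors import (
    GeometryError,
    InsufficientDataError,
    MalformedTrajectoryError,
)
from flyassay.trajectory import epoch_metrics_table


def make_trajectory(points, dt=0.1):
    pts = np.asarray(points, dtype=float)
    return Trajectory(np.arange(len(pts)) * dt, pts[:, 0], pts[:, 1])


class TestTrajectoryValidation:
    def test_rejects_non_increasing_timestamps(self):
        with pytest.raises(MalformedTrajectoryError):
            Trajectory([0.0, 0.0, 0.1], [0, 1, 2], [0, 0, 0])

    def test_rejects_non_finite_coordinates(self):
        with pytest.raises(MalformedTrajectoryError):
            Trajectory([0.0, 0.1], [0, np.nan], [0, 0])

    def test_csv_round_trip(self, tmp_path):
        traj = make_trajectory([(0, 0), (1, 1), (2, 0)])
        traj.to_csv(tmp_path / "t.csv")
        back = Trajectory.from_csv(tmp_path / "t.csv")
        assert np.allclose(back.x, traj.x) and np.allclose(back.t, traj.t)


class TestActivityIndex:
    def test_stationary_is_zero(self):
        traj = make_trajectory([(5, 5)] * 30)
        assert activity_index(traj) == 0.0

    def test_constant_fast_motion_is_one(self):
        # 0.3 mm per 0.1 s step -> 1.5 mm per complete 0.5 s bin
        traj = make_trajectory([(0.3 * i % 18, 5) for i in range(40)])
        assert activity_index(traj) == 1.0

    def test_hand_counted_fixture(self):
        """10 complete bins, exactly 4 of them mobile -> 0.4."""
        xs = []
        x = 0.0
        for b in range(10):
            step = 0.4 if b in (0, 3, 5, 8) else 0.0  # 2.0 mm vs 0 mm per bin
            for _ in range(5):
                x += step
                xs.append(x)
        xs.append(x)  # one extra sample so bin 9's steps stay within span
        traj = make_trajectory([(v % 19, 3) for v in xs])
        assert activity_index(traj) == pytest.approx(0.4)

    def test_trailing_partial_bin_discarded(self):
        # 0.7 s at 10 Hz -> one complete 0.5 s bin only
        traj = make_trajectory([(0.5 * i, 2) for i in range(8)])
        assert activity_index(traj) == 1.0

    def test_too_short_trajectory_raises(self):
        with pytest.raises(InsufficientDataError):
            activity_index(make_trajectory([(0, 0), (1, 0)]))

    def test_net_displacement_mode_is_laxer_on_loops(self):
        # back-and-forth: large path length, zero net displacement
        pts = [(0.5 * (i % 2), 1) for i in range(11)]
        traj = make_trajectory(pts)
        assert activity_index(traj, mode="path") == 1.0
        assert activity_index(traj, mode="net") == 0.0

    def test_monotone_under_added_motion(self):
        base = [(0, 0)] * 20
        moved = [(0, 0)] * 10 + [(0.5 * i, 0) for i in range(10)]
        assert activity_index(make_trajectory(moved)) >= activity_index(make_trajectory(base))


class TestDistanceTravelled:
    def test_single_sample_is_zero(self):
        assert distance_travelled(make_trajectory([(1, 1)])) == 0.0

    def test_three_four_five(self):
        assert distance_travelled(make_trajectory([(0, 0), (3, 4)])) == pytest.approx(5.0)

    def test_adjacent_windows_are_additive(self):
        rng = np.random.default_rng(4)
        traj = make_trajectory(rng.uniform(0, 10, size=(50, 2)))
        w1 = distance_travelled(traj, (0.0, 2.0))
        w2 = distance_travelled(traj, (2.0, 4.9))
        total = distance_travelled(traj, (0.0, 4.9))
        assert w1 + w2 == pytest.approx(total)


class TestExclusionFilter:
    @pytest.mark.parametrize(
        "distance,ai,keep,reason_word",
        [
            (150.0, 0.5, False, "distance"),
            (250.0, 0.05, False, "activity"),
            (250.0, 0.5, True, None),
            (200.0, 0.10, True, None),      # boundary values are kept (strict <)
            (199.999, 0.5, False, "distance"),
        ],
    )
    def test_rules(self, distance, ai, keep, reason_word):
        decision = exclusion_filter(distance, ai)
        assert decision.keep is keep
        if reason_word:
            assert reason_word in decision.reason


def dogleg_session():
    """Piecewise-linear fixture with known alcove-crossing time.

    The fly walks a right-angle dog-leg whose total length is twice the
    straight-line distance to the alcove.
    """
    alcove = box(8.0, 19.0, 12.0, 22.0)
    # start at (10, 11): direct distance to the alcove edge (y=19) is 8 mm;
    # the dog-leg detour walks 4+4+4+4.5 = 16.5 mm before the entry sample
    t = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
    px = [10.0, 14.0, 14.0, 10.0, 10.0, 10.0]
    py = [11.0, 11.0, 15.0, 15.0, 19.5, 20.5]
    traj = Trajectory(np.array(t), np.array(px), np.array(py))
    session = SnacSession(
        trajectory=traj,
        epochs=[(0.0, 0.0, 6.0)],
        alcove=alcove,
        arena=box(0, 0, 20, 22),
        fly_id="fx",
    )
    return session


class TestSnacMetrics:
    def test_dogleg_path_efficiency(self):
        session = dogleg_session()
        metrics = snac_metrics(session, debounce=1)
        assert metrics.entries == 1
        # direct distance from (10,11) to the alcove edge (y=19) is 8 mm;
        # the walked path to the entry sample is 4+4+4+4.5 = 16.5 mm
        assert metrics.path_efficiency[0] == pytest.approx(8.0 / 16.5)
        assert metrics.time_to_feed[0] == pytest.approx(4.0)
        assert metrics.distance_travelled[0] == pytest.approx(16.5)

    def test_straight_run_efficiency_is_one(self):
        alcove = box(8.0, 19.0, 12.0, 22.0)
        # entry sample lies exactly on the alcove boundary, so the walked
        # path to entry equals the direct distance
        traj = Trajectory(
            np.arange(5, dtype=float), np.full(5, 10.0), np.array([11.0, 15.0, 19.0, 20.0, 20.5])
        )
        session = SnacSession(traj, [(0.0, 0.0, 5.0)], alcove, arena=box(0, 0, 20, 22))
        metrics = snac_metrics(session, debounce=1)
        assert metrics.path_efficiency[0] == pytest.approx(1.0)

    def test_no_entry_censored(self):
        alcove = box(8.0, 19.0, 12.0, 22.0)
        traj = Trajectory(np.arange(10, dtype=float), np.full(10, 2.0), np.full(10, 2.0))
        session = SnacSession(traj, [(0.0, 0.0, 5.0), (6.0, 6.0, 9.0)], alcove)
        metrics = snac_metrics(session)
        assert metrics.entries == 0
        assert metrics.task_performance == 0.0
        assert metrics.time_to_feed == []

    def test_task_performance_is_entry_fraction(self):
        session = dogleg_session()
        metrics = snac_metrics(session, debounce=1)
        assert metrics.task_performance == metrics.entries / metrics.n_epochs

    def test_degenerate_alcove_rejected(self):
        traj = Trajectory([0.0, 1.0], [1, 2], [1, 2])
        with pytest.raises(GeometryError):
            SnacSession(traj, [(0.0, 0.0, 1.0)], alcove=box(5, 5, 5, 5))

    def test_epoch_table_has_exclusion_columns(self):
        session = dogleg_session()
        table = epoch_metrics_table(session, debounce=1)
        assert set(table.columns) == {
            "fly_id", "epoch", "metric", "value", "kept", "exclusion_reason",
        }
        # 16.5 mm of travel is far below the 200 mm minimum -> epoch dropped
        assert not table["kept"].any()

    def test_session_json_round_trip(self, tmp_path):
        session = dogleg_session()
        session.trajectory.to_csv(tmp_path / "traj.csv")
        session.to_json(tmp_path / "session.json", "traj.csv")
        back = SnacSession.from_json(tmp_path / "session.json")
        assert back.epochs == session.epochs
        assert back.alcove.equals(session.alcove)
        assert np.allclose(back.trajectory.x, session.trajectory.x)
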