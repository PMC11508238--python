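"""Association, Kalman filtering, trajectory voting and tracking-to-count."""

import itertools

import numpy as np
import pytest

from icucount.fixtures import make_fixtures
from icucount.kalman import KalmanState, kalman_init, kalman_predict, kalman_update
from icucount.simulate import (
    NoiseConfig,
    SimulationConfig,
    simulate_detections,
    simulate_ground_truth,
    symmetric_confusion,
)
from icucount.tracking import (
    Tracker,
    TrackerConfig,
    Trajectory,
    TrajectoryEntry,
    appearance_affinity,
    count_by_tracking,
    match_bipartite,
    trajectory_category,
)
from icucount.types import BoundingBox, Category

from conftest import make_detection, make_frame, one_hot, unit_vector


def brute_force_best(sim: np.ndarray) -> float:
    """Exhaustive maximum-total-similarity one-to-one assignment value."""
    n, m = sim.shape
    k = min(n, m)
    best = -np.inf
    rows = range(n)
    for chosen in itertools.permutations(range(m), k):
        for rsub in itertools.combinations(rows, k):
            best = max(best, sum(sim[r, c] for r, c in zip(rsub, chosen)))
    return best


class TestAffinity:
    def test_identical_and_orthogonal(self, rng):
        v = unit_vector(rng)
        w = unit_vector(rng)
        w = w - (w @ v) * v
        w /= np.linalg.norm(w)
        traj = Trajectory(1, [], kalman_init(BoundingBox(0, 0, 1, 1)), appearance_summary=v)
        d_same = make_detection(appearance=v)
        d_orth = make_detection(appearance=w)
        M = appearance_affinity([traj], [d_same, d_orth])
        assert M[0, 0] == pytest.approx(1.0)
        assert M[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_dot_products(self, rng):
        trajs = [
            Trajectory(i, [], kalman_init(BoundingBox(0, 0, 1, 1)),
                       appearance_summary=unit_vector(rng))
            for i in range(2)
        ]
        dets = [make_detection(appearance=unit_vector(rng)) for _ in range(3)]
        M = appearance_affinity(trajs, dets)
        for k in range(2):
            for j in range(3):
                assert M[k, j] == pytest.approx(
                    float(trajs[k].appearance_summary @ dets[j].appearance)
                )

    def test_zero_norm_rejected(self, rng):
        traj = Trajectory(1, [], kalman_init(BoundingBox(0, 0, 1, 1)),
                          appearance_summary=np.zeros(128))
        with pytest.raises(ValueError, match="zero-norm"):
            appearance_affinity([traj], [make_detection()])


class TestBipartiteMatching:
    def test_two_by_two(self):
        pairs, ur, uc = match_bipartite(np.array([[0.9, 0.1], [0.2, 0.8]]), 0.0)
        assert set(pairs) == {(0, 0), (1, 1)} and not ur and not uc

    def test_all_below_threshold(self):
        pairs, ur, uc = match_bipartite(np.array([[0.1, 0.2], [0.3, 0.1]]), 0.5)
        assert pairs == [] and ur == [0, 1] and uc == [0, 1]

    def test_rectangular(self):
        pairs, ur, uc = match_bipartite(np.array([[0.3, 0.7]]), 0.5)
        assert pairs == [(0, 1)] and ur == [] and uc == [0]

    def test_matches_exhaustive_search(self, rng):
        for _ in range(120):
            n, m = rng.integers(1, 7, size=2)
            sim = rng.uniform(-1, 1, size=(n, m))
            pairs, _, _ = match_bipartite(sim, -np.inf)
            total = sum(sim[r, c] for r, c in pairs)
            assert total == pytest.approx(brute_force_best(sim), abs=1e-9)


class TestKalman:
    def test_zero_velocity_zero_noise_mean_unchanged(self):
        s = kalman_init(BoundingBox(100, 100, 50, 100))
        s2 = kalman_predict(s, process_noise=np.zeros((8, 8)))
        np.testing.assert_allclose(s2.mean, s.mean)

    def test_constant_velocity_propagation(self):
        s = kalman_init(BoundingBox(100, 100, 50, 100))
        mean = s.mean.copy()
        mean[4] = 1.0  # cx velocity
        s = KalmanState(mean=mean, covariance=s.covariance)
        s2 = kalman_predict(s)
        assert s2.mean[0] == pytest.approx(101.0)

    def test_update_with_predicted_mean_is_noop(self):
        s = kalman_init(BoundingBox(100, 100, 50, 100))
        s2 = kalman_update(s, s.box)
        np.testing.assert_allclose(s2.mean, s.mean, atol=1e-9)

    def test_zero_measurement_noise_snaps_to_measurement(self):
        s = kalman_init(BoundingBox(100, 100, 50, 100))
        z = BoundingBox(130, 90, 40, 120)
        s2 = kalman_update(s, z, measurement_noise=np.zeros((4, 4)))
        np.testing.assert_allclose(s2.mean[:4], [130, 90, 40 / 120, 120], atol=1e-9)

    def test_scalar_gain_closed_form(self):
        # diagonal prior + diagonal noise decouples into 1-D updates with
        # gain K = P/(P+R)
        P = np.diag([4.0, 9.0, 0.01, 16.0, 1, 1, 1, 1])
        mean = np.array([10.0, 20.0, 0.5, 100.0, 0, 0, 0, 0])
        s = KalmanState(mean=mean, covariance=P)
        R = np.diag([1.0, 3.0, 0.01, 4.0])
        z = BoundingBox(cx=14, cy=26, w=0.6 * 110, h=110)
        s2 = kalman_update(s, z, measurement_noise=R)
        zv = np.array([14, 26, 0.6, 110.0])
        for k in range(4):
            gain = P[k, k] / (P[k, k] + R[k, k])
            assert s2.mean[k] == pytest.approx(mean[k] + gain * (zv[k] - mean[k]))
            assert s2.covariance[k, k] == pytest.approx((1 - gain) * P[k, k])

    def test_update_shrinks_covariance_trace(self):
        s = kalman_init(BoundingBox(100, 100, 50, 100))
        s = kalman_predict(s)
        s2 = kalman_update(s, BoundingBox(105, 102, 50, 100))
        assert np.trace(s2.covariance) <= np.trace(s.covariance)

    def test_converges_on_constant_velocity_track(self):
        # measurements are exact, so the filter is told so (tiny R); the
        # one-step prediction error tracks the velocity-estimate error
        s = kalman_init(BoundingBox(100, 300, 50, 100))
        R = np.diag([1e-6] * 4)
        err = None
        for i in range(1, 21):
            s = kalman_predict(s)
            true_cx = 100 + 5.0 * i
            err = abs(s.mean[0] - true_cx)
            s = kalman_update(s, BoundingBox(true_cx, 300, 50, 100), measurement_noise=R)
        assert err < 0.1

    def test_covariance_stays_symmetric_psd(self, rng):
        s = kalman_init(BoundingBox(500, 500, 120, 260))
        for _ in range(1000):
            s = kalman_predict(s)
            box = BoundingBox(
                500 + rng.normal(0, 5), 500 + rng.normal(0, 5),
                120 * np.exp(rng.normal(0, 0.05)), 260 * np.exp(rng.normal(0, 0.05)),
            )
            s = kalman_update(s, box)
            np.testing.assert_allclose(s.covariance, s.covariance.T, atol=1e-8)
            assert np.linalg.eigvalsh(s.covariance).min() > -1e-8


class TestTrajectoryVote:
    def _traj(self, probs_list):
        entries = [
            TrajectoryEntry(i, BoundingBox(0, 0, 1, 1), np.asarray(p, float), None)
            for i, p in enumerate(probs_list)
        ]
        return Trajectory(1, entries, kalman_init(BoundingBox(0, 0, 1, 1)),
                          appearance_summary=np.zeros(1))

    def test_unanimous(self):
        t = self._traj([one_hot(Category.CLINICIAN)] * 4)
        assert trajectory_category(t) is Category.CLINICIAN

    def test_soft_vote_hand_sum(self):
        t = self._traj([(0.6, 0.3, 0.1), (0.2, 0.5, 0.3), (0.3, 0.4, 0.3)])
        # column sums (1.1, 1.2, 0.7)
        assert trajectory_category(t) is Category.CLINICIAN

    def test_single_entry_reduces_to_argmax(self):
        t = self._traj([(0.2, 0.3, 0.5)])
        assert trajectory_category(t) is Category.VISITOR

    def test_tie_breaks_toward_lower_index(self):
        t = self._traj([(0.5, 0.5, 0.0)])
        assert trajectory_category(t) is Category.PATIENT

    def test_vote_beats_per_detection_argmax_under_confusion(self, rng):
        # symmetric 30% confusion, tracks of length 20: the trajectory-level
        # vote must be strictly more accurate than per-detection argmax
        cm = symmetric_confusion(0.3)
        n_traj, length = 250, 20
        det_correct = 0
        traj_correct = 0
        for _ in range(n_traj):
            true = int(rng.integers(0, 3))
            probs = []
            for _ in range(length):
                observed = int(rng.choice(3, p=cm[true]))
                p = cm[observed]
                det_correct += int(np.argmax(p) == true)
                probs.append(p)
            traj_correct += int(int(trajectory_category(self._traj(probs))) == true)
        assert traj_correct / n_traj > det_correct / (n_traj * length)


class TestTrackerScenarios:
    def test_cold_start_two_trajectories(self, rng):
        tracker = Tracker()
        frame = make_frame(0, [
            make_detection(cx=200, appearance=unit_vector(rng)),
            make_detection(cx=900, appearance=unit_vector(rng)),
        ])
        tracker.step(frame)
        assert len(tracker.active) == 2

    def test_out_of_order_frames_rejected(self):
        tracker = Tracker()
        tracker.step(make_frame(3, []))
        with pytest.raises(ValueError, match="out of order"):
            tracker.step(make_frame(3, []))

    def test_two_separated_actors_keep_identity(self, rng):
        appA, appB = unit_vector(rng), unit_vector(rng)
        tracker = Tracker()
        for i in range(10):
            tracker.step(make_frame(i, [
                make_detection(cx=200 + 10 * i, appearance=appA),
                make_detection(cx=1000 - 10 * i, cy=700, appearance=appB,
                               category=Category.VISITOR),
            ]))
        trajs = tracker.finalize()
        assert len(trajs) == 2
        assert sorted(t.length for t in trajs) == [10, 10]

    def test_gap_is_bridged_not_split(self):
        seq = make_fixtures(0)["occlusion_gap"]
        counts, trajs = count_by_tracking(seq, TrackerConfig(max_age=2))
        assert len(trajs) == 1
        assert trajs[0].active_frames() == list(range(12))
        assert (counts["clinician"] == 1).all()

    def test_track_terminates_after_max_age(self, rng):
        app = unit_vector(rng)
        tracker = Tracker(TrackerConfig(max_age=1))
        tracker.step(make_frame(0, [make_detection(appearance=app)]))
        tracker.step(make_frame(1, []))
        assert len(tracker.active) == 1  # one miss tolerated
        tracker.step(make_frame(2, []))
        assert len(tracker.active) == 0 and len(tracker.finished) == 1

    def test_every_admitted_detection_in_exactly_one_trajectory(self):
        cfg = SimulationConfig(duration_frames=150, n_clinician_visits=4,
                               n_visitor_visits=3, seed=19)
        gt = simulate_ground_truth(cfg)
        dets = simulate_detections(gt, NoiseConfig(), seed=23)
        tcfg = TrackerConfig()
        admitted = sum(
            sum(1 for d in f.detections if d.confidence >= tcfg.confidence_threshold)
            for f in dets
        )
        _, trajs = count_by_tracking(dets, tcfg)
        assert sum(t.length for t in trajs) == admitted


class TestCountByTracking:
    def test_patient_only_zero_noise(self):
        cfg = SimulationConfig(duration_frames=30, n_clinician_visits=0,
                               n_visitor_visits=0, seed=1)
        gt = simulate_ground_truth(cfg)
        dets = simulate_detections(gt, NoiseConfig.none(), seed=1)
        counts, trajs = count_by_tracking(dets)
        assert len(trajs) == 1
        assert (counts["patient"] == 1).all()
        assert (counts[["clinician", "visitor"]] == 0).all().all()

    def test_confused_frames_outvoted(self):
        seq = make_fixtures(0)["class_confusion"]
        counts, trajs = count_by_tracking(seq)
        assert len(trajs) == 1
        assert trajs[0].category() is Category.CLINICIAN
        assert (counts["clinician"] == 1).all()
        assert (counts["visitor"] == 0).all()

    def test_empty_sequence(self):
        counts, trajs = count_by_tracking([])
        assert len(counts) == 0 and trajs == []
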