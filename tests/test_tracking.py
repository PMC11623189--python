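"""Kalman/NSA filtering, EMA appearance, association costs, lifecycle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedtrack.tracking import (
    CostConfig,
    Detection,
    KalmanState,
    MotionModel,
    Track,
    Tracker,
    TrackingError,
    TrackStatus,
    appearance_cost,
    associate,
    combined_cost,
    ema_update,
    kf_predict,
    kf_update,
    motion_cost,
    nsa_update,
    predict,
)
from tests.conftest import unit


def make_detection(frame=0, box=(95.0, 75.0, 10.0, 50.0), confidence=0.8,
                   embedding=None, scores=(1.0, 0.0)):
    if embedding is None:
        embedding = unit([1.0, 0.0, 0.0])
    return Detection(frame=frame, box=box, confidence=confidence,
                     class_scores=np.array(scores), embedding=embedding)


def make_track(model=None, mean=None, embedding=None, alpha=0.9, n_classes=2):
    model = model or MotionModel()
    if mean is None:
        mean = np.array([100.0, 100.0, 0.2, 50.0, 0, 0, 0, 0])
    if embedding is None:
        embedding = unit([1.0, 0.0, 0.0])
    m, cov = model.initiate(mean[:4])
    m[:] = mean
    return Track(track_id=1, kalman=KalmanState(m, cov), appearance=embedding,
                 alpha=alpha, identity_votes=np.zeros(n_classes))


class TestKalmanPrimitives:
    def test_scalar_predict_and_update_by_hand(self):
        # hand-evaluated 1-state system: F=1, Q=0.5, H=1, R=1
        F = np.array([[1.0]]); Q = np.array([[0.5]]); H = np.array([[1.0]])
        mean, cov = kf_predict(np.array([2.0]), np.array([[1.0]]), F, Q)
        assert mean == pytest.approx([2.0])
        assert cov == pytest.approx(np.array([[1.5]]))
        mean, cov = kf_update(mean, cov, np.array([4.0]), H, np.array([[1.0]]))
        k = 1.5 / 2.5
        assert mean == pytest.approx([2.0 + k * 2.0])
        assert cov == pytest.approx(np.array([[(1 - k) * 1.5]]))

    def test_eight_dim_predict_matches_dense_arithmetic(self):
        model = MotionModel()
        rng = np.random.default_rng(0)
        mean = rng.normal(size=8)
        A = rng.normal(size=(8, 8))
        cov = A @ A.T + np.eye(8)
        m2, P2 = kf_predict(mean, cov, model.F, model.Q)
        assert m2 == pytest.approx(model.F @ mean)
        assert P2 == pytest.approx(model.F @ cov @ model.F.T + model.Q)

    def test_eight_dim_update_matches_dense_arithmetic(self):
        model = MotionModel()
        rng = np.random.default_rng(1)
        mean = rng.normal(size=8)
        A = rng.normal(size=(8, 8))
        cov = A @ A.T + np.eye(8)
        z = rng.normal(size=4)
        H, R = model.H, model.R
        m2, P2 = kf_update(mean, cov, z, H, R)
        S = H @ cov @ H.T + R
        K = cov @ H.T @ np.linalg.inv(S)
        assert m2 == pytest.approx(mean + K @ (z - H @ mean))
        assert P2 == pytest.approx((np.eye(8) - K @ H) @ cov, rel=1e-8, abs=1e-8)

    def test_non_finite_measurement_rejected(self):
        model = MotionModel()
        track = make_track(model)
        det = make_detection()
        object.__setattr__(det, "box", (np.nan, 0.0, 10.0, 10.0))
        with pytest.raises(TrackingError, match="invalid measurement"):
            nsa_update(track, det, model)


class TestPredict:
    def test_zero_velocity_zero_noise_leaves_mean_unchanged(self):
        model = MotionModel()
        model.Q = np.zeros((8, 8))
        track = make_track(model)
        before = track.kalman.mean.copy()
        predict(track, model)
        assert track.kalman.mean == pytest.approx(before)
        assert track.time_since_update == 1

    def test_constant_velocity_propagation(self):
        model = MotionModel()
        track = make_track(model, mean=np.array([100.0, 100.0, 1.0, 50.0, 2.0, -1.0, 0, 0]))
        predict(track, model)
        assert track.kalman.mean[:2] == pytest.approx([102.0, 99.0])

    def test_deleted_track_cannot_predict(self):
        track = make_track()
        track.status = TrackStatus.DELETED
        with pytest.raises(TrackingError):
            predict(track, MotionModel())


class TestNsaUpdate:
    def test_zero_confidence_is_vanilla_kalman(self):
        model = MotionModel()
        t1, t2 = make_track(model), make_track(model)
        det = make_detection(confidence=0.0)
        nsa_update(t1, det, model)
        m, P = kf_update(t2.kalman.mean, t2.kalman.covariance,
                         det.to_measurement(), model.H, model.R)
        assert t1.kalman.mean == pytest.approx(m)
        assert t1.kalman.covariance == pytest.approx(P)

    def test_full_confidence_pins_posterior_to_measurement(self):
        model = MotionModel()
        track = make_track(model)
        det = make_detection(confidence=1.0)
        nsa_update(track, det, model)
        # the eps floor keeps R~ nonsingular, so equality is to ~1e-6 relative
        assert track.kalman.mean[:4] == pytest.approx(det.to_measurement(), rel=1e-4)
        assert track.hits == 2 and track.time_since_update == 0

    def test_half_confidence_scalar_gain_two_thirds(self):
        # scalar toy per the NSA rule: P=1, R=1, c=0.5 -> R~=0.5, K=1/1.5
        m, P = kf_update(np.array([0.0]), np.array([[1.0]]), np.array([3.0]),
                         np.array([[1.0]]), np.array([[0.5]]))
        assert m == pytest.approx([3.0 * 2 / 3])

    @pytest.mark.parametrize("c_pair", [(0.0, 0.5), (0.5, 0.9), (0.9, 1.0)])
    def test_posterior_variance_non_increasing_in_confidence(self, c_pair):
        model = MotionModel()
        lo, hi = c_pair
        out = []
        for c in (lo, hi):
            track = make_track(model)
            nsa_update(track, make_detection(confidence=c), model)
            out.append(np.diag(track.kalman.covariance))
        assert np.all(out[1] <= out[0] + 1e-12)

    def test_covariance_stays_symmetric_psd_through_cycles(self):
        model = MotionModel()
        track = make_track(model)
        rng = np.random.default_rng(2)
        for k in range(50):
            predict(track, model)
            box = (95 + rng.normal(0, 3), 75 + rng.normal(0, 3), 10.0, 50.0)
            nsa_update(track, make_detection(box=box, confidence=float(rng.uniform())), model)
            P = track.kalman.covariance
            assert np.allclose(P, P.T, atol=1e-8)
            assert np.linalg.eigvalsh(P).min() >= -1e-9


class TestEmaUpdate:
    def test_constant_input_is_fixed_point(self):
        v = unit([0.3, 0.4, 0.5])
        track = make_track(embedding=v.copy())
        ema_update(track, make_detection(embedding=v.copy()))
        assert track.appearance == pytest.approx(v)

    def test_orthogonal_mix_is_renormalized_convex_combination(self):
        track = make_track(embedding=np.array([1.0, 0.0]))
        ema_update(track, make_detection(embedding=np.array([0.0, 1.0])))
        expected = np.array([0.9, 0.1]) / np.linalg.norm([0.9, 0.1])
        assert track.appearance == pytest.approx(expected)

    def test_zero_momentum_replaces_appearance(self):
        track = make_track(embedding=np.array([1.0, 0.0]), alpha=0.0)
        ema_update(track, make_detection(embedding=np.array([0.0, 1.0])))
        assert track.appearance == pytest.approx([0.0, 1.0])

    def test_geometric_convergence_at_rate_alpha(self):
        # with constant input the (renormalized) EMA closes its angle to
        # the input geometrically; the per-step contraction tends to alpha
        f = unit([0.0, 1.0, 0.0])
        track = make_track(embedding=unit([1.0, 0.0, 0.0]), alpha=0.9)
        e_ref = np.array([1.0, 0.0, 0.0])
        angles = []
        for _ in range(60):
            ema_update(track, make_detection(embedding=f.copy()))
            e_ref = 0.9 * e_ref + 0.1 * f
            e_ref /= np.linalg.norm(e_ref)
            assert track.appearance == pytest.approx(e_ref)
            angles.append(np.arccos(np.clip(track.appearance @ f, -1, 1)))
        ratios = np.array(angles[-10:]) / np.array(angles[-11:-1])
        assert ratios == pytest.approx(np.full(10, 0.9), rel=1e-3)

    def test_antipodal_cancellation_keeps_previous(self, caplog):
        track = make_track(embedding=np.array([1.0, 0.0]), alpha=0.5)
        with caplog.at_level("WARNING"):
            ema_update(track, make_detection(embedding=np.array([-1.0, 0.0])))
        assert track.appearance == pytest.approx([1.0, 0.0])
        assert any("zero-norm" in r.message for r in caplog.records)

    def test_dimension_mismatch_raises(self):
        track = make_track(embedding=np.array([1.0, 0.0]))
        with pytest.raises(TrackingError):
            ema_update(track, make_detection(embedding=unit([1, 1, 1])))


class TestCostMatrices:
    def test_appearance_cost_identical_orthogonal_antipodal(self):
        e = unit([1.0, 0.0])
        tracks = [make_track(embedding=e)]
        dets = [
            make_detection(embedding=np.array([1.0, 0.0])),
            make_detection(embedding=np.array([0.0, 1.0])),
            make_detection(embedding=np.array([-1.0, 0.0])),
        ]
        A = appearance_cost(tracks, dets)
        assert A[0] == pytest.approx([0.0, 1.0, 2.0])

    def test_motion_cost_zero_innovation(self):
        model = MotionModel()
        track = make_track(model)
        cx, cy, a, h = track.kalman.mean[:4]
        w = a * h
        det = make_detection(box=(cx - w / 2, cy - h / 2, w, h))
        A = motion_cost([track], [det], model, gate_threshold=1e9)
        assert A[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_motion_cost_is_squared_mahalanobis(self):
        # with P = 0 the innovation covariance is exactly R, so the cost
        # reduces to sum(innovation^2 / diag(R)) for a diagonal R
        model = MotionModel()
        track = make_track(model)
        track.kalman.covariance = np.zeros((8, 8))
        cx, cy, a, h = track.kalman.mean[:4]
        w = a * h
        det = make_detection(box=(cx - w / 2 + 2.0, cy - h / 2, w, h))
        A = motion_cost([track], [det], model, gate_threshold=1e9)
        assert A[0, 0] == pytest.approx(4.0 / model.R[0, 0])

    def test_gated_entries_are_infeasible(self):
        model = MotionModel()
        track = make_track(model)
        det = make_detection(box=(900.0, 900.0, 10.0, 50.0))
        A = motion_cost([track], [det], model, gate_threshold=9.4877)
        assert np.isinf(A[0, 0])

    def test_combined_cost_examples(self):
        cfg = CostConfig(lambda_weight=0.98)
        M = np.array([[0.3, 0.6]])
        assert combined_cost(M, M, cfg) == pytest.approx(M)
        C = combined_cost(np.array([[1.0]]), np.array([[0.0]]), cfg)
        assert C[0, 0] == pytest.approx(0.98)
        C = combined_cost(np.array([[0.4]]), np.array([[5.0]]),
                          CostConfig(lambda_weight=1.0))
        assert C[0, 0] == pytest.approx(0.4)

    def test_combined_cost_preserves_infeasibility_and_checks_shape(self):
        cfg = CostConfig()
        A_m = np.array([[np.inf, 1.0]])
        C = combined_cost(np.array([[0.1, 0.1]]), A_m, cfg)
        assert np.isinf(C[0, 0]) and np.isfinite(C[0, 1])
        with pytest.raises(TrackingError):
            combined_cost(np.zeros((2, 2)), np.zeros((2, 3)), cfg)


class TestAssociate:
    def test_zero_cost_diagonal(self):
        matches, ut, ud = associate(np.array([[0.0, 1.0], [1.0, 0.0]]), max_cost=10)
        assert set(matches) == {(0, 0), (1, 1)} and not ut and not ud

    def test_optimal_against_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            C = rng.uniform(0, 1, size=(n, n))
            matches, _, _ = associate(C, max_cost=np.inf)
            total = sum(C[i, j] for i, j in matches)
            brute = min(
                sum(C[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert total == pytest.approx(brute)

    def test_all_infeasible_yields_no_matches(self):
        C = np.full((2, 3), np.inf)
        matches, ut, ud = associate(C, max_cost=10)
        assert matches == [] and ut == [0, 1] and ud == [0, 1, 2]

    def test_matches_above_max_cost_demoted(self):
        matches, ut, ud = associate(np.array([[0.9]]), max_cost=0.7)
        assert matches == [] and ut == [0] and ud == [0]

    def test_empty_inputs(self):
        matches, ut, ud = associate(np.zeros((0, 0)), max_cost=1)
        assert matches == [] and ut == [] and ud == []


class TestTrackerLifecycle:
    def test_single_detection_matches_and_corrects_state(self):
        tracker = Tracker()
        d0 = make_detection(frame=0)
        tracker.step([d0])
        assert len(tracker.tracks) == 1
        d1 = make_detection(frame=1, box=(101.0, 81.0, 10.0, 50.0))
        tracker.step([d1])
        t = tracker.tracks[0]
        assert t.hits == 2
        # center moved from (100, 100) toward the measurement (106, 106)
        assert 100.0 < t.kalman.mean[0] <= 106.0

    def test_track_deleted_after_max_age_misses(self):
        tracker = Tracker(n_init=1, max_age=3)
        tracker.step([make_detection(frame=0)])
        assert tracker.tracks[0].status is TrackStatus.CONFIRMED
        tid = tracker.tracks[0].track_id
        for f in range(1, 6):
            tracker.step([])
        assert all(t.track_id != tid for t in tracker.tracks)

    def test_tentative_confirmed_after_n_init_consecutive_hits(self):
        tracker = Tracker(n_init=3)
        for f in range(3):
            tracker.step([make_detection(frame=f)])
        assert tracker.tracks[0].status is TrackStatus.CONFIRMED

    def test_mixed_frame_indices_rejected(self):
        tracker = Tracker()
        with pytest.raises(TrackingError):
            tracker.step([make_detection(frame=0), make_detection(frame=1)])

    def test_determinism_identical_runs(self):
        def run():
            rng = np.random.default_rng(11)
            tracker = Tracker()
            out = []
            for f in range(40):
                dets = [
                    make_detection(
                        frame=f,
                        box=(100 + 3 * f + rng.normal(0, 1), 80.0, 10.0, 50.0),
                        embedding=unit([1, 0, 0]),
                    ),
                    make_detection(
                        frame=f,
                        box=(400 - 3 * f + rng.normal(0, 1), 80.0, 10.0, 50.0),
                        embedding=unit([0, 1, 0]),
                        scores=(0.0, 1.0),
                    ),
                ]
                tracker.step(dets)
                out.append([(t.track_id, t.kalman.mean.copy()) for t in tracker.tracks])
            return out

        a, b = run(), run()
        for fa, fb in zip(a, b):
            for (ida, ma), (idb, mb) in zip(fa, fb):
                assert ida == idb
                assert np.array_equal(ma, mb)

    @pytest.mark.parametrize("seed", range(0, 200, 10))
    def test_crossing_tracks_keep_identity_with_separated_embeddings(self, seed):
        """Two targets crossing paths; cosine-separated embeddings disambiguate."""
        rng = np.random.default_rng(seed)
        e0, e1 = np.array([1.0, 0.0]), np.array([0.0, 1.0])  # distance 1.0 >= 0.8
        tracker = Tracker(n_init=2)
        id_of = {}
        for f in range(60):
            x0, x1 = 100.0 + 5 * f, 400.0 - 5 * f  # cross at f = 30
            dets = [
                make_detection(frame=f, box=(x0, 80 + rng.normal(0, 1), 10, 50),
                               embedding=unit(e0 + rng.normal(0, 0.01, 2)),
                               scores=(1.0, 0.0)),
                make_detection(frame=f, box=(x1, 80 + rng.normal(0, 1), 10, 50),
                               embedding=unit(e1 + rng.normal(0, 0.01, 2)),
                               scores=(0.0, 1.0)),
            ]
            tracker.step(dets)
            if f == 5:
                id_of = {t.identity: t.track_id for t in tracker.tracks}
        final = {t.identity: t.track_id for t in tracker.tracks
                 if t.status is TrackStatus.CONFIRMED}
        assert final == id_of  # same physical track carries each identity
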