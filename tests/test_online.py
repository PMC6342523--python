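"""Streaming pipeline: sufficient-statistic consistency, the shape-update
schedule, residual-buffer detection and fixed-point behavior."""

import numpy as np
import pytest

from caldemix.model import ComponentSet
from caldemix.movies import Movie
from caldemix.online import (
    OnlineParams,
    find_new_components,
    initialize_online,
    process_frame,
    run_online,
    shape_update_schedule,
    update_shapes,
)
from caldemix.synth import SynthParams, generate_movie


def make_state(movie, params):
    prefix = Movie(
        movie.data[:, : params.init_frames].copy(), movie.fov_dims, movie.frame_rate
    )
    return initialize_online(prefix, params, total_frames=movie.n_frames)


class TestSchedule:
    def test_every_component_updated_within_period(self):
        """1000 frames, T_u = 200, no additions: every component is
        updated at least 4 times and no inter-update gap exceeds T_u."""
        K, T_u, T = 7, 200, 1000
        A = np.eye(K)  # disjoint dummy footprints
        q = None
        updates = {i: [] for i in range(K)}
        for t in range(T):
            due, q = shape_update_schedule(q, A, [], T_u)
            for i in due:
                updates[i].append(t)
        for i in range(K):
            assert len(updates[i]) >= 4
            gaps = np.diff([0] + updates[i])
            assert gaps.max() <= T_u

    def test_insertion_frame_suppresses_updates(self):
        A = np.ones((4, 3))  # all-overlapping footprints
        q = np.array([0.5, 1.5, 0.5])  # two due
        due, q = shape_update_schedule(q, A, [2], 200)
        assert due.size == 0
        # overlapping neighbors of the insertion forced to update next frame
        assert q[0] == 0.0 and q[1] == 0.0
        due2, q = shape_update_schedule(q, A, [], 200)
        assert set(due2) >= {0, 1}

    def test_single_component_steady_state_period(self):
        A = np.ones((4, 1))
        T_u = 100
        q = None
        times = []
        for t in range(600):
            due, q = shape_update_schedule(q, A, [], T_u)
            if due.size:
                times.append(t)
        gaps = np.diff(times)
        # steady state: exactly one update per T_u-frame window
        assert np.all(gaps == T_u)


class TestStatistics:
    @pytest.fixture(scope="class")
    def movie(self):
        movie, truth = generate_movie(
            SynthParams(fov_dims=(24, 24), n_frames=260, n_neurons=3, seed=51)
        )
        return movie, truth

    def test_init_stat_identity(self, movie):
        m, _ = movie
        params = OnlineParams(init_frames=200, buffer_frames=100, seed=51)
        state = make_state(m, params)
        # reconstruct [C; f] from the recorded histories
        cf = np.concatenate(
            [state.trace_history[:, :200], state.bg_history[:, :200]], axis=0
        )
        np.testing.assert_allclose(state.stat_cc, cf @ cf.T / 200, atol=1e-8)
        np.testing.assert_allclose(
            state.stat_yc, m.data[:, :200] @ cf.T / 200, atol=1e-8
        )

    def test_stats_track_explicit_accumulation(self, movie):
        """After 50 streamed frames, stat_cc * t equals the explicitly
        accumulated [C; f][C; f]' to high precision."""
        m, _ = movie
        params = OnlineParams(
            init_frames=200, buffer_frames=100, candidates_per_frame=0, seed=51
        )
        state = make_state(m, params)
        acc_cc = state.stat_cc * state.t
        acc_yc = state.stat_yc * state.t
        for t in range(200, 250):
            state = process_frame(state, m.frame(t), params)
            cf = np.concatenate([state.trace_values, state.bg_values])
            acc_cc += np.outer(cf, cf)
            acc_yc += np.outer(m.frame(t).ravel(), cf)
        np.testing.assert_allclose(state.stat_cc * state.t, acc_cc, atol=1e-8)
        np.testing.assert_allclose(state.stat_yc * state.t, acc_yc, atol=1e-8)

    def test_zero_frame_leaves_traces_quiet(self, movie):
        m, _ = movie
        params = OnlineParams(
            init_frames=200, buffer_frames=100, candidates_per_frame=0, seed=51
        )
        state = make_state(m, params)
        K_before = state.n_components
        state = process_frame(state, np.zeros(m.fov_dims), params)
        assert state.n_components == K_before
        assert np.all(state.trace_values <= 1e-6)

    def test_nonfinite_frame_rejected(self, movie):
        m, _ = movie
        params = OnlineParams(init_frames=200, buffer_frames=100, seed=51)
        state = make_state(m, params)
        frame = np.full(m.fov_dims, np.nan)
        with pytest.raises(ValueError, match="finite"):
            process_frame(state, frame, params)


class TestUpdateShapes:
    def test_fixed_point_on_noiseless_truth(self):
        movie, truth = generate_movie(
            SynthParams(fov_dims=(24, 24), n_frames=200, n_neurons=2,
                        noise_sigma=0.0, background_rank=0, seed=53, spike_rate=2.0)
        )
        A = truth.footprints.copy()
        cf = truth.traces
        stat_yc = movie.data @ cf.T / movie.n_frames
        stat_cc = cf @ cf.T / movie.n_frames
        out = update_shapes(
            stat_yc, stat_cc, A.copy(), np.zeros((A.shape[0], 0)),
            np.array([0, 1]), movie.fov_dims,
        )
        np.testing.assert_allclose(out, A, atol=1e-8)

    def test_unlisted_indices_untouched(self):
        movie, truth = generate_movie(
            SynthParams(fov_dims=(24, 24), n_frames=200, n_neurons=2,
                        noise_sigma=0.5, background_rank=0, seed=54, spike_rate=2.0)
        )
        rng = np.random.default_rng(0)
        A = np.maximum(truth.footprints + 0.01 * rng.standard_normal(truth.footprints.shape), 0)
        cf = truth.traces
        stat_yc = movie.data @ cf.T / movie.n_frames
        stat_cc = cf @ cf.T / movie.n_frames
        before = A.copy()
        out = update_shapes(
            stat_yc, stat_cc, A, np.zeros((A.shape[0], 0)), np.array([1]), movie.fov_dims
        )
        np.testing.assert_array_equal(out[:, 0], before[:, 0])
        assert not np.array_equal(out[:, 1], before[:, 1])

    def test_perturbation_shrinks_toward_truth(self):
        movie, truth = generate_movie(
            SynthParams(fov_dims=(24, 24), n_frames=400, n_neurons=1,
                        noise_sigma=0.0, background_rank=0, seed=55, spike_rate=2.0)
        )
        rng = np.random.default_rng(1)
        a_true = truth.footprints[:, 0]
        noise = 0.05 * rng.random(a_true.size) * (a_true > 0)
        A = np.maximum(a_true + noise, 0)[:, None]
        cf = truth.traces
        stat_yc = movie.data @ cf.T / movie.n_frames
        stat_cc = cf @ cf.T / movie.n_frames
        out = update_shapes(
            stat_yc, stat_cc, A.copy(), np.zeros((A.shape[0], 0)),
            np.array([0]), movie.fov_dims,
        )
        assert np.linalg.norm(out[:, 0] - a_true) < np.linalg.norm(A[:, 0] - a_true)


class TestDetection:
    def test_planted_transient_detected(self, rng):
        fov = (24, 24)
        d, l_b = fov[0] * fov[1], 100
        buffer = rng.normal(0, 1.0, (d, l_b))
        rr, cc = np.mgrid[0 : fov[0], 0 : fov[1]]
        blob = np.exp(-((rr - 12) ** 2 + (cc - 12) ** 2) / (2 * 1.5**2)).ravel()
        blob /= np.linalg.norm(blob)
        trace = np.zeros(l_b)
        trace[40] = 10.0
        for t in range(41, l_b):
            trace[t] = 0.95 * trace[t - 1]
        buffer += np.outer(blob, trace)
        A_new, C_new = find_new_components(
            buffer, fov, n_candidates=5, neuron_radius=3, frame_rate=30,
            snr_threshold=1.2, classifier_threshold=0.6,
        )
        assert A_new.shape[1] == 1
        peak = np.unravel_index(A_new[:, 0].argmax(), fov)
        assert np.hypot(peak[0] - 12, peak[1] - 12) <= 3

    def test_zero_buffer_no_candidates(self):
        A_new, C_new = find_new_components(
            np.zeros((100, 50)), (10, 10), 5, 2, 30, 1.2, 0.6
        )
        assert A_new.shape[1] == 0

    def test_nearby_transients_yield_single_proposal(self, rng):
        """Two planted sources closer than 2r produce at most one
        proposal (the separation rule)."""
        fov = (20, 20)
        d, l_b = 400, 100
        buffer = rng.normal(0, 0.5, (d, l_b))
        rr, cc = np.mgrid[0:20, 0:20]
        for center in [(10, 10), (10, 13)]:  # 3 px apart, r = 3
            blob = np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * 1.5**2)).ravel()
            trace = np.maximum(rng.normal(0, 1, l_b), 0) * 8
            buffer += np.outer(blob / np.linalg.norm(blob), trace)
        A_new, _ = find_new_components(buffer, fov, 5, 3, 30, 1.2, 0.6)
        assert A_new.shape[1] <= 1


class TestRunOnline:
    def test_component_count_never_decreases_and_deterministic(self):
        movie, _ = generate_movie(
            SynthParams(fov_dims=(32, 32), n_frames=400, n_neurons=4, seed=57)
        )
        params = OnlineParams(seed=57, epochs=1)
        c1, b1, _ = run_online(movie, params)
        c2, b2, _ = run_online(movie, params)
        np.testing.assert_array_equal(c1.footprints, c2.footprints)
        np.testing.assert_array_equal(c1.traces, c2.traces)

    def test_batch_init_matches_run_batch_on_prefix(self):
        from caldemix.batch import BatchParams, run_batch

        movie, _ = generate_movie(
            SynthParams(fov_dims=(32, 32), n_frames=300, n_neurons=3, seed=58)
        )
        bp = BatchParams(patch_size=(32, 32), components_per_patch=5, seed=58)
        prefix = Movie(movie.data[:, :200].copy(), movie.fov_dims, movie.frame_rate)
        comps_ref, _, _ = run_batch(prefix, bp)
        params = OnlineParams(init_mode="batch", init_frames=200, buffer_frames=100, seed=58)
        state = initialize_online(prefix, params, batch_params=bp, total_frames=300)
        assert state.n_components == comps_ref.n_components
        np.testing.assert_allclose(state.footprints, comps_ref.footprints)

    def test_truth_initialized_tracks_noiseless_traces(self):
        movie, truth = generate_movie(
            SynthParams(fov_dims=(24, 24), n_frames=300, n_neurons=2,
                        noise_sigma=0.0, background_rank=0, seed=59, spike_rate=2.0)
        )
        params = OnlineParams(
            init_frames=200, buffer_frames=100, candidates_per_frame=0,
            background_rank=0, seed=59, trace_passes=3,
        )
        prefix = Movie(movie.data[:, :200].copy(), movie.fov_dims, movie.frame_rate)
        state = initialize_online(prefix, params, total_frames=300)
        # overwrite with exact truth to probe the per-frame update
        state.footprints = truth.footprints.copy()
        state.trace_values = truth.traces[:, 199].copy()
        state.groups = [np.array([0]), np.array([1])]
        state.update_counter = np.full(2, 10.0)  # no shape updates
        for t in range(200, 300):
            state = process_frame(state, movie.frame(t), params)
            np.testing.assert_allclose(state.trace_values, truth.traces[:, t], atol=1e-6)
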