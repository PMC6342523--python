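"""Batch pipeline pieces: patch tiling, seam merging, background
combination, HALS monotonicity and the ring background."""

import numpy as np
import pytest

from caldemix.batch import (
    BatchParams,
    construct_patches,
    hals_refine,
    merge_backgrounds,
    merge_components,
    process_in_patches,
    ring_background,
    run_batch,
)
from caldemix.initialization import InitParams
from caldemix.model import BackgroundModel, ComponentSet
from caldemix.movies import Movie, write_memmap
from caldemix.quality import QualityThresholds
from caldemix.synth import SynthParams, generate_movie
from caldemix._nmf import rank1_nmf


class TestConstructPatches:
    def test_single_patch_covers_fov(self):
        layout = construct_patches((64, 64), (64, 64), 8)
        assert layout.n_patches == 1
        assert (layout.coverage == 1).all()

    def test_40_8_tiling_arithmetic(self):
        """64 px axis, 40 px patches, 8 px overlap: stride 32 gives starts
        {0, 32}, the second patch clamped at the border, with the interior
        seam pixels covered twice."""
        layout = construct_patches((64, 64), (40, 40), 8)
        row_ranges = sorted({p[0] for p in layout.patches})
        assert row_ranges == [(0, 40), (32, 64)]
        assert layout.n_patches == 4
        assert (layout.coverage[:32, :32] == 1).all()
        assert (layout.coverage[32:40, 32:40] == 4).all()
        assert layout.coverage.min() == 1

    def test_overlap_equal_to_patch_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            construct_patches((64, 64), (40, 40), 40)


class TestMergeComponents:
    def test_exact_rank1_duplicate_pair(self, rng):
        a = np.zeros(100)
        a[30:40] = rng.random(10)
        c = np.abs(rng.standard_normal(80))
        comps = ComponentSet(np.stack([a, a], axis=1) * 0.5, np.stack([c, c], axis=0))
        merged = merge_components(comps, merge_threshold=0.8)
        assert merged.n_components == 1
        residual = np.linalg.norm(
            comps.reconstruct() - merged.reconstruct()
        ) / np.linalg.norm(comps.reconstruct())
        assert residual < 1e-6

    def test_uncorrelated_overlapping_pair_untouched(self, rng):
        a = np.zeros(100)
        a[30:40] = 1.0
        c1 = np.zeros(200)
        c1[::20] = 1.0
        c2 = np.zeros(200)
        c2[10::20] = 1.0
        comps = ComponentSet(np.stack([a, a], axis=1), np.stack([c1, c2], axis=0))
        merged = merge_components(comps, merge_threshold=0.8)
        assert merged.n_components == 2

    def test_chain_merge_matches_multistart_oracle(self, rng):
        """Overlap chain i-j, j-k collapses to one component whose rank-1
        fit is as good as a multi-start brute-force fit (within 1%)."""
        d, T = 120, 90
        base = np.zeros(d)
        base[40:52] = rng.random(12)
        shifts = [0, 6, 12]
        c = np.abs(rng.standard_normal(T)) + 0.2
        A = np.stack([np.roll(base, s) for s in shifts], axis=1)
        C = np.stack([c * (1 + 0.01 * rng.standard_normal(T)) for _ in shifts], axis=0)
        comps = ComponentSet(A, C)
        merged = merge_components(comps, merge_threshold=0.8)
        assert merged.n_components == 1
        prod = A @ C
        res_merged = np.linalg.norm(prod - merged.reconstruct())
        best = np.inf
        for k in range(8):  # multi-start rank-1 oracle
            rng_k = np.random.default_rng(k)
            a0, c0 = rank1_nmf(prod, n_iter=200, tol=0.0, init_c=np.abs(rng_k.standard_normal(T)))
            best = min(best, np.linalg.norm(prod - np.outer(a0, c0)))
        assert res_merged <= best * 1.01

    def test_never_increases_count(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            A = np.maximum(r.standard_normal((60, 6)), 0)
            C = np.abs(r.standard_normal((6, 40)))
            merged = merge_components(ComponentSet(A, C), merge_threshold=0.6)
            assert merged.n_components <= 6


class TestMergeBackgrounds:
    def test_single_patch_preserves_reconstruction(self, rng):
        b = np.abs(rng.standard_normal((64, 2)))
        f = np.abs(rng.standard_normal((2, 50)))
        bg = merge_backgrounds([(b, f, ((0, 8), (0, 8)))], (8, 8), 50, g_b=2, final_rank=2)
        np.testing.assert_allclose(bg.matrix(), b @ f, atol=1e-6 * np.abs(b @ f).max())

    def test_disjoint_rank1_patches_exact(self, rng):
        b1 = np.abs(rng.standard_normal((32, 1)))
        f1 = np.abs(rng.standard_normal((1, 40)))
        b2 = np.abs(rng.standard_normal((32, 1)))
        f2 = np.abs(rng.standard_normal((1, 40)))
        bg = merge_backgrounds(
            [(b1, f1, ((0, 4), (0, 8))), (b2, f2, ((4, 8), (0, 8)))],
            (8, 8), 40, g_b=1, final_rank=2,
        )
        B = bg.matrix()
        np.testing.assert_allclose(B[:32], b1 @ f1, atol=1e-6)
        np.testing.assert_allclose(B[32:], b2 @ f2, atol=1e-6)

    def test_zero_backgrounds_give_zero_model(self):
        bg = merge_backgrounds(
            [(np.zeros((16, 1)), np.zeros((1, 10)), ((0, 4), (0, 4)))], (4, 4), 10
        )
        assert bg.rank == 0 or not bg.matrix().any()


class TestHalsRefine:
    def test_fixed_point_at_noiseless_truth(self, noiseless_movie):
        movie, truth = noiseless_movie
        comps = ComponentSet(truth.footprints.copy(), truth.traces.copy())
        bg = BackgroundModel.empty(movie.n_pixels, movie.n_frames)
        out, _ = hals_refine(movie, comps, bg, iterations=3)
        assert np.linalg.norm(movie.data - out.reconstruct()) < 1e-6
        np.testing.assert_allclose(out.footprints, truth.footprints, atol=1e-6)

    def test_perturbed_truth_strictly_improves(self, noiseless_movie, rng):
        movie, truth = noiseless_movie
        A = truth.footprints * rng.uniform(0.8, 1.2, truth.footprints.shape[1])[None, :]
        C = truth.traces * 1.3
        comps = ComponentSet(A, C)
        bg = BackgroundModel.empty(movie.n_pixels, movie.n_frames)
        before = np.linalg.norm(movie.data - comps.reconstruct(), "fro")
        out, _ = hals_refine(movie, comps, bg, iterations=1)
        after = np.linalg.norm(movie.data - out.reconstruct(), "fro")
        assert after < before

    def test_zero_iterations_identity(self, small_movie):
        movie, truth = small_movie
        comps = ComponentSet(truth.footprints, truth.traces)
        bg = BackgroundModel(
            kind="low_rank", spatial=truth.background_spatial, temporal=truth.background_temporal
        )
        out_c, out_b = hals_refine(movie, comps, bg, iterations=0)
        assert out_c is comps and out_b is bg

    def test_objective_monotone_on_random_movies(self):
        """The Frobenius objective may never increase across iterations —
        hals_refine itself asserts this internally; drive it on a spread
        of random small movies."""
        for seed in range(8):
            movie, truth = generate_movie(
                SynthParams(fov_dims=(16, 16), n_frames=120, n_neurons=3,
                            gaussian_radius=2.0, seed=seed)
            )
            rng = np.random.default_rng(seed)
            A = np.maximum(truth.footprints + 0.01 * rng.standard_normal(truth.footprints.shape), 0)
            C = np.maximum(truth.traces + 0.1 * rng.standard_normal(truth.traces.shape), 0)
            comps = ComponentSet(A, C)
            bg = BackgroundModel(
                kind="low_rank",
                spatial=np.abs(rng.standard_normal((movie.n_pixels, 2))),
                temporal=np.abs(rng.standard_normal((2, movie.n_frames))),
            )
            hals_refine(movie, comps, bg, iterations=20)  # raises on divergence


class TestRingBackground:
    def test_zero_movie_zero_background(self):
        movie = Movie(np.zeros((100, 20)), (10, 10), 10.0)
        comps = ComponentSet.empty(100, 20)
        bg = ring_background(movie, comps, ring_radius=3)
        assert not bg.matrix(movie.data, comps).any()

    def test_smooth_field_reconstructed(self, rng):
        """A spatially smooth, temporally varying field is well explained
        by its own annulus pixels."""
        from scipy import ndimage as ndi

        rows = cols = 16
        T = 60
        surf = ndi.gaussian_filter(rng.standard_normal((rows, cols)), 4)
        surf = surf - surf.min() + 0.5
        tcourse = 1.0 + 0.3 * np.sin(np.arange(T) / 5)
        data = np.outer(surf.ravel(), tcourse)
        movie = Movie(data, (rows, cols), 10.0)
        comps = ComponentSet.empty(rows * cols, T)
        bg = ring_background(movie, comps, ring_radius=3)
        B = bg.matrix(movie.data, comps)
        rel = np.linalg.norm(data - B) / np.linalg.norm(data)
        assert rel < 0.1

    def test_tiny_fov_annulus_empty(self):
        movie = Movie(np.ones((4, 10)), (2, 2), 10.0)
        comps = ComponentSet.empty(4, 10)
        with pytest.raises(ValueError, match="annulus"):
            ring_background(movie, comps, ring_radius=50, ring_width=0.1)

    def test_1p_style_movie_trace_recovery(self):
        """Neurons over a large smooth background: one ring round recovers
        the true traces."""
        movie, truth = generate_movie(
            SynthParams(fov_dims=(32, 32), n_frames=300, n_neurons=3, seed=31,
                        background_rank=1, noise_sigma=0.5)
        )
        comps = ComponentSet(truth.footprints.copy(), truth.traces.copy())
        bg = ring_background(movie, comps, ring_radius=6)
        B = bg.matrix(movie.data, comps)
        # refit traces against the ring background
        from caldemix._nmf import hals_traces

        C = hals_traces(movie.data - B, comps.footprints, comps.traces.copy(), n_passes=3)
        for i in range(3):
            assert np.corrcoef(C[i], truth.traces[i])[0, 1] >= 0.9


class TestProcessInPatches:
    def test_seam_neuron_merged_once(self):
        """A neuron straddling the patch seam appears in both patches and
        must come out as exactly one component."""
        movie, truth = generate_movie(
            SynthParams(fov_dims=(32, 32), n_frames=300, n_neurons=1, seed=33,
                        background_rank=0)
        )
        # recenter check: find a layout whose seam crosses the neuron
        mm = write_memmap_movie(movie)
        layout = construct_patches((32, 32), (20, 20), 8)
        params = BatchParams(
            patch_size=(20, 20), overlap=8, components_per_patch=2,
            background_rank=0, seed=33,
            init=InitParams(gaussian_width=3),
        )
        comps, _ = process_in_patches(mm, layout, params)
        assert comps.n_components >= 1
        from caldemix.postproc import match_components

        res = match_components(comps, truth.footprints, match_threshold=0.7)
        assert res.recall == 1.0

    def test_order_invariance(self):
        movie, _ = generate_movie(
            SynthParams(fov_dims=(24, 24), n_frames=200, n_neurons=2, seed=35)
        )
        mm = write_memmap_movie(movie)
        layout = construct_patches((24, 24), (16, 16), 4)
        params = BatchParams(patch_size=(16, 16), overlap=4, components_per_patch=2, seed=35)
        c1, b1 = process_in_patches(mm, layout, params)
        shuffled = construct_patches((24, 24), (16, 16), 4)
        shuffled.patches = list(reversed(shuffled.patches))
        c2, b2 = process_in_patches(mm, shuffled, params)
        # same components recovered regardless of processing order
        assert c1.n_components == c2.n_components


def write_memmap_movie(movie):
    import tempfile

    tmp = tempfile.NamedTemporaryFile(suffix=".pmap", delete=False)
    tmp.close()
    return write_memmap(list(movie.frames()), tmp.name, frame_rate=movie.frame_rate)


class TestRunBatch:
    def test_reproducible_with_same_seed(self):
        movie, _ = generate_movie(
            SynthParams(fov_dims=(32, 32), n_frames=300, n_neurons=4, seed=41)
        )
        p = BatchParams(patch_size=(32, 32), components_per_patch=6, seed=41)
        c1, _, _ = run_batch(movie, p)
        c2, _, _ = run_batch(movie, p)
        np.testing.assert_array_equal(c1.footprints, c2.footprints)
        np.testing.assert_array_equal(c1.traces, c2.traces)

    def test_zero_neuron_movie_yields_nothing(self):
        """Background + noise only: the pipeline should come up empty."""
        empty = 0
        n_seeds = 5
        for seed in range(n_seeds):
            movie, _ = generate_movie(
                SynthParams(fov_dims=(32, 32), n_frames=300, n_neurons=0, seed=seed)
            )
            comps, _, _ = run_batch(
                movie,
                BatchParams(patch_size=(32, 32), components_per_patch=4, seed=seed),
            )
            empty += comps.n_components == 0
        assert empty == n_seeds

    def test_result_file_roundtrip(self, tmp_path):
        from caldemix.batch import load_result

        movie, _ = generate_movie(
            SynthParams(fov_dims=(32, 32), n_frames=300, n_neurons=3, seed=43)
        )
        out = tmp_path / "res.h5"
        comps, bg, report = run_batch(
            movie,
            BatchParams(patch_size=(32, 32), components_per_patch=5, seed=43),
            out_path=str(out),
        )
        comps2, bg2, report2 = load_result(str(out))
        np.testing.assert_allclose(comps2.footprints, comps.footprints)
        np.testing.assert_allclose(comps2.traces, comps.traces)
        np.testing.assert_array_equal(report2.accepted, report.accepted)
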