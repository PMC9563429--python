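"""Preprocessing chain: smoothing, cropping, normalisation, averaging,
and the rank-1 outer-product transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirmeat import preprocess as pp
from nirmeat import synth


def savgol_kernel_oracle(window, polyorder):
    """Centre-point weights from the per-window least-squares fit."""
    half = window // 2
    t = np.arange(-half, half + 1, dtype=float)
    A = np.vander(t, polyorder + 1, increasing=True)
    # fitted value at t=0 is the first row of (A^T A)^-1 A^T
    return np.linalg.solve(A.T @ A, A.T)[0]


class TestSavitzkyGolay:
    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(pp.sg_smooth(np.full(20, 3.5)), 3.5)

    def test_quadratic_reproduced_exactly(self):
        t = np.linspace(0, 1, 30)
        y = 2.0 - 3.0 * t + 0.5 * t ** 2
        np.testing.assert_allclose(pp.sg_smooth(y), y, atol=1e-12)

    def test_interior_kernel_matches_least_squares_oracle(self):
        # impulse response on an interior point reveals the kernel
        x = np.zeros(21)
        x[10] = 1.0
        smoothed = pp.sg_smooth(x)
        kernel = smoothed[8:13]
        np.testing.assert_allclose(kernel, savgol_kernel_oracle(5, 2),
                                   atol=1e-12)
        np.testing.assert_allclose(kernel,
                                   np.array([-3, 12, 17, 12, -3]) / 35,
                                   atol=1e-12)

    @pytest.mark.parametrize("window, polyorder", [(4, 2), (5, 5), (3, 4)])
    def test_invalid_window_configuration_rejected(self, window, polyorder):
        with pytest.raises(ValueError):
            pp.sg_smooth(np.arange(30.0), window, polyorder)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            pp.sg_smooth(np.arange(3.0), window=5)

    def test_noise_variance_never_amplified(self):
        t = np.linspace(0, 2 * np.pi, 200)
        signal = np.sin(t)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noisy = signal + rng.normal(0, 0.05, t.size)
            resid_before = np.var(noisy - signal)
            resid_after = np.var(pp.sg_smooth(noisy) - signal)
            assert resid_after <= resid_before


class TestCrop:
    def test_full_modelling_grid_retained(self, small_grid):
        wl, v = pp.crop(small_grid, np.ones_like(small_grid))
        assert wl.size == small_grid.size

    def test_single_channel_boundary(self):
        wl = np.array([1000.0, 1500.0, 2000.0])
        w, v = pp.crop(wl, wl * 0.0, lo=1500, hi=1500)
        assert w.tolist() == [1500.0]

    def test_bounds_respected_on_arbitrary_grid(self, rng):
        wl = np.sort(rng.uniform(900, 2500, 300))
        w, _ = pp.crop(wl, np.zeros_like(wl))
        assert w.min() >= 1038 and w.max() <= 2475

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="no channels"):
            pp.crop(np.array([500.0, 600.0]), np.zeros(2))


class TestMinMax:
    def test_affine_map(self):
        np.testing.assert_allclose(pp.minmax_normalize([0.2, 0.4, 0.6]),
                                   [0.0, 0.5, 1.0])

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pp.minmax_normalize(np.full(10, 0.3))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=64))
    def test_extrema_and_idempotence(self, values):
        v = np.asarray(values)
        if v.max() - v.min() <= 1e-9:
            return
        out = pp.minmax_normalize(v)
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_allclose(pp.minmax_normalize(out), out, atol=1e-12)


class TestAveraging:
    def test_direction_means_count(self, small_dataset):
        out = pp.mean_per_direction(small_dataset)
        assert len(out) == 39 * 4

    def test_identical_points_average_to_themselves(self, endmembers):
        design = synth.DatasetDesign(replicates_per_config=1,
                                     pure_classes=("mutton",),
                                     adulterants=(), proportions=(0.1,))
        df = synth.generate_dataset(design, endmembers,
                                    synth.NoiseParams(0, 0, 0, 0), seed=0)
        out = pp.mean_per_direction(df)
        assert len(out) == 4
        wl_cols = [c for c in out.columns if c not in pp.META_COLUMNS]
        vals = out[wl_cols].to_numpy()
        np.testing.assert_allclose(vals, np.broadcast_to(vals[0], vals.shape))

    def test_missing_point_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="expected 4 points"):
            pp.mean_per_direction(small_dataset.iloc[:-1])

    def test_four_direction_mean_equals_mean_of_all_points(self, small_dataset):
        per_dir = pp.mean_per_direction(small_dataset)
        four = pp.mean_of_directions(per_dir)
        assert len(four) == 39
        wl_cols = [c for c in four.columns if c not in pp.META_COLUMNS]
        sid = four["sample_id"].iloc[5]
        direct = small_dataset[small_dataset["sample_id"] == sid][wl_cols]
        np.testing.assert_allclose(
            four[four["sample_id"] == sid][wl_cols].to_numpy()[0],
            direct.to_numpy().mean(axis=0))

    def test_wrong_direction_count_rejected(self, small_dataset):
        per_dir = pp.mean_per_direction(small_dataset)
        with pytest.raises(ValueError, match="direction means"):
            pp.mean_of_directions(per_dir.iloc[:-1])


class TestOuterProduct:
    def test_two_channel_example(self):
        S = pp.to_matrix(np.array([1.0, 0.5]))
        np.testing.assert_allclose(S, [[1.0, 0.5], [0.5, 0.25]])

    def test_zero_vector(self):
        np.testing.assert_array_equal(pp.to_matrix(np.zeros(4)), np.zeros((4, 4)))

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            pp.to_matrix(np.array([0.5, 1.5]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_rank_and_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(rng.integers(2, 32))
        S = pp.to_matrix(x)
        np.testing.assert_array_equal(S, S.T)
        assert np.linalg.matrix_rank(S, tol=1e-10) <= 1
        np.testing.assert_allclose(np.diag(S), x ** 2)
        np.testing.assert_allclose(np.trace(S), (x ** 2).sum())
        assert S.min() >= 0.0 and S.max() <= 1.0


class TestPipeline:
    def test_spectrum_counts_conserved_through_schemes(self, small_dataset):
        per_dir = pp.preprocess_table(small_dataset, scheme="per-direction")
        four = pp.preprocess_table(small_dataset, scheme="four-direction")
        assert len(per_dir) == 4 * 39
        assert len(four) == 39

    def test_outputs_are_normalised(self, small_dataset):
        out = pp.preprocess_table(small_dataset, scheme="four-direction")
        wl_cols = [c for c in out.columns if c not in pp.META_COLUMNS]
        v = out[wl_cols].to_numpy()
        np.testing.assert_allclose(v.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(v.max(axis=1), 1.0, atol=1e-12)

    def test_unknown_scheme_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="scheme"):
            pp.preprocess_table(small_dataset, scheme="mean-of-everything")

    def test_matrices_match_spectra(self, small_dataset):
        out = pp.preprocess_table(small_dataset, scheme="four-direction")
        mats, meta = pp.matrices_from_table(out)
        assert mats.shape == (39, 64, 64)
        assert len(meta) == 39
        wl_cols = [c for c in out.columns if c not in pp.META_COLUMNS]
        x = out[wl_cols].to_numpy()[3]
        np.testing.assert_allclose(mats[3], np.outer(x, x))
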