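"""Spectrum normalization, ROI masking, and dataset construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsdpa import (PhantomSpec, amplitude_mask, average_frames, build_dataset,
                   cnr_mask, filter_min_size, normalize_spectrum,
                   sample_phantom, simulate_multispectral)
from lsdpa.errors import DataError, NormalizationError, NumericalError, \
    ValidationError
from lsdpa.spectra import SpectraDataset


class TestNormalize:
    def test_arithmetic_example(self):
        out = normalize_spectrum([1.0, 1.0, 2.0])
        np.testing.assert_allclose(out.values, [0.25, 0.25, 0.5])
        assert out.normalized

    def test_idempotent_on_normalized_input(self):
        s = normalize_spectrum([0.2, 0.5, 0.3])
        again = normalize_spectrum(s.values)
        np.testing.assert_allclose(again.values, s.values)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(1e-6, 1e6),
           seed=st.integers(0, 10_000))
    def test_scale_invariance_discards_amplitude(self, scale, seed):
        raw = np.random.default_rng(seed).random(9) + 1e-9
        a = normalize_spectrum(raw).values
        b = normalize_spectrum(scale * raw).values
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_spectrum(np.zeros(5))


class TestCnrMask:
    def test_single_bright_pixel_survives(self):
        """bg mean 1, bg std 1: only the pixel at 4 has CNR >= 2."""
        img = np.tile([0.0, 2.0], (8, 4))  # mean 1, std 1
        bg = np.ones((8, 8), dtype=bool)
        bg[4, 4] = False
        img[4, 4] = 4.0
        mask = cnr_mask(img, bg, threshold=2.0)
        assert mask[4, 4]
        assert mask.sum() == 1

    def test_zero_threshold_keeps_positive_contrast(self):
        img = np.ones((4, 4)) * 5
        bg = np.zeros((4, 4), dtype=bool)
        bg[:2] = True
        img[:2] = [[1, 3, 1, 3], [3, 1, 3, 1]]
        mask = cnr_mask(img, bg, threshold=0.0)
        assert mask[2:].all()

    def test_background_statistics_image_mostly_empty_at_2(self):
        """An image drawn from the background law itself keeps ~P(Z>=2)."""
        rng = np.random.default_rng(0)
        img = rng.normal(0.0, 1.0, (100, 100))
        mask = cnr_mask(img, np.ones_like(img, dtype=bool), threshold=2.0)
        assert mask.mean() < 0.05  # P(Z >= 2) ~ 0.023

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        img = rng.random((20, 20))
        bg = np.ones_like(img, dtype=bool)
        loose = cnr_mask(img, bg, 0.5)
        tight = cnr_mask(img, bg, 1.5)
        assert not np.any(tight & ~loose)

    def test_degenerate_background_rejected(self):
        with pytest.raises(NumericalError):
            cnr_mask(np.ones((4, 4)), np.ones((4, 4), dtype=bool))


class TestAmplitudeMask:
    def test_msot_style_threshold(self):
        img = np.array([[1e4, 3e4], [2e4, 5e4]])
        mask = amplitude_mask(img, 2e4)
        assert mask.sum() == 2
        assert mask[0, 1] and mask[1, 1]

    def test_threshold_at_max_empties_mask(self):
        img = np.arange(12.0).reshape(3, 4)
        assert not amplitude_mask(img, img.max()).any()

    def test_infinitely_low_threshold_keeps_all(self):
        img = np.zeros((3, 3))
        assert amplitude_mask(img, -np.inf).all()


class TestMinSize:
    def test_twenty_pixel_rule(self):
        """Components of 19 and 21 pixels: only the 21-pixel one remains."""
        mask = np.zeros((10, 40), dtype=bool)
        mask[2, 1:20] = True       # 19 pixels
        mask[5:8, 25:32] = True    # 21 pixels
        out = filter_min_size(mask, min_pixels=20)
        assert not out[2].any()
        assert out[5:8, 25:32].all()

    def test_min_one_is_identity(self):
        rng = np.random.default_rng(2)
        mask = rng.random((15, 15)) > 0.5
        np.testing.assert_array_equal(filter_min_size(mask, 1), mask)

    def test_empty_mask_stays_empty(self):
        assert not filter_min_size(np.zeros((5, 5), bool), 20).any()

    def test_diagonal_pixels_are_separate_components(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert not filter_min_size(mask, 2).any()  # 4-connectivity


class TestAverageFrames:
    def test_identical_frames_are_a_fixed_point(self):
        frame = np.arange(6.0).reshape(2, 3)
        frames = np.stack([frame] * 10)
        np.testing.assert_array_equal(average_frames(frames, 10), frame)

    def test_two_frame_mean(self):
        out = average_frames(np.array([[0.0], [2.0]]), k=2)
        assert out == pytest.approx(1.0)

    def test_noise_variance_shrinks_like_one_over_k(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(0, 1, (10, 2000))
        averaged = average_frames(frames, 10)
        assert averaged.var() == pytest.approx(1 / 10, rel=0.2)

    def test_too_few_frames_rejected(self):
        with pytest.raises(DataError):
            average_frames(np.zeros((3, 2, 2)), k=10)


@pytest.fixture(scope="module")
def flow_case(table):
    spec = PhantomSpec("flow", grid_shape=(96, 96), voxel_size_mm=0.1)
    vol = sample_phantom(spec, np.random.default_rng(5))
    wl = np.arange(700, 951, 50.0)
    stack = simulate_multispectral(vol, wl, table)
    ds = build_dataset([stack], [vol], rng=np.random.default_rng(6))
    return vol, ds


class TestBuildDataset:
    def test_labels_equal_the_tube_oxygenation(self, flow_case):
        vol, ds = flow_case
        assert len(ds) > 0
        np.testing.assert_allclose(ds.labels, vol.ground_truth_so2[1])

    def test_rows_sum_to_one(self, flow_case):
        _, ds = flow_case
        np.testing.assert_allclose(ds.spectra.sum(axis=1), 1.0, atol=1e-9)

    def test_metadata_consistency(self, flow_case):
        vol, ds = flow_case
        assert np.all(ds.tissue_label == 1)
        assert ds.depth_mm.min() > 0

    def test_extraction_deterministic_given_rng_seed(self, table):
        spec = PhantomSpec("flow", grid_shape=(64, 96))
        vol = sample_phantom(spec, np.random.default_rng(7))
        wl = np.array([700.0, 800.0, 900.0])
        stack = simulate_multispectral(vol, wl, table)
        d1 = build_dataset([stack], [vol], rng=np.random.default_rng(1))
        d2 = build_dataset([stack], [vol], rng=np.random.default_rng(1))
        assert np.array_equal(d1.spectra, d2.spectra)

    def test_dataset_invariants_enforced(self):
        with pytest.raises(ValidationError):
            SpectraDataset(np.array([[0.5, 0.6]]), np.array([0.5]),
                           np.array([700.0, 800.0]), np.array([0]),
                           np.array([1.0]), np.array([0]))
        with pytest.raises(ValidationError):
            SpectraDataset(np.array([[0.5, 0.5]]), np.array([1.5]),
                           np.array([700.0, 800.0]), np.array([0]),
                           np.array([1.0]), np.array([0]))

    def test_csv_round_trip_columns(self, flow_case, tmp_path):
        _, ds = flow_case
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert "so2" in df.columns and "depth_mm" in df.columns
        assert len(df) == len(ds)
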