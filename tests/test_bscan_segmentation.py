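import numpy as np
import pytest
from scipy import ndimage

from conftest import make_spec, true_rows_at
from relaxindex.bscan_segmentation import (
    LayerCandidates,
    RowEnvelope,
    detect_layer_candidates,
    detect_roi,
    enhance,
    fit_layers,
    reject_outliers,
    row_envelope,
    segment_bscan,
    smooth,
)
from relaxindex.composite_io import ImageGrid, split_composite
from relaxindex.config import SegmentationParams
from relaxindex.errors import (
    EmptyRoiError,
    ImageShapeError,
    LayerFitError,
    NormalizationError,
    ParameterError,
    RejectionSkippedWarning,
    SegmentationStageError,
)
from relaxindex.phantom import generate_series


def grid(arr):
    return ImageGrid(np.asarray(arr, dtype=float))


class TestSmooth:
    def test_constant_preserved(self):
        out = smooth(grid(np.full((30, 30), 3.0)))
        assert np.allclose(out.pixels, 3.0)

    def test_impulse_spreads_to_uniform_block(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        out = smooth(grid(img)).pixels
        assert np.allclose(out[13:18, 13:18], 1 / 25)
        assert np.allclose(out[:12], 0)

    def test_matches_nested_loop_oracle(self, rng):
        img = rng.uniform(0, 1, (20, 22))
        out = smooth(grid(img)).pixels
        padded = np.pad(img, 2, mode="symmetric")  # edge-repeating reflection
        oracle = np.empty_like(img)
        for r in range(20):
            for c in range(22):
                oracle[r, c] = padded[r:r + 5, c:c + 5].mean()
        assert np.allclose(out, oracle, atol=1e-12)

    def test_too_small_image_raises(self):
        # ImageGrid's own floor is 16 px, so shrink the kernel constraint instead
        with pytest.raises(ImageShapeError):
            smooth(grid(np.zeros((16, 16))), kernel=17)


class TestEnhance:
    def test_flat_input_unchanged(self):
        out = enhance(grid(np.full((30, 30), 0.4)))
        assert np.allclose(out.pixels, 0.4)

    def test_step_edge_overshoots(self):
        img = np.zeros((40, 40))
        img[:, 20:] = 1.0
        out = enhance(grid(img)).pixels
        assert out.max() > 1.0  # overshoot on the bright side

    def test_equals_composed_gaussian_highpass(self, rng):
        img = rng.uniform(0, 1, (30, 30))
        alpha, sigma = 1.5, 2.0
        out = enhance(grid(img), sigma=sigma, alpha=alpha).pixels
        low = ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")
        oracle = np.clip(img + alpha * (img - low), 0, None)
        assert np.allclose(out, oracle, atol=1e-12)

    @pytest.mark.parametrize("kwargs", [{"sigma": 0}, {"alpha": -1}])
    def test_bad_parameters_raise(self, kwargs):
        with pytest.raises(ParameterError):
            enhance(grid(np.zeros((30, 30))), **kwargs)


class TestRowEnvelope:
    def test_single_bright_row(self):
        img = np.zeros((40, 40))
        img[17] = 1.0
        env = row_envelope(grid(img), smooth_window=None)
        assert env.values[17] == 1.0
        assert np.all(env.values[np.arange(40) != 17] == 0.0)

    def test_two_bands_give_two_maxima(self):
        img = np.zeros((60, 40))
        img[15], img[45] = 1.0, 0.8
        env = row_envelope(grid(img), smooth_window=None).values
        peaks = [r for r in range(1, 59) if env[r] > env[r - 1] and env[r] >= env[r + 1]]
        assert peaks == [15, 45]

    def test_normalized_exactly_to_unit_range(self, rng):
        env = row_envelope(grid(rng.uniform(0, 1, (50, 50)))).values
        assert env.min() == 0.0 and env.max() == 1.0

    def test_constant_image_raises(self):
        with pytest.raises(NormalizationError):
            row_envelope(grid(np.full((30, 30), 0.5)))

    def test_phantom_envelope_peaks_near_band_centers(self, clean_series):
        panel = split_composite(clean_series.composites["T1"])
        enh = enhance(smooth(panel.bscan))
        env = row_envelope(enh).values
        truth = clean_series.truth
        for center in (truth.erm_rows.mean(), truth.rpe_rows.mean()):
            lo, hi = int(center) - 6, int(center) + 7
            assert env[lo:hi].max() > 0.5  # a strong local response near each band


class TestDetectRoi:
    def test_hand_thresholded_profile(self):
        env = RowEnvelope(np.array([0, 0.2, 0.5, 0.9, 0.6, 0.3, 0.45, 0.1]))
        roi = detect_roi(env, 0.4)
        assert (roi.row_top, roi.row_bottom) == (2, 6)

    def test_all_below_threshold_raises(self):
        with pytest.raises(EmptyRoiError):
            detect_roi(RowEnvelope(np.full(20, 0.39)), 0.4)

    def test_threshold_must_be_interior(self):
        with pytest.raises(ParameterError):
            detect_roi(RowEnvelope(np.linspace(0, 1, 10)), 1.2)

    def test_phantom_roi_contains_both_layers(self, clean_series):
        panel = split_composite(clean_series.composites["T1"])
        enh = enhance(smooth(panel.bscan))
        roi = detect_roi(row_envelope(enh))
        truth = clean_series.truth
        assert roi.row_top <= truth.erm_rows.min()
        assert roi.row_bottom >= truth.rpe_rows.max()


def _triangle(center, width, height, n):
    col = np.zeros(n)
    for i in range(n):
        col[i] = max(0.0, height * (1 - abs(i - center) / width))
    return col


class TestDetectCandidates:
    def test_two_triangular_peaks(self):
        img = np.zeros((200, 20))
        col = _triangle(40, 8, 1.0, 200) + _triangle(120, 8, 0.9, 200)
        img[:] = col[:, None]
        roi = detect_roi(RowEnvelope(col / col.max()), 0.3)
        cand = detect_layer_candidates(grid(img), roi)
        assert np.allclose(cand.erm_rows, 40)
        assert np.allclose(cand.rpe_rows, 120)

    def test_single_peak_yields_missing_by_default(self):
        img = np.zeros((200, 20))
        col = _triangle(80, 10, 1.0, 200)
        img[:] = col[:, None]
        roi = detect_roi(RowEnvelope(col / col.max()), 0.3)
        cand = detect_layer_candidates(grid(img), roi)
        assert np.all(np.isnan(cand.erm_rows))
        assert np.all(np.isnan(cand.rpe_rows))
        single = detect_layer_candidates(grid(img), roi, single_peak_is_rpe=True)
        assert np.allclose(single.rpe_rows, 80)

    def test_phantom_candidates_near_truth(self, clean_series):
        panel = split_composite(clean_series.composites["T1"])
        enh = enhance(smooth(panel.bscan))
        roi = detect_roi(row_envelope(enh))
        cand = detect_layer_candidates(enh, roi)
        truth = clean_series.truth
        ok = 0
        for c in range(panel.bscan.n_cols):
            if np.isfinite(cand.erm_rows[c]) and np.isfinite(cand.rpe_rows[c]):
                if (abs(cand.erm_rows[c] - truth.erm_rows[c]) <= 2
                        and abs(cand.rpe_rows[c] - truth.rpe_rows[c]) <= 2):
                    ok += 1
        assert ok >= 0.9 * panel.bscan.n_cols


def _candidates(columns, erm=None, rpe=None):
    n = columns.size
    nanarr = np.full(n, np.nan)
    return LayerCandidates(
        columns=columns,
        erm_rows=nanarr.copy() if erm is None else np.asarray(erm, float),
        rpe_rows=nanarr.copy() if rpe is None else np.asarray(rpe, float),
    )


class TestRejectOutliers:
    def test_single_gross_outlier_removed(self):
        cols = np.arange(51)
        rows = 100 + 0.5 * cols
        rows[25] += 30.0
        cand = _candidates(cols, erm=rows, rpe=rows + 60)
        out = reject_outliers(cand)
        assert out.erm_rejected.sum() == 1 and out.erm_rejected[25]
        assert out.rpe_rejected.sum() == 1

    def test_smooth_quadratic_untouched(self):
        cols = np.arange(60)
        rows = 150 - 0.2 * cols + 0.001 * cols ** 2
        out = reject_outliers(_candidates(cols, rpe=rows))
        assert out.rpe_rejected.sum() == 0

    def test_contaminated_columns_mostly_removed(self, rng):
        cols = np.arange(400)
        rows = 120 + 0.02 * cols
        bad = rng.choice(400, size=20, replace=False)  # 5% contamination
        noisy = rows.copy()
        noisy[bad] = rng.uniform(60, 260, size=20)  # uniform row noise in the ROI band
        big = np.abs(noisy - rows) > 10  # only grossly displaced ones count
        out = reject_outliers(_candidates(cols, erm=noisy))
        assert out.erm_rejected[big].mean() >= 0.8
        clean = np.ones(400, bool)
        clean[bad] = False
        assert out.erm_rejected[clean].mean() <= 0.02

    def test_too_few_candidates_warns_and_skips(self):
        cols = np.arange(5)
        with pytest.warns(RejectionSkippedWarning):
            out = reject_outliers(_candidates(cols, erm=np.array([1., 2., 3., 4., 50.])))
        assert out.erm_rejected.sum() == 0

    def test_bad_parameters_raise(self):
        cand = _candidates(np.arange(20), erm=np.zeros(20))
        with pytest.raises(ParameterError):
            reject_outliers(cand, window=4)
        with pytest.raises(ParameterError):
            reject_outliers(cand, k=0)


class TestFitLayers:
    def test_exact_quadratic_rpe_recovered(self):
        cols = np.arange(0, 400)
        rpe = 0.001 * cols ** 2 - 0.2 * cols + 150
        erm = rpe - 60
        erm_t, rpe_t = fit_layers(_candidates(cols, erm=erm, rpe=rpe))
        truth = 0.001 * rpe_t.columns ** 2 - 0.2 * rpe_t.columns + 150
        assert np.max(np.abs(rpe_t.rows - truth) / np.abs(truth)) < 1e-6
        assert len(rpe_t.rows) == 100

    def test_spline_reproduces_linear_erm(self):
        cols = np.arange(0, 300)
        erm = 100 + 0.1 * cols
        erm_t, _ = fit_layers(_candidates(cols, erm=erm, rpe=erm + 80))
        assert np.max(np.abs(erm_t.rows - (100 + 0.1 * erm_t.columns))) < 1e-3

    def test_noisy_candidates_recovered_within_one_px(self, rng):
        cols = np.arange(0, 400)
        erm_true = 120 + 3 * np.sin(2 * np.pi * cols / 160)
        rpe_true = 200 + 1e-4 * (cols - 200) ** 2
        erm = erm_true + rng.normal(0, 1.0, cols.size)
        rpe = rpe_true + rng.normal(0, 1.0, cols.size)
        erm_t, rpe_t = fit_layers(_candidates(cols, erm=erm, rpe=rpe),
                                  spline_smoothing=1.0)
        erm_ref = 120 + 3 * np.sin(2 * np.pi * erm_t.columns / 160)
        rpe_ref = 200 + 1e-4 * (rpe_t.columns - 200) ** 2
        assert np.abs(erm_t.rows - erm_ref).mean() <= 1.0
        assert np.abs(rpe_t.rows - rpe_ref).mean() <= 1.0

    def test_insufficient_support_names_layer(self):
        cols = np.arange(400)
        rpe = np.full(400, 200.0)
        erm = np.full(400, np.nan)
        erm[:5] = 100.0
        with pytest.raises(LayerFitError, match="ERM"):
            fit_layers(_candidates(cols, erm=erm, rpe=rpe))


class TestSegmentBscan:
    def test_noise_free_phantom_traces(self, clean_series):
        panel = split_composite(clean_series.composites["T1"])
        seg = segment_bscan(panel.bscan)
        truth = clean_series.truth
        assert np.abs(seg.erm.rows - true_rows_at(truth.erm_rows, seg.erm.columns)).mean() <= 1.5
        assert np.abs(seg.rpe.rows - true_rows_at(truth.rpe_rows, seg.rpe.columns)).mean() <= 1.5

    def test_noisy_phantom_traces(self, noisy_series):
        panel = split_composite(noisy_series.composites["T1"])
        seg = segment_bscan(panel.bscan)
        truth = noisy_series.truth
        assert np.abs(seg.erm.rows - true_rows_at(truth.erm_rows, seg.erm.columns)).mean() <= 3.0
        assert np.abs(seg.rpe.rows - true_rows_at(truth.rpe_rows, seg.rpe.columns)).mean() <= 3.0

    def test_single_layer_image_fails_for_erm(self):
        img = np.full((320, 400), 0.03)
        rows = np.arange(320)[:, None]
        img = img + np.exp(-0.5 * ((rows - 200) / 3.0) ** 2)
        with pytest.raises(SegmentationStageError) as err:
            segment_bscan(ImageGrid(img))
        assert "layer fit failed" in str(err.value)

    def test_ordering_invariant(self, noisy_series):
        for tp in ("T1", "T2", "POST"):
            panel = split_composite(noisy_series.composites[tp])
            seg = segment_bscan(panel.bscan)
            assert np.all(seg.erm.rows < seg.rpe.rows)

    def test_intensity_equivariance(self, clean_series):
        panel = split_composite(clean_series.composites["T1"])
        seg1 = segment_bscan(panel.bscan)
        seg2 = segment_bscan(ImageGrid(panel.bscan.pixels * 2.5))
        assert (seg1.roi.row_top, seg1.roi.row_bottom) == (seg2.roi.row_top, seg2.roi.row_bottom)
        assert np.allclose(seg1.erm.rows, seg2.erm.rows)
        assert np.allclose(seg1.rpe.rows, seg2.rpe.rows)

    def test_determinism(self, noisy_series):
        panel = split_composite(noisy_series.composites["T1"])
        seg1 = segment_bscan(panel.bscan)
        seg2 = segment_bscan(panel.bscan)
        assert np.array_equal(seg1.erm.rows, seg2.erm.rows)
        assert np.array_equal(seg1.rpe.rows, seg2.rpe.rows)

    def test_params_recorded_on_result(self, clean_series):
        panel = split_composite(clean_series.composites["T1"])
        params = SegmentationParams(roi_threshold=0.35)
        seg = segment_bscan(panel.bscan, params)
        assert seg.params.roi_threshold == 0.35
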