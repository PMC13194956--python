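"""Profile extraction, peak detection and the rEZR ratio."""

import numpy as np
import pytest

from rezr.io import BScan
from rezr.reflectivity import (
    AxialProfile,
    BandPeaks,
    compute_rezr,
    detect_band_peaks,
    extract_axial_profile,
    measure_scan,
)
from rezr.roi import Location, ROISpec, plan_rois
from rezr.synthetic import PhantomSpec, generate_phantom


def _bump_profile(rows=40, background=20.0, bumps=((10, 100.0), (25, 160.0)), sigma=2.0):
    z = np.arange(rows, dtype=float)
    v = np.full(rows, background)
    for centre, amp in bumps:
        v += amp * np.exp(-((z - centre) ** 2) / (2 * sigma**2))
    return AxialProfile(v, axial_scale=3.0)


class TestExtractProfile:
    def test_constant_image_gives_flat_profile(self):
        scan = BScan(np.full((64, 64), 50, np.uint8), 3.0, 10.0, 32)
        roi = ROISpec(Location("foveola", 0), centre_col=32, top_row=10)
        profile = extract_axial_profile(scan, roi)
        assert len(profile.values) == 40
        np.testing.assert_array_equal(profile.values, 50.0)

    def test_noiseless_phantom_profile_matches_analytic_model(self, clean_phantom):
        spec, scan, truth = clean_phantom
        col = scan.fovea_col
        roi = ROISpec(Location("foveola", 0), centre_col=col,
                      top_row=int(truth.elm_row[col]) - 12)
        profile = extract_axial_profile(scan, roi)
        z = (np.arange(roi.top_row, roi.top_row + 40)) * spec.axial_scale
        cols = roi.columns
        analytic = np.zeros_like(z)
        from rezr.synthetic import _resolve_profile

        elm_d = _resolve_profile(spec.elm_depth_profile)(
            (cols - spec.fovea_col) * spec.lateral_scale
        )
        ez_amp = _resolve_profile(spec.ez_peak_profile)(
            np.abs(cols - spec.fovea_col) * spec.lateral_scale
        )
        for c, d, a in zip(cols, elm_d, ez_amp):
            analytic += (
                spec.background
                + spec.elm_peak * np.exp(-((z - d) ** 2) / (2 * spec.band_sigma_um**2))
                + a * np.exp(-((z - d - spec.band_gap_um) ** 2) / (2 * spec.band_sigma_um**2))
            )
        analytic /= len(cols)
        np.testing.assert_allclose(profile.values, analytic, atol=0.5)

    def test_excluded_roi_is_a_pipeline_error(self, clean_phantom):
        _, scan, _ = clean_phantom
        roi = ROISpec(Location("foveola", 0), centre_col=10, status="excluded")
        with pytest.raises(ValueError, match="excluded"):
            extract_axial_profile(scan, roi)


def _oracle_local_maxima(v):
    return [i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]]


def _oracle_prominence(v, i):
    """Prominence by definition: height above the higher of the two minima
    down to the nearest higher ground on each side (or the signal edge)."""
    left = v[:i][::-1]
    right = v[i + 1:]
    def side_min(arr):
        m = v[i]
        for x in arr:
            if x > v[i]:
                break
            m = min(m, x)
        return m
    return v[i] - max(side_min(left), side_min(right))


def _oracle_detect(profile, min_prom=5.0, min_sep_um=10.0):
    v = profile.values
    cands = [
        (i, _oracle_prominence(v, i))
        for i in _oracle_local_maxima(v)
        if _oracle_prominence(v, i) >= min_prom
    ]
    best = None
    for ai in range(len(cands)):
        for bi in range(ai + 1, len(cands)):
            (a, pa), (b, pb) = cands[ai], cands[bi]
            if (b - a) * profile.axial_scale < min_sep_um:
                continue
            key = (-(pa + pb), a, b)
            if best is None or key < best:
                best = key
    if best is None:
        return None, len(cands)
    return (best[1], best[2]), len(cands)


class TestDetectPeaks:
    def test_constructed_two_bump_profile(self):
        profile = _bump_profile(bumps=((10, 100.0), (25, 160.0)))
        peaks, n = detect_band_peaks(profile)
        assert (peaks.elm_row, peaks.ez_row) == (10, 25)
        rezr = compute_rezr(peaks)
        np.testing.assert_allclose(rezr, peaks.ez_intensity / peaks.elm_intensity)
        np.testing.assert_allclose(peaks.elm_intensity, 120.0, atol=1.0)
        np.testing.assert_allclose(peaks.ez_intensity, 180.0, atol=1.0)

    def test_monotone_ramp_is_peak_failure_with_zero_candidates(self):
        profile = AxialProfile(np.linspace(0, 100, 40), axial_scale=3.0)
        peaks, n = detect_band_peaks(profile)
        assert peaks is None and n == 0

    def test_close_peaks_rejected_by_separation_rule(self):
        profile = _bump_profile(bumps=((18, 100.0), (20, 160.0)), sigma=0.7)
        peaks, _ = detect_band_peaks(profile, min_separation_um=10.0)
        assert peaks is None  # 2 rows * 3 µm < 10 µm

    def test_ordering_invariant_elm_above_ez(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            v = rng.uniform(0, 255, size=40)
            peaks, _ = detect_band_peaks(AxialProfile(v, 3.0))
            if peaks is not None:
                assert peaks.elm_row < peaks.ez_row

    def test_agrees_with_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(12345)
        n_checked = 0
        for _ in range(1000):
            v = rng.uniform(0, 255, size=rng.integers(10, 60))
            profile = AxialProfile(v, axial_scale=3.0)
            peaks, n = detect_band_peaks(profile)
            rows, n_oracle = _oracle_detect(profile)
            assert n == n_oracle
            if rows is None:
                assert peaks is None
            else:
                assert (peaks.elm_row, peaks.ez_row) == rows
                n_checked += 1
        assert n_checked > 500  # the comparison actually exercised pairs

    def test_noisy_phantom_peak_rows_within_one_row_of_truth(self):
        """Detected band rows stay on the true bands under noise (200 seeds)."""
        hits = 0
        total = 0
        for seed in range(200):
            spec = PhantomSpec(noise_sd=5.0, seed=seed)
            scan, truth = generate_phantom(spec)
            col = scan.fovea_col + 100
            roi = ROISpec(
                Location("nasal", 1000),
                centre_col=col,
                top_row=int(truth.elm_row[col]) - 12,
            )
            peaks, _ = detect_band_peaks(extract_axial_profile(scan, roi))
            total += 1
            if peaks is None:
                continue
            elm_true = truth.elm_row[roi.columns].mean() - roi.top_row
            ez_true = truth.ez_row[roi.columns].mean() - roi.top_row
            if abs(peaks.elm_row - elm_true) <= 1 and abs(peaks.ez_row - ez_true) <= 1:
                hits += 1
        assert hits / total >= 0.95


class TestComputeRezr:
    def test_ratio_arithmetic(self):
        peaks = BandPeaks(120.0, 10, 180.0, 25)
        assert compute_rezr(peaks) == pytest.approx(1.5)
        assert compute_rezr(BandPeaks(90.0, 5, 90.0, 20)) == pytest.approx(1.0)

    def test_elm_and_ez_must_be_ordered_and_positive(self):
        with pytest.raises(ValueError, match="shallower"):
            BandPeaks(120.0, 25, 180.0, 10)
        with pytest.raises(ValueError, match="positive"):
            BandPeaks(0.0, 10, 180.0, 25)


class TestMeasureScan:
    def test_horizontal_phantom_gives_8_measurements(self, clean_phantom):
        _, scan, truth = clean_phantom
        ms = measure_scan(scan, plan_rois(scan))
        assert len(ms) == 8
        assert all(m.status == "ok" for m in ms)

    def test_clean_phantom_rezr_within_2_percent_of_truth(self, clean_phantom):
        _, scan, truth = clean_phantom
        rois = plan_rois(scan)
        for m, roi in zip(measure_scan(scan, rois), rois):
            t = truth.rezr[roi.columns].mean()
            assert abs(m.rezr - t) / t < 0.02

    def test_fully_shadowed_scan_propagates_exclusions(self, clean_phantom):
        from rezr.roi import adjust_roi

        spec = PhantomSpec(noise_sd=0.0, shadow_columns=[(-6000.0, 6000.0, 0.5)])
        scan, truth = generate_phantom(spec)
        rois = [
            adjust_roi(r, truth.validity_mask, scan.lateral_scale, scan.fovea_col)
            for r in plan_rois(scan)
        ]
        ms = measure_scan(scan, rois)
        assert all(m.status == "excluded" for m in ms)
        assert all(np.isnan(m.rezr) for m in ms)


class TestBrightnessInvariance:
    def test_global_intensity_scaling_leaves_rezr_unchanged(self):
        """The ratio's purpose: device brightness cancels (pre-quantisation)."""
        spec = PhantomSpec(noise_sd=0.0, elm_peak=110.0,
                           ez_peak_profile=("constant", {"value": 160.0}))
        scan, truth = generate_phantom(spec, quantize=False)
        float_img = np.asarray(scan.pixels, dtype=float)
        roi = ROISpec(
            Location("nasal", 1000),
            centre_col=spec.fovea_col + 100,
            top_row=int(truth.elm_row[spec.fovea_col + 100]) - 12,
        )
        base_peaks, _ = detect_band_peaks(
            extract_axial_profile(float_img, roi, axial_scale=spec.axial_scale)
        )
        base = compute_rezr(base_peaks)
        for c in (0.5, 0.75, 1.25, 1.5):
            peaks, _ = detect_band_peaks(
                extract_axial_profile(c * float_img, roi, axial_scale=spec.axial_scale),
                min_prominence=2.0,
            )
            assert abs(compute_rezr(peaks) - base) / base < 0.01
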