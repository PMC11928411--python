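"""Flow-pixel classification, area-ratio series, cycle detection, IRPI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalsmi.errors import (
    DegenerateInputError,
    FormatError,
    NoPulsatilityError,
)
from renalsmi.simulate.cine import OVERLAY_RGB, generate_cine
from renalsmi.smi import (
    AreaRatioSeries,
    CineLoop,
    FlowColorModel,
    RoiSet,
    area_ratio,
    area_ratio_series,
    classify_flow_pixels,
    compute_irpi,
    detect_cycles,
)

from conftest import small_cine_spec


class TestClassifyFlowPixels:
    def test_uniform_gray_is_all_background(self):
        frame = np.full((32, 32, 3), 120, dtype=np.uint8)
        assert not classify_flow_pixels(frame).any()

    def test_overlay_color_is_all_flow(self):
        frame = np.broadcast_to(
            OVERLAY_RGB.astype(np.uint8), (32, 32, 3)
        ).copy()
        assert classify_flow_pixels(frame).all()

    def test_two_channel_input_rejected(self):
        with pytest.raises(FormatError):
            classify_flow_pixels(np.zeros((8, 8, 2)))

    def test_f1_against_planted_mask(self, clean_cine):
        cine, truth = clean_cine
        pred = classify_flow_pixels(cine.frames[0])
        true = truth.flow_masks[0]
        tp = (pred & true).sum()
        f1 = 2 * tp / (pred.sum() + true.sum())
        assert f1 >= 0.99


class TestAreaRatio:
    def test_exact_count_arithmetic(self):
        roi = np.zeros((40, 25), dtype=bool)
        roi[:40, :25] = True  # 1000 px
        flow = np.zeros_like(roi)
        assert area_ratio(flow, roi) == 0.0
        flow[:10, :25] = True  # 250 px
        assert area_ratio(flow, roi) == 0.25
        assert area_ratio(np.ones_like(roi), roi) == 1.0

    def test_empty_roi_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            area_ratio(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    def test_shape_mismatch_is_format_error(self):
        with pytest.raises(FormatError):
            area_ratio(np.ones((4, 4), bool), np.ones((5, 5), bool))


class TestAreaRatioSeries:
    def test_constant_cine_gives_constant_series(self):
        frames = np.full((10, 16, 16, 3), 100, dtype=np.uint8)
        cine = CineLoop(frames=frames, frame_rate=30.0)
        roi = RoiSet(masks={"interlobular": np.ones((16, 16), bool)})
        series = area_ratio_series(cine, roi)["interlobular"]
        assert np.all(series.a == series.a[0])

    def test_zero_smoothing_is_identity(self, clean_cine):
        cine, truth = clean_cine
        roi = truth.roi_set()
        s0 = area_ratio_series(cine, roi, smoothing_window=0.0)["interlobular"]
        frame_wise = np.array(
            [
                area_ratio(m, roi.masks["interlobular"])
                for m in classify_flow_pixels(cine.frames)
            ]
        )
        assert np.array_equal(s0.a, frame_wise)

    def test_extrema_match_planted_occupancy(self, clean_cine):
        # noise-free default cine, interlobular m=0.3: series min/max inside
        # binomial sampling bounds of p0(1-m), p0(1+m)
        cine, truth = clean_cine
        spec = truth.vessel_specs[0]
        roi = truth.roi_set()
        s = area_ratio_series(cine, roi)["interlobular"]
        n = s.n_roi_pixels
        hi, lo = spec.p0 * (1 + spec.m), spec.p0 * (1 - spec.m)
        sd_hi = np.sqrt(hi * (1 - hi) / n)
        sd_lo = np.sqrt(lo * (1 - lo) / n)
        assert abs(s.a.max() - hi) <= 4 * sd_hi
        assert abs(s.a.min() - lo) <= 4 * sd_lo

    def test_shape_mismatch_rejected(self, clean_cine):
        cine, _ = clean_cine
        roi = RoiSet(masks={"interlobular": np.ones((8, 8), bool)})
        with pytest.raises(FormatError):
            area_ratio_series(cine, roi)


class TestDetectCycles:
    def test_sinusoid_period_count(self):
        fs, f, dur = 120.0, 5.5, 2.0
        t = np.arange(int(fs * dur)) / fs
        a = 0.4 + 0.1 * np.sin(2 * np.pi * f * t)
        series = AreaRatioSeries(t=t, a=a)
        det = detect_cycles(series)
        periods = dur * det.frequency_hz
        assert abs(periods - 11) <= 1

    def test_constant_trace_raises(self):
        t = np.arange(240) / 120.0
        with pytest.raises(NoPulsatilityError):
            detect_cycles(AreaRatioSeries(t=t, a=np.full(240, 0.4)))

    def test_generator_rate_recovered(self, clean_cine):
        cine, truth = clean_cine
        s = area_ratio_series(cine, truth.roi_set())["interlobular"]
        det = detect_cycles(s)
        assert det.frequency_hz == pytest.approx(5.5, rel=0.05)


class TestComputeIrpi:
    def test_constant_series_global_zero(self):
        t = np.arange(10) / 10.0
        res = compute_irpi(
            AreaRatioSeries(t=t, a=np.full(10, 0.4)), method="global"
        )
        assert res.irpi == 0.0

    def test_two_level_series(self):
        t = np.arange(10) / 10.0
        a = np.array([0.5, 0.25] * 5)
        res = compute_irpi(AreaRatioSeries(t=t, a=a), method="global")
        assert res.irpi == pytest.approx(0.5)

    def test_zero_amax_is_degenerate(self):
        t = np.arange(10) / 10.0
        with pytest.raises(DegenerateInputError):
            compute_irpi(AreaRatioSeries(t=t, a=np.zeros(10)), method="global")

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=10,
            max_size=10,
        )
    )
    def test_global_method_matches_brute_force(self, values):
        a = np.array(values)
        series = AreaRatioSeries(t=np.arange(10) / 10.0, a=a)
        res = compute_irpi(series, method="global")
        assert res.irpi == pytest.approx(
            (a.max() - a.min()) / a.max(), abs=1e-15
        )
        assert 0.0 <= res.irpi <= 1.0

    def test_scale_invariance(self, clean_cine):
        cine, truth = clean_cine
        s = area_ratio_series(cine, truth.roi_set())["interlobular"]
        for c in (0.25, 0.9):
            scaled = AreaRatioSeries(t=s.t, a=c * s.a)
            for method in ("global", "per_cycle_median"):
                r1 = compute_irpi(s, method=method)
                r2 = compute_irpi(scaled, method=method)
                assert abs(r1.irpi - r2.irpi) <= 1e-12

    def test_monotone_in_modulation_small(self):
        irpis = []
        for m in (0.1, 0.3, 0.5):
            cine, truth = generate_cine(small_cine_spec(m=m, seed=4))
            s = area_ratio_series(cine, truth.roi_set())["interlobular"]
            irpis.append(compute_irpi(s).irpi)
        assert irpis[0] < irpis[1] < irpis[2]


class TestRoiSet:
    def test_combined_must_contain_union(self):
        a = np.zeros((8, 8), bool)
        a[0, 0] = True
        b = np.zeros((8, 8), bool)
        b[1, 1] = True
        bad_combined = a.copy()  # missing b
        with pytest.raises(Exception, match="combined"):
            RoiSet(
                masks={
                    "interlobular": a,
                    "interlobar": b,
                    "combined": bad_combined,
                }
            )
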