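"""Chip uptake kinetics: trace extraction, ratio law, OLS fit, group tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from btbquant import (
    ChipSimConfig,
    RatioSeries,
    RoiTrace,
    UptakeKinetics,
    compare_groups,
    estimate_steady_state_delay,
    extract_roi_traces,
    fit_kin,
    simulate_chip_stack,
    trim_to_steady_state,
    uptake_ratio,
)
from btbquant.exceptions import (
    DegenerateInputError,
    InputError,
    InsufficientDataError,
)


class TestExtraction:
    def test_roi_sum_is_plain_pixel_sum(self):
        stack = np.zeros((1, 2, 2))
        stack[0] = [[3.0, 4.0], [7.0, 0.0]]
        mask = np.array([[2, 2], [1, 1]])
        trace = extract_roi_traces(stack, mask, [0.0])
        assert trace.c_cc[0] == 7.0
        assert trace.c_pf[0] == 7.0

    def test_missing_label_and_shape_mismatch_raise(self):
        stack = np.ones((2, 4, 4))
        mask = np.ones((4, 4), int)  # central label 2 absent
        with pytest.raises(InputError):
            extract_roi_traces(stack, mask, [0.0, 1.0])
        with pytest.raises(InputError):
            extract_roi_traces(stack, np.ones((3, 3), int), [0.0, 1.0])

    def test_trace_matches_generator_analytic_series(self, clean_chip, clean_trace):
        truth = clean_chip.truth
        assert np.allclose(clean_trace.c_pf, truth["c_pf_sum"])
        assert np.allclose(clean_trace.c_cc, truth["c_cc_sum"])

    def test_nonpositive_outer_signal_names_frame(self):
        with pytest.raises(InputError, match="frame 1"):
            RoiTrace(times=[0, 1, 2], c_pf=[1.0, 0.0, 1.0], c_cc=[0, 0, 0])

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(InputError):
            RoiTrace(times=[0, 1, 1], c_pf=[1, 1, 1], c_cc=[0, 0, 0])


class TestUptakeRatio:
    def test_empty_central_compartment_gives_unity(self):
        trace = RoiTrace(times=[0.0], c_pf=[100.0], c_cc=[0.0])
        assert uptake_ratio(trace).ratio[0] == 1.0

    def test_half_filled_central_gives_one_point_five(self):
        trace = RoiTrace(times=[0.0], c_pf=[100.0], c_cc=[50.0])
        assert uptake_ratio(trace).ratio[0] == 1.5

    def test_ratio_affine_past_delay_on_clean_trace(self, clean_chip, clean_trace):
        series = uptake_ratio(clean_trace)
        post = series.times >= clean_chip.config.steady_state_delay
        slopes = np.diff(series.ratio[post]) / np.diff(series.times[post])
        assert np.allclose(slopes, clean_chip.config.true_kin, rtol=1e-8)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_gain_invariance(self, scale):
        """Multiplying both compartments by one gain leaves the ratio unchanged."""
        t = np.arange(5.0)
        pf = np.full(5, 200.0)
        cc = np.linspace(0, 80, 5)
        base = uptake_ratio(RoiTrace(times=t, c_pf=pf, c_cc=cc)).ratio
        scaled = uptake_ratio(RoiTrace(times=t, c_pf=pf * scale, c_cc=cc * scale)).ratio
        assert np.allclose(base, scaled, rtol=1e-9)


class TestTrim:
    def test_first_retained_frame_reorigins_to_zero(self):
        series = RatioSeries(times=np.arange(0, 91, 2.0), ratio=np.ones(46))
        out = trim_to_steady_state(series, 22.0)
        assert out.times[0] == 0.0
        assert len(out) == 35  # frames at 22..90 min inclusive

    def test_zero_delay_is_identity(self):
        series = RatioSeries(times=np.arange(0, 10.0), ratio=np.arange(10.0))
        out = trim_to_steady_state(series, 0.0)
        assert np.array_equal(out.times, series.times)
        assert np.array_equal(out.ratio, series.ratio)

    def test_delay_beyond_last_frame_rejected(self):
        series = RatioSeries(times=np.arange(0, 91, 2.0), ratio=np.ones(46))
        with pytest.raises(InputError):
            trim_to_steady_state(series, 95.0)

    def test_near_terminal_delay_leaves_too_few_points_to_fit(self):
        series = RatioSeries(times=np.arange(0, 91, 2.0), ratio=np.ones(46))
        out = trim_to_steady_state(series, 89.9)
        assert len(out) == 1
        with pytest.raises(InsufficientDataError):
            fit_kin(out)


class TestFit:
    def test_exact_line_recovered(self):
        series = RatioSeries(times=np.array([0.0, 2.0, 4.0]),
                             ratio=np.array([1.0, 1.2, 1.4]))
        est = fit_kin(series)
        assert est.kin == pytest.approx(0.1, abs=1e-12)
        assert est.oc == pytest.approx(1.0, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0)
        assert est.p_slope_gt_zero == 0.0

    def test_constant_series_null_slope(self):
        series = RatioSeries(times=np.arange(5.0), ratio=np.full(5, 1.3))
        est = fit_kin(series)
        assert est.kin == pytest.approx(0.0, abs=1e-12)
        assert est.p_slope_gt_zero >= 0.5

    def test_degenerate_time_axis_rejected(self):
        with pytest.raises((DegenerateInputError, InputError)):
            UptakeKinetics(RatioSeries(times=np.array([1.0, 1.0, 1.0]),
                                       ratio=np.array([1.0, 2.0, 3.0])))

    def test_noise_free_roundtrip_matches_generator(self, clean_chip, clean_trace):
        cfg = clean_chip.config
        est = UptakeKinetics.from_trace(clean_trace, cfg.steady_state_delay).fit()
        assert est.kin == pytest.approx(cfg.true_kin, abs=1e-9)
        assert est.oc == pytest.approx(cfg.intercept_oc, abs=1e-9)

    def test_monte_carlo_recovery_unbiased(self):
        """Mean fitted k_in over 200 noisy chips lies within 3 SE of truth."""
        true_kin = 2.12  # tumor-barrier scale slope
        fits = []
        for seed in range(200):
            cfg = ChipSimConfig(true_kin=true_kin, intercept_oc=1.2,
                                noise_sd=30.0, image_shape=(16, 16), seed=seed)
            sim = simulate_chip_stack(cfg)
            trace = extract_roi_traces(sim.stack, sim.mask, sim.times)
            fits.append(UptakeKinetics.from_trace(trace, 22.0).fit().kin)
        fits = np.asarray(fits)
        se = fits.std(ddof=1) / np.sqrt(fits.size)
        assert abs(fits.mean() - true_kin) < 3 * se + 1e-6

    def test_time_reorigin_shifts_only_intercept(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 40, 2.0)
        r = 1.1 + 0.05 * t + rng.normal(0, 0.02, t.size)
        a = fit_kin(RatioSeries(times=t, ratio=r))
        b = fit_kin(RatioSeries(times=t + 13.0, ratio=r))
        assert a.kin == pytest.approx(b.kin, rel=1e-9)
        assert a.oc != pytest.approx(b.oc, rel=1e-3)

    def test_changepoint_estimator_finds_configured_delay(self):
        for delay in (22.0, 36.0):
            cfg = ChipSimConfig(true_kin=0.2, steady_state_delay=delay,
                                noise_sd=0.0, total_duration=90.0)
            sim = simulate_chip_stack(cfg)
            trace = extract_roi_traces(sim.stack, sim.mask, sim.times)
            est = estimate_steady_state_delay(uptake_ratio(trace))
            assert est == pytest.approx(delay, abs=cfg.frame_interval)


class TestGroupComparison:
    def test_identical_groups_are_indistinguishable(self):
        comp = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert comp.t_welch == pytest.approx(0.0, abs=1e-12)
        assert comp.p_welch == pytest.approx(1.0)
        assert comp.f_stat == pytest.approx(1.0)

    def test_welch_t_matches_hand_computation(self):
        """(1,2,3) vs (11,12,13): t = -10/sqrt(2/3), df = 4 by Welch-Satterthwaite."""
        comp = compare_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        t_hand = -10.0 / np.sqrt(2.0 / 3.0)
        assert comp.t_welch == pytest.approx(t_hand, rel=1e-9)
        assert comp.df_welch == pytest.approx(4.0, rel=1e-9)
        p_hand = 2 * sstats.t.sf(abs(t_hand), 4)
        assert comp.p_welch == pytest.approx(p_hand, rel=1e-6)

    def test_f_test_puts_larger_variance_in_numerator(self):
        comp = compare_groups([0.0, 10.0, 20.0], [1.0, 1.1, 1.2])
        assert comp.f_stat >= 1.0
        comp_rev = compare_groups([1.0, 1.1, 1.2], [0.0, 10.0, 20.0])
        assert comp.f_stat == pytest.approx(comp_rev.f_stat)
        assert comp.p_f == pytest.approx(comp_rev.p_f)

    def test_undersized_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [1.0, 2.0])

    def test_separated_groups_detected_in_most_replicates(self):
        """Restricted-barrier vs unrestricted-diffusion slopes: p<0.05 in >=95%."""
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            bbb = rng.normal(0.18, 0.05, size=3)
            free = rng.normal(3.0, 0.3, size=3)
            if compare_groups(bbb, free).p_welch < 0.05:
                hits += 1
        assert hits >= 0.95 * n_rep
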