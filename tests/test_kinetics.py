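import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rckring import synthetic
from rckring.errors import DegenerateTraceError, FitFailureError, UsageError
from rckring.kinetics import (
    ExponentialDecayModel,
    ExponentialFit,
    FluxTrace,
    HillModel,
    NormalizationAnchors,
    TitrationSeries,
    derive_anchors,
    extract_rate,
    fit_exponential,
    fit_hill,
    hill_equation,
    normalize,
    select_model,
    summarize_rates,
)


class TestNormalization:
    def test_anchor_points_map_to_one_and_zero(self):
        trace = synthetic.make_flux_trace(0.05, valinomycin_tail=100.0,
                                          raw_scale=900.0, raw_offset=120.0)
        anchors = derive_anchors(trace, "valinomycin")
        nf = normalize(trace, anchors, "valinomycin")
        last_baseline = nf.fluorescence[nf.time <= nf.cccp_time][-1]
        assert last_baseline == pytest.approx(1.0)
        assert nf.fluorescence[nf.time >= trace.valinomycin_time].min() == pytest.approx(0.0)

    def test_matches_hand_computed_formula(self):
        trace = synthetic.make_flux_trace(0.08, valinomycin_tail=100.0,
                                          raw_scale=500.0, raw_offset=40.0, noise_sigma=0.01,
                                          seed=6)
        anchors = derive_anchors(trace, "valinomycin")
        nf = normalize(trace, anchors, "valinomycin")
        expected = (trace.fluorescence - anchors.F_val) / (anchors.F_ini - anchors.F_val)
        assert nf.fluorescence == pytest.approx(expected)

    def test_steady_state_mode_uses_final_window_mean(self):
        trace = synthetic.make_flux_trace(0.10, floor=0.2, raw_scale=300.0)
        anchors = derive_anchors(trace, "steady_state")
        window = trace.time > trace.time[-1] - 50.0
        assert anchors.F_ss == pytest.approx(trace.fluorescence[window].mean())
        nf = normalize(trace, anchors, "steady_state")
        assert nf.fluorescence[-1] == pytest.approx(0.0, abs=1e-3)

    @given(st.floats(min_value=0.1, max_value=50.0), st.floats(min_value=-100.0, max_value=100.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_affine_invariance(self, a, b):
        base = synthetic.make_flux_trace(0.096, valinomycin_tail=100.0, seed=2)
        scaled = FluxTrace(time=base.time, fluorescence=a * base.fluorescence + b,
                           cccp_time=base.cccp_time, valinomycin_time=base.valinomycin_time)
        nf1 = normalize(base, mode="valinomycin").fluorescence
        nf2 = normalize(scaled, mode="valinomycin").fluorescence
        assert nf2 == pytest.approx(nf1, abs=1e-9)

    def test_flat_trace_is_degenerate(self):
        t = np.arange(0.0, 300.0, 2.0)
        trace = FluxTrace(time=t, fluorescence=np.ones_like(t), valinomycin_time=250.0)
        with pytest.raises(DegenerateTraceError):
            normalize(trace, NormalizationAnchors(F_ini=1.0, F_val=1.0), "valinomycin")

    def test_missing_valinomycin_segment_is_usage_error(self):
        trace = synthetic.make_flux_trace(0.05)
        with pytest.raises(UsageError):
            normalize(trace, mode="valinomycin")


class TestExponentialFit:
    def test_noiseless_single_exponential_recovered_exactly(self):
        trace = synthetic.make_flux_trace(0.1, floor=0.05)  # tau = 10 s
        fit = fit_exponential(trace, order=1)
        assert fit.tau == pytest.approx(10.0, abs=1e-6)
        assert fit.y0 == pytest.approx(0.05, abs=1e-6)
        assert fit.A1 == pytest.approx(0.95, abs=1e-6)

    def test_noisy_trace_tau_within_five_percent(self):
        errs = []
        for seed in range(30):
            trace = synthetic.make_flux_trace(1 / 10.4, noise_sigma=0.01, seed=seed)
            fit = fit_exponential(trace, order=1)
            errs.append(abs(fit.tau - 10.4) / 10.4)
        assert np.median(errs) < 0.05

    def test_two_phase_taus_within_ten_percent(self):
        taus_f, taus_s = [], []
        for seed in range(10):
            trace = synthetic.make_flux_trace(1 / 8.0, k_slow=1 / 80.0, amp_fast=0.6,
                                              noise_sigma=0.01, seed=seed)
            fit = fit_exponential(trace, order=2)
            taus_f.append(fit.tau_fast)
            taus_s.append(fit.tau_slow)
        assert np.mean(taus_f) == pytest.approx(8.0, rel=0.10)
        assert np.mean(taus_s) == pytest.approx(80.0, rel=0.10)

    def test_first_post_cccp_point_is_excluded(self):
        trace = synthetic.make_flux_trace(0.1)
        # corrupt exactly the first post-CCCP sample: fit must be unaffected
        idx = int(np.argmax(trace.time > trace.cccp_time))
        corrupted = trace.fluorescence.copy()
        corrupted[idx] = 5.0
        trace2 = FluxTrace(time=trace.time, fluorescence=corrupted,
                           cccp_time=trace.cccp_time)
        fit = fit_exponential(trace2, order=1)
        assert fit.tau == pytest.approx(10.0, abs=1e-6)

    def test_flat_trace_raises_degenerate(self):
        t = np.arange(0.0, 300.0, 2.0)
        trace = FluxTrace(time=t, fluorescence=np.ones_like(t))
        with pytest.raises(DegenerateTraceError):
            fit_exponential(trace, order=1)

    def test_too_few_points_is_usage_error(self):
        t = np.arange(0.0, 125.0, 2.0)
        y = np.exp(-0.1 * np.clip(t - 100, 0, None))
        trace = FluxTrace(time=t, fluorescence=y)
        with pytest.raises(UsageError):
            ExponentialDecayModel(order=2, x0=118.0).fit(trace)

    def test_estimator_predict_matches_model(self):
        trace = synthetic.make_flux_trace(0.096)
        est = ExponentialDecayModel(order=1).fit(trace)
        post = trace.time >= trace.cccp_time
        assert est.predict(trace.time[post]) == pytest.approx(
            trace.fluorescence[post], abs=1e-6)
        assert est.get_params()["order"] == 1


class TestModelSelection:
    def test_pure_single_exponential_prefers_order_one(self):
        trace = synthetic.make_flux_trace(0.096, noise_sigma=0.01, seed=1)
        fit1 = fit_exponential(trace, order=1)
        fit2 = fit_exponential(trace, order=2)
        assert select_model(fit1, fit2).order == 1

    def test_strongly_biphasic_data_prefers_order_two(self):
        trace = synthetic.make_flux_trace(0.2, k_slow=0.02, amp_fast=0.5,
                                          noise_sigma=0.01, seed=3)
        fit1 = fit_exponential(trace, order=1)
        fit2 = fit_exponential(trace, order=2)
        assert select_model(fit1, fit2).order == 2

    def test_tie_goes_to_the_simpler_model(self):
        f1 = ExponentialFit(order=1, y0=0, x0=100, A1=1, tau=10,
                            information_criterion=-100.0, n_points=200)
        f2 = ExponentialFit(order=2, y0=0, x0=100, A1=0.5, A2=0.5, tau_fast=5,
                            tau_slow=50, information_criterion=-100.0, n_points=200)
        assert select_model(f1, f2).order == 1
        with pytest.raises(UsageError):
            select_model(f1, ExponentialFit(order=2, y0=0, x0=90, A1=1, A2=0,
                                            tau_fast=1, tau_slow=2, n_points=100))


class TestRateExtraction:
    def test_inversion_of_time_constant(self):
        fit = ExponentialFit(order=1, y0=0, x0=100, A1=1, tau=10.417)
        assert extract_rate(fit).k == pytest.approx(0.096, abs=5e-4)
        assert extract_rate(ExponentialFit(order=1, y0=0, x0=0, A1=1, tau=1.0)).k == 1.0

    def test_fast_component_reported_with_dominance_flag(self):
        fit = ExponentialFit(order=2, y0=0, x0=100, A1=0.3, A2=0.5,
                             tau_fast=5.0, tau_slow=50.0)
        rate = extract_rate(fit)
        assert rate.k == pytest.approx(0.2)
        assert rate.component == "fast"
        assert rate.fast_dominant is False

    def test_invalid_tau_rejected(self):
        with pytest.raises(FitFailureError):
            extract_rate(ExponentialFit(order=1, y0=0, x0=0, A1=1, tau=-1.0))

    def test_round_trip_with_summary(self):
        ks = [1.0 / tau for tau in (10.0, 12.0, 11.0)]
        mean, sd = summarize_rates(ks)
        assert mean == pytest.approx(np.mean(ks))
        assert sd == pytest.approx(np.std(ks, ddof=1))


class TestHillFit:
    def test_noiseless_titration_recovered_exactly(self):
        series = synthetic.make_titration(155.0, 1.8, 0.01, 0.10, synthetic.MG_GRID_UM,
                                          replicate_noise_sigma=0.0, n_replicates=1)[0]
        fit = fit_hill(series)
        assert fit.k_half == pytest.approx(155.0, abs=1e-4)
        assert fit.n_hill == pytest.approx(1.8, abs=1e-6)
        assert fit.start == pytest.approx(0.01, abs=1e-6)
        assert fit.end == pytest.approx(0.10, abs=1e-6)

    @pytest.mark.parametrize("k_half,n_hill,grid,unit", [
        (155.0, 1.8, synthetic.MG_GRID_UM, "uM"),
        (25.0, 1.9, synthetic.CHOLINE_GRID_MM, "mM"),
    ])
    def test_noisy_replicates_recover_k_half_within_15_percent(self, k_half, n_hill, grid, unit):
        fits = [
            fit_hill(s)
            for s in synthetic.make_titration(k_half, n_hill, 0.01, 0.10, grid, unit=unit,
                                              replicate_noise_sigma=0.05, n_replicates=3,
                                              seed=20)
        ]
        k_mean = np.mean([f.k_half for f in fits])
        n_mean = np.mean([f.n_hill for f in fits])
        assert abs(k_mean - k_half) / k_half < 0.15
        assert abs(n_mean - n_hill) < 0.4

    def test_two_point_series_is_precondition_error(self):
        series = TitrationSeries(concentrations=[0.0, 100.0], rates=[0.01, 0.1])
        with pytest.raises(UsageError):
            fit_hill(series)

    def test_unit_handling(self):
        series = TitrationSeries(concentrations=[0, 5, 25, 100, 150],
                                 rates=hill_equation(np.array([0, 5, 25, 100, 150]),
                                                     0.01, 0.1, 25.0, 1.9),
                                 unit="mM")
        fit = fit_hill(series)
        assert fit.unit == "mM"
        assert fit.k_half == pytest.approx(25.0, abs=1e-3)
        assert series.conc_um[1] == pytest.approx(5000.0)
        with pytest.raises(UsageError):
            TitrationSeries(concentrations=[0, 1], rates=[0, 1], unit="furlong")

    def test_estimator_predict_round_trip(self):
        x = synthetic.MG_GRID_UM
        y = hill_equation(x, 0.01, 0.1, 155.0, 1.8)
        est = HillModel().fit(x, y)
        assert est.predict(x) == pytest.approx(y, abs=1e-6)
        assert est.get_params() == {"weighted": False, "max_restarts": 4}


class TestTraceValidation:
    def test_time_must_increase_and_have_post_cccp_points(self):
        with pytest.raises(UsageError):
            FluxTrace(time=np.array([0.0, 2.0, 1.0]), fluorescence=np.zeros(3))
        with pytest.raises(UsageError):
            FluxTrace(time=np.arange(0.0, 20.0, 2.0), fluorescence=np.zeros(10))
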