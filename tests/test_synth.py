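"""Synthetic generator: kernels, rate profiles, Poisson statistics, truth."""

import numpy as np
import pytest
from scipy import integrate

import glomclass as gc
from glomclass.recording import ParameterError
from glomclass.synth import (
    draw_vc_events,
    frac_fast_for_tau_w,
    psc_decay_truth,
    psc_kernel_peak_time,
)


class TestPscKernel:
    def test_zero_at_onset_and_before(self):
        assert gc.psc_kernel(0.0, 0.0005, 0.005, 0.05, 0.7) == 0.0
        assert gc.psc_kernel(-0.01, 0.0005, 0.005, 0.05, 0.7) == 0.0

    def test_single_exponential_limit(self):
        # vanishing rise, one component: value at t = tau1 is 1/e of peak
        v = gc.psc_kernel(0.005, 1e-7, 0.005, 0.005, 1.0)
        assert v == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_closed_form_value(self):
        # independent dense-grid evaluation of the closed form
        rise, t1, t2, f = 0.0005, 0.005, 0.050, 0.7
        raw = lambda t: ((1 - np.exp(-t / rise))
                         * (f * np.exp(-t / t1) + (1 - f) * np.exp(-t / t2)))
        grid = np.linspace(0.0, 0.3, 300001)
        expected = raw(0.010) / raw(grid).max()
        assert gc.psc_kernel(0.010, rise, t1, t2, f) == pytest.approx(
            expected, rel=1e-6)

    def test_peak_normalised_to_one(self):
        t = np.linspace(0, 0.5, 20001)
        k = gc.psc_kernel(t, 0.001, 0.01, 0.1, 0.5)
        assert k.max() == pytest.approx(1.0, abs=1e-4)

    def test_nonpositive_time_constant_rejected(self):
        with pytest.raises(ParameterError):
            gc.psc_kernel(0.01, 0.0, 0.005, 0.05, 0.5)

    def test_post_peak_decay_truth_matches_quadrature_free_algebra(self):
        rise, t1, t2 = 0.0005, 0.005, 0.020
        f = frac_fast_for_tau_w(0.008, rise, t1, t2)
        w1, w2, tw = psc_decay_truth(rise, t1, t2, f)
        assert w1 + w2 == pytest.approx(1.0)
        assert tw == pytest.approx(0.008, rel=1e-6)
        tpk = psc_kernel_peak_time(rise, t1, t2, f)
        a1 = f * np.exp(-tpk / t1)
        a2 = (1 - f) * np.exp(-tpk / t2)
        assert w1 == pytest.approx(a1 / (a1 + a2))


class TestRateProfile:
    def test_full_suppression_window_is_exactly_zero(self):
        cfg = gc.LcaSimConfig(baseline_rate=5.0, inhibition_duration=0.4,
                              inhibition_depth=1.0, musc_gain=1.0,
                              stim_times=(0.5,))
        lam = gc.rate_profile(cfg)
        assert lam(np.array([0.55, 0.89])).tolist() == [0.0, 0.0]
        assert lam(np.array([0.49, 0.91])).tolist() == [5.0, 5.0]

    def test_muscarinic_peak_is_gain_times_baseline(self):
        cfg = gc.LcaSimConfig(baseline_rate=1.0, inhibition_duration=0.0,
                              musc_gain=3.0, stim_times=(0.0,),
                              episode_duration=15.0)
        lam = gc.rate_profile(cfg)
        t = np.linspace(0, 15, 150001)
        assert lam(t).max() == pytest.approx(3.0, rel=1e-4)

    def test_integral_matches_quadrature(self):
        cfg = gc.LcaSimConfig(baseline_rate=1.2, inhibition_duration=0.0,
                              musc_gain=3.0, musc_rise=0.3, musc_decay=3.0,
                              stim_times=(0.5,), episode_duration=15.0)
        lam = gc.rate_profile(cfg)
        got, _ = integrate.quad(lambda t: float(lam(t)), 0.5, 10.5, limit=200)
        # analytic: baseline*10 + baseline*(gain-1)*int g over [0, 10]
        rise, dec = 0.3, 3.0
        tpk = np.log(dec / rise) * rise * dec / (dec - rise)
        peak = np.exp(-tpk / dec) - np.exp(-tpk / rise)
        g_int = (dec * (1 - np.exp(-10 / dec))
                 - rise * (1 - np.exp(-10 / rise))) / peak
        expected = 1.2 * 10 + 1.2 * 2.0 * g_int
        assert got == pytest.approx(expected, rel=1e-6)


class TestSimulateLca:
    def test_silent_cell_trace_is_noise_plus_step(self):
        cfg = gc.LcaSimConfig(baseline_rate=0.0, evoked_spike_prob=0.0,
                              inhibition_duration=0.0, capacitive_step_pA=-5.0,
                              noise_sd=0.0, n_episodes=2, seed=0)
        rec, truth = gc.simulate_lca(cfg)
        assert sum(len(t) for t in truth.spike_times) == 0
        assert rec.traces.min() == pytest.approx(-5.0, rel=1e-2)

    def test_poisson_count_oracle(self):
        cfg = gc.LcaSimConfig(baseline_rate=5.0, inhibition_duration=0.0,
                              n_episodes=100, episode_duration=2.0, seed=42,
                              stim_times=())
        trains = gc.simulate_lca_spikes(cfg)
        n = trains.n_spikes
        # 2 ms refractory removes ~1% of candidate spikes
        assert abs(n - 1000) < 3 * np.sqrt(1000) + 15

    def test_forced_evoked_spike_latency(self):
        cfg = gc.LcaSimConfig(baseline_rate=0.0, inhibition_duration=0.0,
                              evoked_spike_prob=1.0, evoked_latency_mean=0.013,
                              evoked_latency_sd=0.0, noise_sd=0.0,
                              n_episodes=5, stim_times=(0.5,), seed=1)
        rec, truth = gc.simulate_lca(cfg)
        spk = gc.detect_spikes(rec, threshold=50.0)
        for train in spk.trains:
            assert len(train) == 1
            assert train[0] - 0.5 == pytest.approx(0.013, abs=1e-4)

    def test_seed_determinism_bytes(self, tmp_path):
        cfg = gc.LcaSimConfig(baseline_rate=3.0, n_episodes=2, seed=7)
        rec1, _ = gc.simulate_lca(cfg)
        rec2, _ = gc.simulate_lca(cfg)
        assert np.array_equal(rec1.traces, rec2.traces)
        b1 = gc.write_recording(rec1, tmp_path / "a")
        b2 = gc.write_recording(rec2, tmp_path / "b")
        assert (tmp_path / "a.traces.csv").read_bytes() == \
            (tmp_path / "b.traces.csv").read_bytes()

    def test_ground_truth_matches_rendered_spikes(self):
        cfg = gc.LcaSimConfig(baseline_rate=4.0, noise_sd=0.0, n_episodes=5,
                              inhibition_duration=0.0, seed=3)
        rec, truth = gc.simulate_lca(cfg)
        spk = gc.detect_spikes(rec, threshold=50.0)
        for det, tru in zip(spk.trains, truth.spike_times):
            assert len(det) == len(tru)
            if len(det):
                assert np.max(np.abs(det - tru)) < 2.5e-4

    def test_runaway_rate_rejected(self):
        with pytest.raises(ParameterError):
            gc.LcaSimConfig(baseline_rate=1e4, episode_duration=2.0).validate()

    def test_empirical_rate_tracks_profile(self):
        """Windowed spike counts converge to the integral of lambda."""
        cfg = gc.LcaSimConfig(baseline_rate=4.0, inhibition_duration=0.39,
                              inhibition_depth=1.0, musc_gain=2.0,
                              n_episodes=500, episode_duration=4.0,
                              stim_times=(1.5,), seed=9)
        spk = gc.simulate_lca_spikes(cfg)
        lam = gc.rate_profile(cfg)
        for win in [(-1.0, 0.0), (0.0, 0.39), (1.0, 2.0)]:
            counts, _ = gc.rate_in_window(spk, [1.5], win)
            t = np.linspace(1.5 + win[0], 1.5 + win[1], 2001)
            expect = np.trapezoid(lam(t), t)
            tol = 4 * np.sqrt(max(expect, 0.05) / 500) + 0.05 * expect
            assert abs(counts.mean() - expect) < max(tol, 0.02)


class TestSimulateVc:
    def test_pure_noise_when_nothing_enabled(self):
        cfg = gc.VcSimConfig(spont_event_rate=0.0, noise_sd=1.0,
                             n_episodes=2, seed=0, stim_times=())
        rec, truth = gc.simulate_vc(cfg)
        assert truth.event_times[0].size == 0
        assert abs(rec.traces.std() - 1.0) < 0.05

    def test_single_evoked_psc_peak_equals_amplitude(self):
        cfg = gc.VcSimConfig(spont_event_rate=0.0, noise_sd=0.0,
                             evoked_latency=0.005, evoked_amplitude_pA=62.0,
                             psc_polarity="inward", n_episodes=1, seed=0)
        rec, _ = gc.simulate_vc(cfg)
        assert rec.traces.min() == pytest.approx(-62.0, rel=1e-6)

    def test_spontaneous_poisson_count_oracle(self):
        cfg = gc.VcSimConfig(spont_event_rate=15.7, n_episodes=20,
                             episode_duration=2.0, seed=5, stim_times=())
        times, _ = draw_vc_events(cfg)
        n = sum(len(t) for t in times)
        assert abs(n - 628) < 3 * np.sqrt(628)

    def test_ground_truth_counts_match_render(self):
        cfg = gc.VcSimConfig(spont_event_rate=3.0, noise_sd=0.0, n_episodes=4,
                             seed=2, min_event_interval=0.05, stim_times=())
        rec, truth = gc.simulate_vc(cfg)
        ev = gc.detect_events(rec, polarity="inward")
        assert ev.n_events == sum(len(t) for t in truth.event_times)


class TestCohort:
    def test_empty_spec_yields_empty_truth(self, tmp_path):
        truth = gc.simulate_cohort([], tmp_path, seed=0)
        assert len(truth) == 0

    def test_truth_table_rows_and_labels(self, tmp_path):
        spec = [("nonresponsive", None, 3), ("inhibition", None, 3)]
        truth = gc.simulate_cohort(spec, tmp_path, seed=1, render=False)
        assert len(truth) == 6
        assert set(truth["label"]) == {"nonresponsive", "inhibition"}
        assert truth["cell_id"].is_unique

    def test_unknown_label_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            gc.simulate_cohort([("mystery", None, 1)], tmp_path, seed=0)

    def test_rendered_cohort_round_trips(self, tmp_path):
        cfg = gc.LcaSimConfig(baseline_rate=1.0, n_episodes=2,
                              episode_duration=1.0, stim_times=(0.5,),
                              inhibition_duration=0.0)
        truth = gc.simulate_cohort([("nonresponsive", cfg, 2)], tmp_path,
                                   seed=3, render=True)
        rec = gc.read_recording(tmp_path / truth["cell_id"].iloc[0])
        assert rec.provenance == "synthetic"
        assert rec.n_episodes == 2
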